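"""Trial-to-trial reliability of the sparse strong responses (shuffle ROC).

Tests, per simulated neuron, whether above-half-max responses repeat across
trials (1000 label shuffles, p < 0.01), and calibrates the test's type-I
error on stimulus-independent null neurons.
"""

import argparse
import json
from pathlib import Path

from v1sparse import studies
from v1sparse.reliability import population_reliability


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    tensor, _ = studies.desk_scale_tensor(args.seed)
    table, frac = population_reliability(tensor, seed=args.seed)
    table.to_csv(args.out_dir / "reliability.csv", index=False)
    cal = studies.reliability_calibration_study(args.seed + 1)
    (args.out_dir / "reliability.json").write_text(
        json.dumps({"fraction_significant": frac, "type1_rate_null": cal["type1_rate"]})
    )
    print(
        f"{100 * frac:.1f}% of {tensor.n_neurons} neurons have reliable sparse "
        f"strong responses (shuffle-ROC p < 0.01); null calibration: type-I "
        f"rate {cal['type1_rate']:.4f} at alpha = 0.01 over {cal['n_null']} null neurons"
    )


if __name__ == "__main__":
    main()
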