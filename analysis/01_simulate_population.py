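"""Generate the desk-scale synthetic population used by all later steps.

Writes the trial x stimulus x neuron dF/F0 tensor (200 stimuli x 200
neurons x 3 trials, one strong responder per stimulus) plus its ground
truth to results/analysis/.
"""

import argparse
import json
from pathlib import Path

from v1sparse import studies


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    tensor, truth = studies.desk_scale_tensor(args.seed)
    tensor.to_hdf5(args.out_dir / "responses.h5")
    truth.to_json(args.out_dir / "ground_truth.json")
    (args.out_dir / "simulate_meta.json").write_text(
        json.dumps({"seed": args.seed, "shape": list(tensor.values.shape)})
    )
    print(
        f"simulated tensor {tensor.values.shape} (trials x stimuli x neurons); "
        f"k_strong={truth.tuning.k_strong}, noise_sd={truth.noise_sd}; "
        f"wrote {args.out_dir}/responses.h5"
    )


if __name__ == "__main__":
    main()
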