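"""Half-max population and life-time sparseness of the simulated population.

Reads the tensor written by 01_simulate_population.py (or regenerates it)
and writes the sparseness summary and count histograms.
"""

import argparse
from pathlib import Path

from v1sparse import studies
from v1sparse.core import ResponseTensor
from v1sparse.sparseness import sparseness_summary


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    tensor_path = args.out_dir / "responses.h5"
    if tensor_path.exists():
        tensor = ResponseTensor.from_hdf5(tensor_path)
    else:
        tensor, _ = studies.desk_scale_tensor(args.seed)

    s = sparseness_summary(tensor)
    s.to_json(args.out_dir / "sparseness.json")
    pop_h, life_h = s.histograms()
    pop_h.to_csv(args.out_dir / "population_sparseness_hist.csv", index=False)
    life_h.to_csv(args.out_dir / "lifetime_sparseness_hist.csv", index=False)
    print(
        f"mean population sparseness: {100 * s.mean_population_sparseness:.2f}% "
        f"({s.per_stimulus_counts.mean():.1f}/{tensor.n_neurons} neurons above "
        f"half-max per stimulus); mean life-time sparseness: "
        f"{100 * s.mean_lifetime_sparseness:.2f}% of {tensor.n_stimuli} stimuli; "
        f"{s.n_excluded_neurons} neurons excluded (non-positive peak)"
    )


if __name__ == "__main__":
    main()
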