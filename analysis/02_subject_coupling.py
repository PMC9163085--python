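"""Per-subject time-resolved coupling.

For each subject of the synthetic cohort: z-score the activity, unwrap
it into frame-wise co-fluctuations, build the structural predictors
(Euclidean distance, shortest path length, communicability) and fit the
multilinear model per node and per frame. Writes the node-by-time
coupling matrices plus per-node summary maps (static coupling, cv,
dynamic-vs-static statistics).
"""

import argparse
from pathlib import Path

import numpy as np

from sfcoupling import RunConfig, build_cohort_model, run_subject


def main():
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--subjects", type=int, default=5)
    p.add_argument("--out", type=Path, default=Path("scratch/analysis/subjects"))
    args = p.parse_args()

    cfg = RunConfig(synthetic={}, seed=args.seed, out_dir=str(args.out))
    model = build_cohort_model(cfg)
    for i in range(args.subjects):
        res = run_subject(cfg, f"sub-{i:02d}", index=i, model=model)
        vals = res.coupling.values
        print(
            f"sub-{i:02d}: coupling {vals.shape}, "
            f"mean R2 {np.nanmean(vals):.3f}, mean static {res.static.mean():.3f}, "
            f"mean cv {np.nanmean(res.cv):.3f}, "
            f"degenerate frames {res.coupling.degenerate_frames}"
        )
    print(f"per-subject outputs in {args.out}")


if __name__ == "__main__":
    main()
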