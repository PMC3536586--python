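#!/usr/bin/env python
"""Scan candidate ranks by consensus-clustering stability.

For each k, repeated seeded factorizations are clustered by dominant
metagene; the cophenetic correlation of the averaged connectivity matrix
scores the stability of k.  The profile is a guide, not a verdict: peaks
mark candidate ranks, and small k can look spuriously stable because
merges of true factors are themselves reproducible.
"""

from pathlib import Path

import pandas as pd

from metanmf import scan_ranks
from metanmf import io

OUT = Path("results/analysis")
SEED = 1
K_VALUES = range(2, 9)
RUNS_PER_K = 20


def main() -> None:
    V = io.read_expression_tsv(OUT / "nmf_input.tsv").to_numpy()
    results = scan_ranks(V, K_VALUES, runs_per_k=RUNS_PER_K, seed=SEED)

    profile = pd.DataFrame(
        {"k": [r.k for r in results], "ccc": [r.ccc for r in results],
         "n_runs": [r.n_runs for r in results]}
    )
    profile.to_csv(OUT / "ccc_profile.tsv", sep="\t", index=False)

    print(profile.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    best = profile.loc[profile["ccc"].idxmax()]
    print(f"CCC maximum at k={int(best.k)} (ccc={best.ccc:.4f}); "
          f"planted rank is 4 — inspect the profile, the argmax alone can "
          f"prefer stable merges at small k")


if __name__ == "__main__":
    main()
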