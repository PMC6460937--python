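#!/usr/bin/env python
"""Group spatial ICA on the benchmark cohort and source-recovery scoring.

Runs the multilevel decomposition (subject PCA to 20 components, group
PCA to order 9, Infomax x 10 with stability clustering), matches the
stabilized group maps against the planted sources with the Hungarian
algorithm on |r|, and writes the per-source match table.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from netmosaic import experiments as E
from netmosaic.cohort import generate_cohort
from netmosaic.experiments import _decompose, _ica_cohort_config
from netmosaic.ica import match_components


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/ica"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(_ica_cohort_config(args.seed))
    dec, _ = _decompose(cohort, order=9, k=20, n_runs=10, seed=args.seed)
    mask_idx = np.flatnonzero(cohort.truth.mask.ravel())
    ri, ci, rvals = match_components(cohort.truth.source_maps[:, mask_idx], dec.group_maps)

    table = pd.DataFrame(
        {
            "planted_source": ri,
            "matched_component": ci,
            "abs_r": np.round(rvals, 4),
            "stability": np.round(dec.stability_index[ci], 4),
            "kind": ["neural" if i in set(cohort.truth.neural_indices) else "artefact" for i in ri],
        }
    ).sort_values("planted_source")
    table.to_csv(args.outdir / "source_recovery.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"sources recovered at |r| >= 0.9: {(rvals >= 0.9).sum()} of {len(rvals)}")

    sweep = E.ica_recovery(args.seed, n_seeds=5)
    print(f"5-seed sweep: recovered per seed = {sweep['recovered_per_seed']}")


if __name__ == "__main__":
    main()
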