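#!/usr/bin/env python
"""Do dominants and subordinates differ in community trait composition?

Stacks the two group CWM matrices into one 70-observation table, then:
PERMANOVA (Euclidean, 999 permutations) for a location difference,
beta-dispersion for a spread difference, per-trait Student's t-tests, and
PCA scores/loadings on the significant traits.
"""

from pathlib import Path

import pandas as pd
from scipy.spatial.distance import pdist, squareform

from traitcomm import (
    beta_dispersion,
    pca_scores,
    per_trait_t_tests,
    permanova,
    stacked_cwm,
)

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 42
N_PERM = 999


def main() -> None:
    cwm_dom = pd.read_csv(BASE / "cwm_dominant.csv", index_col=0)
    cwm_sub = pd.read_csv(BASE / "cwm_subordinate.csv", index_col=0)
    X, groups = stacked_cwm(cwm_dom, cwm_sub)
    D = squareform(pdist(X.to_numpy()))

    perm = permanova(D, groups, n_perm=N_PERM, seed=SEED)
    print(
        f"PERMANOVA: pseudo-F = {perm.pseudo_F:.2f}, p = {perm.p_value:.3f} "
        f"({perm.n_permutations} permutations)"
    )
    disp = beta_dispersion(D, groups, n_perm=N_PERM, seed=SEED + 1)
    print(
        f"beta-dispersion: F = {disp.F:.2f}, permutation p = {disp.p_permutation:.3f}"
    )

    ttab = per_trait_t_tests(cwm_dom, cwm_sub)
    ttab.to_csv(BASE / "cwm_t_tests.csv")
    sig = ttab.index[ttab["significant"]].tolist()
    print(f"t-tests: {len(sig)}/{len(ttab)} traits differ at alpha = 0.05")

    if len(sig) >= 2:
        pca = pca_scores(X[sig])
        pca.scores.to_csv(BASE / "pca_scores.csv", index_label="observation")
        pca.loadings.to_csv(BASE / "pca_loadings.csv", index_label="trait")
        print(
            "PCA on significant traits: PC1/PC2 explain "
            f"{100 * pca.explained_variance_ratio[0]:.1f}% / "
            f"{100 * pca.explained_variance_ratio[1]:.1f}%"
        )


if __name__ == "__main__":
    main()
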