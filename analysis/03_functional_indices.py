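#!/usr/bin/env python
"""Community-weighted means and Rao FD per relevé, per species group.

Builds the two 35-plot × 35-column CWM matrices and the two 35 × 16 FD
matrices (one trait group per FD index) and summarises the FD contrast:
the share of trait groups for which subordinates carry more functional
diversity than dominants.
"""

from pathlib import Path

from traitcomm import build_group_matrices, classify_species, expand_traits, to_percent
from traitcomm.io import read_cover_matrix, read_trait_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cover = read_cover_matrix(BASE / "data" / "cover.csv")
    traits = read_trait_table(BASE / "data" / "traits.csv", BASE / "data" / "trait_schema.yaml")
    pct = to_percent(cover)
    g = classify_species(pct)
    dom, sub = build_group_matrices(pct, expand_traits(traits), g, trait_table=traits)
    for ind, name in ((dom, "dominant"), (sub, "subordinate")):
        ind.cwm.to_csv(BASE / f"cwm_{name}.csv", index_label="plot")
        ind.fd.to_csv(BASE / f"fd_{name}.csv", index_label="plot")
    print(f"CWM matrices: {dom.cwm.shape[0]} plots x {dom.cwm.shape[1]} trait columns")
    print(f"FD matrices:  {dom.fd.shape[0]} plots x {dom.fd.shape[1]} trait groups")
    higher = [
        c for c in dom.fd.columns
        if sub.fd[c].mean(skipna=True) > dom.fd[c].mean(skipna=True)
    ]
    print(
        f"subordinates have higher mean FD for {len(higher)}/{dom.fd.shape[1]} "
        f"trait groups"
    )


if __name__ == "__main__":
    main()
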