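"""Braun-Blanquet conversion and the dominant/subordinate classification.

The seven-point cover-abundance codes are converted to percent cover with
the van der Maarel midpoints (r=(0), +=0.1, 1=5.0, 2=17.5, 3=37.5, 4=62.5,
5=87.5).  Species reaching at least the inclusion threshold (default 1 %)
in at least one relevé are retained and split into dominants (cover strictly
above the dominance threshold, default 25 %, in at least one relevé) and
subordinates (everything else retained).  With Braun-Blanquet data the 25 %
boundary is unambiguous: code 2 converts to 17.5 %, code 3 to 37.5 %.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    BB_ALPHABET,
    BB_TO_PERCENT,
    CoverMatrix,
    GroupAssignment,
    PercentCoverMatrix,
    ValidationError,
)


def convert_braun_blanquet(code: str) -> float:
    """Percent cover midpoint of one Braun-Blanquet code.

    >>> convert_braun_blanquet("2")
    17.5
    """
    try:
        return BB_TO_PERCENT[str(code)]
    except KeyError:
        raise ValidationError(
            f"unknown Braun-Blanquet code {code!r}; expected one of {list(BB_ALPHABET)}"
        ) from None


def to_percent(m: CoverMatrix) -> PercentCoverMatrix:
    """Convert a cover matrix (either scale) to percent cover + presence mask.

    Braun-Blanquet ``r`` becomes 0 % cover but remains a presence; absent
    cells become 0 % and non-presence.
    """
    if m.scale_kind == "percent":
        vals = m.values.astype(float)
        presence = vals.notna() & (vals > 0)
        return PercentCoverMatrix(values=vals.fillna(0.0), presence=presence)

    pct = pd.DataFrame(0.0, index=m.values.index, columns=m.values.columns)
    pres = pd.DataFrame(False, index=m.values.index, columns=m.values.columns)
    for plot in m.values.index:
        for sp in m.values.columns:
            cell = m.values.at[plot, sp]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            pct.at[plot, sp] = convert_braun_blanquet(cell)
            pres.at[plot, sp] = True
    return PercentCoverMatrix(values=pct, presence=pres)


def classify_species(
    m: PercentCoverMatrix,
    inclusion_pct: float = 1.0,
    dominance_pct: float = 25.0,
) -> GroupAssignment:
    """Partition species into dominant / subordinate / excluded.

    A species is dominant if its cover exceeds ``dominance_pct`` (strict) in
    at least one plot, subordinate if it reaches at least ``inclusion_pct``
    somewhere but never exceeds the dominance threshold, excluded otherwise.
    """
    if m.values.empty:
        raise ValidationError("empty cover matrix")
    max_cover = m.values.max(axis=0)
    labels = pd.Series("excluded", index=m.values.columns, dtype=object)
    labels[max_cover >= inclusion_pct] = "subordinate"
    labels[max_cover > dominance_pct] = "dominant"
    return GroupAssignment(
        labels=labels,
        max_cover=max_cover,
        inclusion_pct=inclusion_pct,
        dominance_pct=dominance_pct,
    )


def relative_abundances(m: PercentCoverMatrix, subset) -> pd.DataFrame:
    """Plot × species relative abundances, renormalised within ``subset``.

    Within each plot the covers of the subset species are divided by their
    sum, so proportions sum to 1 wherever any subset species carries cover.
    Plots with zero subset cover get an all-NaN row (undefined, not zero) —
    a plot where the group is absent has no group-level community.
    """
    subset = list(subset)
    if not subset:
        raise ValidationError("empty species subset")
    missing = [s for s in subset if s not in m.values.columns]
    if len(missing) == len(subset):
        raise ValidationError("subset disjoint from cover matrix species")
    if missing:
        raise ValidationError(f"subset species not in cover matrix: {missing}")
    sub = m.values[subset].astype(float)
    totals = sub.sum(axis=1)
    out = sub.div(totals, axis=0)
    out[totals <= 0] = np.nan
    return out
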