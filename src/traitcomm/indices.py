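"""Community-weighted means and Rao quadratic functional diversity.

For a plot with species proportions p_i and trait values x_ij, the
community-weighted mean of trait j is CWM_j = Σ_i p_i x_ij, and per-trait
functional diversity is Rao's quadratic entropy FD = Σ_i Σ_j d_ij p_i p_j
over *all ordered pairs* (d_ii = 0) — the expected trait dissimilarity of
two random draws with replacement.  With d in [0, 1] this bounds FD at 0.5
(two species, p = ½ each, d = 1).  Both are computed separately for the
dominant and the subordinate species group, with plot-wise proportions
renormalised within the group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cover import relative_abundances
from .datatypes import GroupAssignment, PercentCoverMatrix, ValidationError
from .traits import TraitMatrixExpanded, trait_dissimilarity

#: Below this mean resultant length a circular weighted mean is undefined.
CIRCULAR_RESULTANT_TOL = 1e-9


def community_weighted_mean(p, x) -> float:
    """Abundance-weighted mean trait value, Σ p_i·x_i.

    Missing trait values are dropped and the weights renormalised over the
    species that carry a value.
    """
    p = np.asarray(p, dtype=float)
    x = np.asarray(x, dtype=float)
    if p.shape != x.shape:
        raise ValidationError("proportions and trait values must align")
    ok = np.isfinite(x)
    if not ok.any() or p[ok].sum() <= 0:
        raise ValidationError("all trait values missing (or zero weight on non-missing)")
    w = p[ok] / p[ok].sum()
    return float(w @ x[ok])


def circular_weighted_mean(p, angles_deg) -> tuple:
    """Direction of the weighted mean resultant vector, in degrees.

    Returns ``(mean_direction, resultant_length)``; the direction is NaN
    (undefined) when the resultant length is below tolerance, e.g. equal
    weight on antipodal directions.
    """
    p = np.asarray(p, dtype=float)
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if p.shape != a.shape:
        raise ValidationError("proportions and angles must align")
    ok = np.isfinite(a)
    if not ok.any() or p[ok].sum() <= 0:
        raise ValidationError("all angles missing")
    w = p[ok] / p[ok].sum()
    c = float(w @ np.cos(a[ok]))
    s = float(w @ np.sin(a[ok]))
    r = float(np.hypot(c, s))
    if r < CIRCULAR_RESULTANT_TOL:
        return float("nan"), r
    ang = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return (0.0 if ang >= 360.0 else ang), r  # fp rounding can yield exactly 360


def rao_quadratic_diversity(p, D) -> float:
    """Rao's quadratic entropy Σ_ij d_ij p_i p_j over ordered pairs.

    ``D`` may contain NaN for pairs undefined under pairwise deletion; those
    pairs are dropped and the remaining pair weights renormalised (the
    denominator Σ p_i p_j over retained pairs, which is 1 when D is
    complete since the zero diagonal is always retained).
    """
    p = np.asarray(p, dtype=float)
    D = np.asarray(getattr(D, "values", D), dtype=float)
    if D.shape != (p.size, p.size):
        raise ValidationError("dissimilarity matrix must align with proportions")
    W = np.outer(p, p)
    ok = np.isfinite(D)
    denom = W[ok].sum()
    if denom <= 0:
        return 0.0
    return float((D[ok] * W[ok]).sum() / denom)


@dataclass
class GroupFunctionalIndices:
    """CWM and FD matrices for one species group."""

    group: str
    cwm: pd.DataFrame        # plots × expanded trait columns
    fd: pd.DataFrame         # plots × trait groups
    weighting: str


def group_functional_indices(
    m: PercentCoverMatrix,
    tm: TraitMatrixExpanded,
    species,
    group_label: str,
    trait_table=None,
    fd_groups=None,
    range_basis=None,
) -> GroupFunctionalIndices:
    """CWM (all expanded columns) and per-trait-group Rao FD for one group.

    Proportions are renormalised within the group per plot; plots where the
    group is absent yield all-NaN rows.  FD needs the raw typed trait table
    to build per-group dissimilarities; ``range_basis`` (typically all
    retained species) fixes the continuous-trait normalisation scale shared
    between groups.
    """
    species = [s for s in species if s in m.values.columns]
    if not species:
        raise ValidationError(f"group {group_label!r} empty after filtering")
    props = relative_abundances(m, species)

    circular_cols = set()
    if trait_table is not None:
        circular_cols = {
            t.name for t in trait_table.schema if t.type == "circular"
        }

    X = tm.values.loc[species]
    cwm = pd.DataFrame(np.nan, index=props.index, columns=X.columns)
    for plot in props.index:
        p = props.loc[plot].to_numpy()
        if not np.isfinite(p).any():
            continue
        for col in X.columns:
            x = X[col].to_numpy()
            if not np.isfinite(x).any():
                continue
            if col in circular_cols:
                cwm.at[plot, col], _ = circular_weighted_mean(p, x)
            else:
                cwm.at[plot, col] = community_weighted_mean(p, x)

    if trait_table is None:
        fd = pd.DataFrame(index=props.index)
    else:
        groups = list(fd_groups) if fd_groups is not None else trait_table.schema.groups
        fd = pd.DataFrame(np.nan, index=props.index, columns=groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-range traits warn per matrix
            dmats = {
                g: trait_dissimilarity(
                    trait_table, g, subset=species, range_basis=range_basis
                ).values.to_numpy()
                for g in groups
            }
        for plot in props.index:
            p = props.loc[plot].to_numpy()
            if not np.isfinite(p).any():
                continue
            for g in groups:
                fd.at[plot, g] = rao_quadratic_diversity(p, dmats[g])

    return GroupFunctionalIndices(
        group=group_label,
        cwm=cwm,
        fd=fd,
        weighting="group-restricted plot-wise renormalised percent cover",
    )


def build_group_matrices(
    m: PercentCoverMatrix,
    tm: TraitMatrixExpanded,
    g: GroupAssignment,
    trait_table=None,
    fd_groups=None,
):
    """The two CWM and two FD matrices: dominants and subordinates.

    Returns ``(dom_indices, sub_indices)``; continuous-trait dissimilarities
    underlying FD share the pooled (all retained species) range so the two
    groups' FD values are comparable.
    """
    retained = g.species("dominant") + g.species("subordinate")
    dom = group_functional_indices(
        m, tm, g.species("dominant"), "dominant",
        trait_table=trait_table, fd_groups=fd_groups, range_basis=retained,
    )
    sub = group_functional_indices(
        m, tm, g.species("subordinate"), "subordinate",
        trait_table=trait_table, fd_groups=fd_groups, range_basis=retained,
    )
    return dom, sub
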