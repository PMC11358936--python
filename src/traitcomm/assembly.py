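"""Trait convergence/divergence detection via Mantel tests.

For each continuous (or circular) trait within a species group, the
association between the species co-occurrence matrix (how often two
species share plots) and the trait dissimilarity matrix is tested with a
Mantel permutation test.  A significant *negative* correlation means
co-occurring species are more similar than expected — trait convergence
(environmental filtering); a significant *positive* correlation means
co-occurring species are more dissimilar — trait divergence (limiting
similarity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GroupAssignment, PercentCoverMatrix, TraitTable, ValidationError
from .traits import trait_dissimilarity


@dataclass
class CooccurrenceMatrix:
    """Symmetric pairwise species association from presence/absence."""

    values: pd.DataFrame
    method: str
    n_plots: int

    @property
    def species_ids(self) -> list:
        return list(self.values.index)


def cooccurrence_matrix(
    m: PercentCoverMatrix, subset=None, method: str = "jaccard"
) -> CooccurrenceMatrix:
    """Pairwise presence/absence association between species.

    ``jaccard``: |plots with both| / |plots with either|, in [0, 1].
    ``phi``: the 2×2 presence-absence (Pearson) correlation, in [-1, 1].
    Presence follows the recorded observation, so a species at 0 % cover
    (Braun-Blanquet ``r``) counts as present.  Species present nowhere (or,
    for phi, everywhere) have undefined associations, flagged NaN.
    """
    species = list(subset) if subset is not None else list(m.values.columns)
    if len(species) < 2:
        raise ValidationError("need at least 2 species")
    P = m.presence[species].to_numpy(dtype=float)
    n_plots = P.shape[0]
    if n_plots < 2:
        raise ValidationError("need at least 2 plots")

    both = P.T @ P
    occ = P.sum(axis=0)
    if method == "jaccard":
        either = occ[:, None] + occ[None, :] - both
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(either > 0, both / np.where(either > 0, either, 1), np.nan)
        np.fill_diagonal(A, 1.0)
        A[occ == 0, :] = np.nan
        A[:, occ == 0] = np.nan
    elif method == "phi":
        a = both
        b = occ[:, None] - both
        c = occ[None, :] - both
        d = n_plots - a - b - c
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
            A = np.where(denom > 0, (a * d - b * c) / np.where(denom > 0, denom, 1), np.nan)
        np.fill_diagonal(A, 1.0)
    else:
        raise ValidationError(f"unknown co-occurrence method {method!r}")
    df = pd.DataFrame(A, index=species, columns=species)
    return CooccurrenceMatrix(values=df, method=method, n_plots=n_plots)


@dataclass
class MantelResult:
    trait_group: str
    r: float
    p_value: float
    n_permutations: int
    tail: str
    classification: str  # 'convergence' | 'divergence' | 'none'
    n_species: int


def mantel_test(
    A,
    B,
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "two_sided",
    alpha: float = 0.05,
    trait_group: str = "",
) -> MantelResult:
    """Mantel permutation test between two square symmetric matrices.

    r is the Pearson correlation of the upper-triangle vectors; the null is
    generated by simultaneous row/column permutation of ``B``.  Pairs where
    either matrix is NaN are dropped (and the same pair mask applied to
    every permutation).  Classification: convergence iff r < 0 and
    p ≤ alpha, divergence iff r > 0 and p ≤ alpha, else none.
    """
    Ma = np.asarray(getattr(A, "values", A), dtype=float)
    Mb = np.asarray(getattr(B, "values", B), dtype=float)
    if Ma.shape != Mb.shape or Ma.ndim != 2 or Ma.shape[0] != Ma.shape[1]:
        raise ValidationError("matrices must be square and of equal shape")
    ia, ib = getattr(A, "index", None), getattr(B, "index", None)
    if ia is not None and ib is not None and not ia.equals(ib):
        raise ValidationError("matrices must share species ordering")
    n = Ma.shape[0]
    iu = np.triu_indices(n, k=1)
    a = Ma[iu]
    ok_a = np.isfinite(a)

    def triangle_r(Mb_perm):
        b = Mb_perm[iu]
        ok = ok_a & np.isfinite(b)
        if ok.sum() < 3:
            return np.nan
        av, bv = a[ok], b[ok]
        if av.std() == 0 or bv.std() == 0:
            return np.nan
        return float(np.corrcoef(av, bv)[0, 1])

    r = triangle_r(Mb)
    if not np.isfinite(r):
        raise ValidationError(
            "Mantel r undefined (fewer than 3 complete pairs or zero variance)"
        )
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = triangle_r(Mb[np.ix_(perm, perm)])
        if not np.isfinite(rp):
            continue
        if tail == "two_sided":
            hit = abs(rp) >= abs(r)
        elif tail == "negative":
            hit = rp <= r
        elif tail == "positive":
            hit = rp >= r
        else:
            raise ValidationError(f"unknown tail {tail!r}")
        if hit:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    if p <= alpha and r < 0:
        cls = "convergence"
    elif p <= alpha and r > 0:
        cls = "divergence"
    else:
        cls = "none"
    return MantelResult(
        trait_group=trait_group,
        r=r,
        p_value=p,
        n_permutations=n_perm,
        tail=tail,
        classification=cls,
        n_species=n,
    )


def convergence_divergence_scan(
    m: PercentCoverMatrix,
    t: TraitTable,
    g: GroupAssignment,
    group: str,
    traits=None,
    method: str = "jaccard",
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    range_basis=None,
) -> pd.DataFrame:
    """Mantel scan over continuous/circular traits within one species group.

    One row per trait: Mantel r between the group's co-occurrence matrix
    and that trait's dissimilarity matrix, permutation p, and the sign-based
    convergence/divergence call at ``alpha``.  Per-trait failures (e.g. a
    zero-variance trait) are flagged in the ``error`` column and the scan
    continues.
    """
    species = g.species(group)
    if len(species) < 3:
        raise ValidationError(f"group {group!r} has fewer than 3 species")
    if traits is None:
        traits = [s.name for s in t.schema.continuous_like_traits()]
    co = cooccurrence_matrix(m, subset=species, method=method)
    rows = []
    for i, trait in enumerate(traits):
        row = {
            "trait": trait, "r": np.nan, "p_value": np.nan,
            "classification": "error", "n_permutations": n_perm,
            "method": method, "error": "",
        }
        try:
            spec = t.schema[trait]
            if spec.type not in ("continuous", "circular"):
                raise ValidationError(f"trait {trait!r} is not continuous/circular")
            D = trait_dissimilarity(t, spec.group, subset=species, range_basis=range_basis)
            res = mantel_test(
                co.values, D.values, n_perm=n_perm,
                seed=seed + i,  # independent permutation stream per trait
                tail="two_sided", alpha=alpha, trait_group=spec.group,
            )
            row.update(
                r=res.r, p_value=res.p_value, classification=res.classification,
            )
        except (ValidationError, KeyError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")
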