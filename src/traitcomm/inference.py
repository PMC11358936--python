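"""Group-comparison statistics: PERMANOVA, beta-dispersion, t-tests, PCA.

PERMANOVA partitions the sum of squared inter-point distances into within-
and between-group components and tests the pseudo-F ratio by permuting
group labels.  Beta-dispersion embeds the distance matrix by principal
coordinates, measures each observation's distance to its own group
centroid (with the standard correction subtracting squared distances along
negative-eigenvalue axes), and compares mean dispersions with a one-way F
test, both classical and permutational.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError


def _as_distance_array(D) -> np.ndarray:
    A = np.asarray(getattr(D, "values", D), dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(A), 0.0, atol=1e-10):
        raise ValidationError("distance matrix must have zero diagonal")
    return A


def _check_groups(groups) -> np.ndarray:
    g = np.asarray(groups)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    if counts.min() < 2:
        raise ValidationError(
            "insufficient replication: every group needs at least 2 members"
        )
    return g


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    ss_total: float
    ss_within: float
    ss_between: float
    df_between: int
    df_within: int


def _permanova_F(D2: np.ndarray, g: np.ndarray):
    """Pseudo-F from the squared-distance matrix and labels.

    SS_total = Σ_{i<j} d²_ij / n; SS_within sums each group's i<j squared
    distances divided by group size.
    """
    n = D2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = D2[iu].sum() / n
    ss_within = 0.0
    labels = np.unique(g)
    for lab in labels:
        idx = np.flatnonzero(g == lab)
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(labels)
    df_b, df_w = a - 1, n - a
    F = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
    return F, ss_total, ss_within, ss_between, df_b, df_w


def permanova(D, groups, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with label permutation.

    p = (1 + #{permuted F ≥ observed F}) / (1 + n_perm).
    """
    A = _as_distance_array(D)
    g = _check_groups(groups)
    if len(g) != A.shape[0]:
        raise ValidationError("labels must match distance matrix size")
    D2 = A**2
    F, sst, ssw, ssb, df_b, df_w = _permanova_F(D2, g)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        gp = rng.permutation(g)
        Fp = _permanova_F(D2, gp)[0]
        if Fp >= F:
            exceed += 1
    return PermanovaResult(
        pseudo_F=float(F),
        p_value=(1 + exceed) / (1 + n_perm),
        n_permutations=n_perm,
        ss_total=float(sst),
        ss_within=float(ssw),
        ss_between=float(ssb),
        df_between=df_b,
        df_within=df_w,
    )


@dataclass
class DispersionResult:
    distances: pd.Series      # observation -> distance to own-group centroid
    F: float
    p_classical: float
    p_permutation: float
    n_permutations: int


def _pcoa_embedding(A: np.ndarray):
    """Principal-coordinate axes of a distance matrix.

    Returns (real_coords, imag_coords): axes with positive eigenvalues and,
    separately, axes with negative eigenvalues (non-Euclidean part), whose
    squared contributions are *subtracted* from squared distances.
    """
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (A**2) @ J
    w, V = np.linalg.eigh((G + G.T) / 2)
    tol = 1e-8 * max(1.0, np.abs(w).max())
    pos = w > tol
    neg = w < -tol
    real = V[:, pos] * np.sqrt(w[pos])
    imag = V[:, neg] * np.sqrt(-w[neg])
    return real, imag


def _centroid_distances(real, imag, g) -> np.ndarray:
    d2 = np.zeros(len(g))
    for lab in np.unique(g):
        idx = np.flatnonzero(g == lab)
        cr = real[idx].mean(axis=0)
        ci = imag[idx].mean(axis=0) if imag.size else np.zeros(imag.shape[1])
        d2[idx] = ((real[idx] - cr) ** 2).sum(axis=1)
        if imag.size:
            d2[idx] -= ((imag[idx] - ci) ** 2).sum(axis=1)
    return np.sqrt(np.clip(d2, 0.0, None))


def beta_dispersion(D, groups, n_perm: int = 999, seed: int = 0) -> DispersionResult:
    """Multivariate homogeneity of group dispersions (betadisper-style).

    Distances to own-group centroids in the principal-coordinate embedding;
    one-way ANOVA F on those distances, with both the classical F p-value
    and a permutation p-value (permuting distances across groups).
    """
    A = _as_distance_array(D)
    g = _check_groups(groups)
    if len(g) != A.shape[0]:
        raise ValidationError("labels must match distance matrix size")
    real, imag = _pcoa_embedding(A)
    d = _centroid_distances(real, imag, g)

    labels = np.unique(g)
    samples = [d[g == lab] for lab in labels]
    if all(np.ptp(s) == 0 for s in samples) and len(set(s[0] for s in samples)) == 1:
        F, p_classical = 0.0, 1.0
    else:
        F, p_classical = stats.f_oneway(*samples)
        F, p_classical = float(F), float(p_classical)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        gp = rng.permutation(g)
        sp = [d[gp == lab] for lab in labels]
        num = sum(len(s) * (s.mean() - d.mean()) ** 2 for s in sp) / (len(labels) - 1)
        den = sum(((s - s.mean()) ** 2).sum() for s in sp) / (len(d) - len(labels))
        Fp = num / den if den > 0 else np.inf
        if Fp >= F:
            exceed += 1
    index = getattr(D, "index", pd.RangeIndex(len(d)))
    return DispersionResult(
        distances=pd.Series(d, index=index),
        F=F,
        p_classical=p_classical,
        p_permutation=(1 + exceed) / (1 + n_perm),
        n_permutations=n_perm,
    )


def per_trait_t_tests(
    cwm_dom: pd.DataFrame,
    cwm_sub: pd.DataFrame,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Independent two-sample t-test per shared trait column.

    Plots with missing CWM (group absent) are dropped per column.  Constant
    columns in both groups with equal means are flagged ``undefined`` rather
    than propagating NaN.  Student's t by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    shared = [c for c in cwm_dom.columns if c in cwm_sub.columns]
    if not shared:
        raise ValidationError("no shared trait columns")
    rows = []
    for col in shared:
        a = cwm_dom[col].dropna().to_numpy()
        b = cwm_sub[col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(
                f"insufficient replication for trait {col!r}: "
                f"{len(a)} vs {len(b)} non-missing plots"
            )
        undefined = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
        if undefined and a.mean() == b.mean():
            t, p, df = 0.0, 1.0, len(a) + len(b) - 2
        elif undefined:
            t, p, df = np.nan, np.nan, len(a) + len(b) - 2
        else:
            import warnings

            with warnings.catch_warnings():
                # near-constant indicator CWMs trip scipy's precision-loss
                # warning; the permutation-free t is still well defined
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(a, b, equal_var=not welch)
            t, p = float(res.statistic), float(res.pvalue)
            df = float(res.df) if welch else len(a) + len(b) - 2
        rows.append(
            {
                "trait": col,
                "mean_dominant": a.mean(),
                "mean_subordinate": b.mean(),
                "t": t,
                "df": df,
                "p_value": p,
                "significant": bool(np.isfinite(p) and p <= alpha),
                "undefined": bool(undefined and a.mean() != b.mean()),
                "n_dominant_plots": len(a),
                "n_subordinate_plots": len(b),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def pca_scores(X, n_components=None, standardize: bool = True) -> PCAResult:
    """PCA by singular value decomposition of the centred (and by default
    standardised, i.e. correlation-matrix) data.

    Standardisation is the sensible default here because expanded trait
    columns mix scales (indicator fractions, mm²/mg, months ...).
    """
    Xdf = pd.DataFrame(X)
    M = Xdf.to_numpy(dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValidationError("PCA input must be complete (drop missing rows first)")
    sd = M.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValidationError("all columns constant")
    M = M - M.mean(axis=0)
    if standardize:
        keep = sd > 0
        if not keep.all():
            Xdf = Xdf.loc[:, keep]
            M = M[:, keep]
            sd = sd[keep]
        M = M / sd
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    k = n_components or min(M.shape)
    var = S**2 / (M.shape[0] - 1)
    comps = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame((U * S)[:, :k], index=Xdf.index, columns=comps),
        loadings=pd.DataFrame(Vt[:k].T, index=Xdf.columns, columns=comps),
        explained_variance=var[:k],
        explained_variance_ratio=(var / var.sum())[:k],
    )
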