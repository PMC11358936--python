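"""End-to-end pipeline: classify → CWM/FD → group comparison → Mantel scan.

The full run is a pure function of (inputs, config including seed): all
statistical tables are written as labelled CSV with no timestamps, so two
runs with identical config produce byte-identical outputs.  A ``run_log.txt``
echoes every effective threshold, seed and permutation count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .assembly import convergence_divergence_scan
from .cover import classify_species, to_percent
from .datatypes import AnalysisConfig, CoverMatrix, TraitTable, ValidationError
from .indices import build_group_matrices
from .inference import beta_dispersion, pca_scores, per_trait_t_tests, permanova
from .traits import expand_traits

log = logging.getLogger("traitcomm")

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, float_format=_FLOAT_FMT, index_label=index_label)


def stacked_cwm(cwm_dom: pd.DataFrame, cwm_sub: pd.DataFrame):
    """Stack the two group CWM matrices into one observation table.

    Each relevé contributes (up to) two observations — its dominant-group
    CWM profile and its subordinate-group CWM profile — with the species
    group as the factor.  Rows with any missing column (group absent from
    the plot, or an undefined circular mean) are dropped with a log note.
    """
    shared = [c for c in cwm_dom.columns if c in cwm_sub.columns]
    dom = cwm_dom[shared].dropna()
    sub = cwm_sub[shared].dropna()
    n_drop = (len(cwm_dom) - len(dom)) + (len(cwm_sub) - len(sub))
    if n_drop:
        log.info("stacked CWM: dropped %d incomplete group-plot rows", n_drop)
    X = pd.concat(
        [
            dom.set_index(pd.Index([f"D:{p}" for p in dom.index])),
            sub.set_index(pd.Index([f"S:{p}" for p in sub.index])),
        ]
    )
    groups = np.array(["dominant"] * len(dom) + ["subordinate"] * len(sub))
    return X, groups


def run_pipeline(
    cover: CoverMatrix,
    traits: TraitTable,
    config: AnalysisConfig,
    out_dir,
) -> dict:
    """Run every stage and write the result bundle under ``out_dir``.

    Returns a dict of the in-memory results keyed by stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    stage = "classify"
    try:
        pct = to_percent(cover)
        assignment = classify_species(
            pct, config.inclusion_threshold_pct, config.dominance_threshold_pct
        )
        results["assignment"] = assignment
        tbl = pd.DataFrame(
            {"max_cover_pct": assignment.max_cover, "label": assignment.labels}
        )
        _write(tbl, out / "group_assignment.csv", "species")

        stage = "functional_indices"
        retained = assignment.species("dominant") + assignment.species("subordinate")
        tm = expand_traits(traits)
        dom, sub = build_group_matrices(pct, tm, assignment, trait_table=traits)
        results["dom"], results["sub"] = dom, sub
        _write(dom.cwm, out / "cwm_dominant.csv", "plot")
        _write(sub.cwm, out / "cwm_subordinate.csv", "plot")
        _write(dom.fd, out / "fd_dominant.csv", "plot")
        _write(sub.fd, out / "fd_subordinate.csv", "plot")

        stage = "inference"
        X, groups = stacked_cwm(dom.cwm, sub.cwm)
        D = squareform(pdist(X.to_numpy(), metric="euclidean"))
        Ddf = pd.DataFrame(D, index=X.index, columns=X.index)
        perm = permanova(Ddf, groups, n_perm=config.n_permutations, seed=config.rng_seed)
        disp = beta_dispersion(
            Ddf, groups, n_perm=config.n_permutations, seed=config.rng_seed + 1
        )
        ttab = per_trait_t_tests(dom.cwm, sub.cwm, alpha=config.alpha, welch=config.welch)
        results["permanova"], results["dispersion"], results["t_tests"] = perm, disp, ttab
        _write(
            pd.DataFrame(
                {
                    "pseudo_F": [perm.pseudo_F],
                    "p_value": [perm.p_value],
                    "n_permutations": [perm.n_permutations],
                    "ss_total": [perm.ss_total],
                    "ss_within": [perm.ss_within],
                    "ss_between": [perm.ss_between],
                }
            ),
            out / "permanova.csv",
            "row",
        )
        _write(
            pd.DataFrame(
                {
                    "F": [disp.F],
                    "p_classical": [disp.p_classical],
                    "p_permutation": [disp.p_permutation],
                    "n_permutations": [disp.n_permutations],
                }
            ),
            out / "beta_dispersion.csv",
            "row",
        )
        _write(ttab, out / "cwm_t_tests.csv", "trait")

        sig = ttab.index[ttab["significant"]].tolist()
        if len(sig) >= 2:
            pca = pca_scores(X[sig], standardize=config.standardize_pca)
            results["pca"] = pca
            _write(pca.scores, out / "pca_scores.csv", "observation")
            _write(pca.loadings, out / "pca_loadings.csv", "trait")

        stage = "assembly"
        scans = {}
        for group in ("dominant", "subordinate"):
            scans[group] = convergence_divergence_scan(
                pct,
                traits,
                assignment,
                group,
                method=config.cooccurrence_method,
                n_perm=config.n_permutations,
                seed=config.rng_seed + (2 if group == "dominant" else 100),
                alpha=config.alpha,
                range_basis=retained,
            )
            _write(scans[group], out / f"mantel_{group}.csv", "trait")
        results["mantel"] = scans
    except Exception as exc:
        raise ValidationError(f"pipeline stage {stage!r}: {exc}") from exc

    with open(out / "run_log.txt", "w") as fh:
        fh.write("traitcomm pipeline run\n")
        fh.write(f"inclusion_threshold_pct = {config.inclusion_threshold_pct}\n")
        fh.write(f"dominance_threshold_pct = {config.dominance_threshold_pct}\n")
        fh.write(f"n_permutations = {config.n_permutations}\n")
        fh.write(f"rng_seed = {config.rng_seed}\n")
        fh.write(f"cooccurrence_method = {config.cooccurrence_method}\n")
        fh.write(f"alpha = {config.alpha}\n")
        fh.write(f"welch = {config.welch}\n")
        fh.write(f"n_plots = {len(cover.plot_ids)}\n")
        fh.write(f"n_species = {len(cover.species_ids)}\n")
        fh.write(f"group_counts = {assignment.counts}\n")
    return results
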