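"""Synthetic dry-grassland relevé generator with planted assembly structure.

Emulates the statistical shape of a semi-natural dry grassland survey:
~35 relevés over a ~100-species pool with mean richness ~38 species/plot,
a small set of high-cover clonal, stress-tolerant dominant species with
narrow trait distributions, and a large set of low-cover subordinates with
wide trait distributions.  Two assembly mechanisms are planted in the
subordinate layer and are recoverable by the downstream Mantel scan:

* **environmental filtering (convergence)** on one trait — each plot draws
  a latent optimum and a species' admission probability decays
  exponentially with its trait distance to the optimum;
* **limiting similarity (divergence)** on another trait — species enter a
  plot sequentially in random order and a candidate too close to any
  resident on that trait is rejected.

Cover codes are drawn per occurrence: dominants from {2, 3, 4} (and each
dominant is guaranteed one code ≥ 3 somewhere), subordinates from
{+, 1, 2} with a guaranteed code ≥ 1 somewhere — so the 1 % / 25 %
classifier recovers the planted groups exactly, by construction.
Everything is a pure function of the config (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CoverMatrix, TraitTable, ValidationError
from .schema import default_schema
from .traits import circular_distance


def _default_trait_params() -> dict:
    """Group-specific trait distributions.

    Dominants: tall, high-LDMC / low-SLA stress tolerators, long flowering,
    clonal with rhizomes and a deep bud bank, narrow spread of values.
    Subordinates: wider distributions, more ruderal, more varied life and
    growth forms.  Continuous entries are (mean, sd, min, max) truncation
    bounds; categorical entries are class probabilities in schema order;
    F_start is (mean_deg, kappa) of a von Mises, or None for uniform.
    """
    return {
        "dominant": {
            "P_height": (45.0, 6.0, 5.0, 150.0),
            "SLA": (14.0, 2.0, 2.0, 60.0),
            "LDMC": (280.0, 20.0, 50.0, 500.0),
            "F_length": (4.5, 0.6, 1.0, 8.0),
            "Persist_CGO": (2.5, 0.4, 0.0, 10.0),
            "NoCloSh": (6.5, 0.8, 0.0, 12.0),
            "Lat_spread": (0.08, 0.02, 0.0, 2.0),
            "F_start": (150.0, 8.0),
            "C": (0.30, 0.04, 0.0, 1.0),
            "S": (0.55, 0.04, 0.0, 1.0),
            "R": (0.15, 0.03, 0.0, 1.0),
            # life form: ch, ge, he, th
            "life_form": (0.02, 0.02, 0.94, 0.02),
            # growth form: tuss, rose, le_st, ro_le
            "growth_form": (0.70, 0.10, 0.10, 0.10),
            # CGO: stolon, epi rhizome, hypo rhizome, stem tuber, bulb,
            #      root splitter, root adv. buds, root tuber
            "CGO_type": (0.15, 0.40, 0.35, 0.02, 0.02, 0.02, 0.02, 0.02),
            "CGO_role": (0.20, 0.60, 0.15, 0.05),
            "bud_bank": (0.05, 0.15, 0.20, 0.60),
        },
        "subordinate": {
            "P_height": (30.0, 15.0, 5.0, 150.0),
            "SLA": (24.0, 7.0, 2.0, 60.0),
            "LDMC": (190.0, 55.0, 50.0, 500.0),
            "F_length": (3.0, 1.2, 1.0, 8.0),
            "Persist_CGO": (1.2, 0.9, 0.0, 10.0),
            "NoCloSh": (5.0, 2.6, 1.0, 10.0),
            "Lat_spread": (0.25, 0.18, 0.0, 2.0),
            "F_start": None,  # uniform around the year
            "C": (0.30, 0.10, 0.0, 1.0),
            "S": (0.35, 0.10, 0.0, 1.0),
            "R": (0.35, 0.10, 0.0, 1.0),
            "life_form": (0.15, 0.15, 0.50, 0.20),
            "growth_form": (0.10, 0.30, 0.30, 0.30),
            "CGO_type": (0.10, 0.15, 0.15, 0.12, 0.08, 0.15, 0.13, 0.12),
            "CGO_role": (0.35, 0.15, 0.30, 0.20),
            "bud_bank": (0.25, 0.30, 0.25, 0.20),
        },
    }


@dataclass
class SimulationConfig:
    """Study-design knobs of the generator; defaults are the study conditions."""

    n_plots: int = 35
    n_dominants: int = 8
    n_subordinates: int = 93          # pool; thinned by realised occupancy
    target_mean_richness: float = 38.0
    richness_sd: float = 4.0
    dominant_presence_prob: float = 0.85
    dominant_code_probs: dict = field(
        default_factory=lambda: {"2": 0.35, "3": 0.45, "4": 0.20}
    )
    subordinate_code_probs: dict = field(
        default_factory=lambda: {"+": 0.30, "1": 0.50, "2": 0.20}
    )
    convergence_trait: str = "F_start"
    filtering_strength: float = 3.0   # decay rate of admission prob with distance
    divergence_trait: str = "NoCloSh"
    min_separation: float = 0.15      # trait units; 0 disables
    trait_params: dict = field(default_factory=_default_trait_params)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_plots, self.n_dominants, self.n_subordinates) <= 0:
            raise ValidationError("counts must be positive")
        if self.filtering_strength < 0 or self.min_separation < 0:
            raise ValidationError("mechanism strengths must be >= 0")
        for dist in (self.dominant_code_probs, self.subordinate_code_probs):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValidationError("cover-code distribution must sum to 1")
        if self.target_mean_richness > self.n_dominants + self.n_subordinates:
            raise ValidationError(
                "infeasible config: richness target exceeds the species pool"
            )


def _truncnorm(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    while bad.any():  # resample, preserving the distribution's shape inside bounds
        x[bad] = rng.normal(mean, sd, bad.sum())
        bad = (x < lo) | (x > hi)
    return x


def _draw_traits(cfg: SimulationConfig, rng) -> pd.DataFrame:
    schema = default_schema()
    species = [f"dom{i + 1:02d}" for i in range(cfg.n_dominants)] + [
        f"sub{i + 1:03d}" for i in range(cfg.n_subordinates)
    ]
    rows = {}
    for group, count in (("dominant", cfg.n_dominants), ("subordinate", cfg.n_subordinates)):
        pars = cfg.trait_params[group]
        cols = {}
        for spec in schema:
            p = pars[spec.name]
            if spec.type == "categorical":
                idx = rng.choice(len(spec.classes), size=count, p=np.asarray(p) / np.sum(p))
                cols[spec.name] = [spec.classes[i] for i in idx]
            elif spec.type == "circular":
                if p is None:
                    cols[spec.name] = rng.uniform(0.0, 360.0, count)
                else:
                    mu, kappa = p
                    ang = np.degrees(rng.vonmises(np.radians(mu - 180.0), kappa, count))
                    cols[spec.name] = (ang + 180.0) % 360.0
            else:
                mean, sd, lo, hi = p
                cols[spec.name] = _truncnorm(rng, mean, sd, lo, hi, count)
        rows[group] = pd.DataFrame(cols)
    df = pd.concat([rows["dominant"], rows["subordinate"]], ignore_index=True)
    df.index = pd.Index(species, name="species")
    return df


def _admission(cfg: SimulationConfig, traits: pd.DataFrame, rng) -> pd.DataFrame:
    """Plot × subordinate presence from the two planted mechanisms."""
    subs = [s for s in traits.index if s.startswith("sub")]
    conv = traits[cfg.convergence_trait]
    div = traits[cfg.divergence_trait]
    conv_spec = default_schema()[cfg.convergence_trait]
    if conv_spec.type == "circular":
        conv_scale = 180.0
    else:
        conv_scale = float(conv.max() - conv.min()) or 1.0

    pres = pd.DataFrame(False, index=[f"plot{i + 1:02d}" for i in range(cfg.n_plots)], columns=subs)
    sub_target_mean = cfg.target_mean_richness - cfg.n_dominants * cfg.dominant_presence_prob
    for plot in pres.index:
        target = int(np.clip(round(rng.normal(sub_target_mean, cfg.richness_sd)), 1, len(subs)))
        if conv_spec.type == "circular":
            optimum = rng.uniform(0.0, 360.0)
        else:
            optimum = rng.uniform(conv.min(), conv.max())
        # environmental filtering: admission odds decay with distance to the
        # plot optimum; candidates are visited in weighted random order
        # (Gumbel keys = weighted sampling without replacement), so strength 0
        # reduces to a uniform permutation
        if conv_spec.type == "circular":
            d = np.array([circular_distance(conv[sp], optimum) for sp in subs]) / conv_scale
        else:
            d = np.abs(conv.loc[subs].to_numpy() - optimum) / conv_scale
        keys = -cfg.filtering_strength * d + rng.gumbel(size=len(subs))
        order = [subs[i] for i in np.argsort(-keys)]

        residents = []
        res_div = []
        for sp in order:
            if len(residents) >= target:
                break
            # limiting similarity: too close to a resident on the divergence trait
            if cfg.min_separation > 0 and any(
                abs(div[sp] - v) < cfg.min_separation for v in res_div
            ):
                continue
            residents.append(sp)
            res_div.append(div[sp])
        pres.loc[plot, residents] = True
    return pres


def _draw_codes(rng, dist: dict, size: int) -> np.ndarray:
    codes = list(dist.keys())
    return rng.choice(codes, size=size, p=[dist[c] for c in codes])


def generate_community(cfg: SimulationConfig):
    """Generate (CoverMatrix, TraitTable, ground_truth) for one seed.

    The ground-truth record lists the planted label of every retained
    species, the planted convergence/divergence traits and mechanism
    strengths, and the realised per-plot richness.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    traits = _draw_traits(cfg, rng)
    doms = [s for s in traits.index if s.startswith("dom")]
    plots = [f"plot{i + 1:02d}" for i in range(cfg.n_plots)]

    sub_pres = _admission(cfg, traits, rng)
    codes = pd.DataFrame(np.nan, index=plots, columns=list(traits.index), dtype=object)

    # dominants: present with high probability, codes over {2,3,4}
    for sp in doms:
        present = rng.random(cfg.n_plots) < cfg.dominant_presence_prob
        if not present.any():
            present[rng.integers(cfg.n_plots)] = True
        drawn = _draw_codes(rng, cfg.dominant_code_probs, int(present.sum()))
        codes.loc[np.array(plots)[present], sp] = drawn
        # guarantee the dominance criterion (code >= 3 somewhere)
        col = codes[sp]
        if not col.isin(["3", "4", "5"]).any():
            where = col.index[col.notna()]
            codes.at[where[rng.integers(len(where))], sp] = "3"

    # subordinates: codes over {+,1,2}; guarantee inclusion (code >= 1 somewhere)
    for sp in sub_pres.columns:
        present = sub_pres[sp].to_numpy()
        if not present.any():
            continue  # thinned by occupancy
        drawn = _draw_codes(rng, cfg.subordinate_code_probs, int(present.sum()))
        codes.loc[np.array(plots)[present], sp] = drawn
        col = codes[sp]
        if not col.isin(["1", "2"]).any():
            where = col.index[col.notna()]
            codes.at[where[rng.integers(len(where))], sp] = "1"

    retained = [sp for sp in codes.columns if codes[sp].notna().any()]
    codes = codes[retained]
    cover = CoverMatrix(values=codes, scale_kind="braun_blanquet")
    trait_table = TraitTable(values=traits.loc[retained], schema=default_schema())

    richness = codes.notna().sum(axis=1)
    ground_truth = {
        "labels": {
            sp: ("dominant" if sp.startswith("dom") else "subordinate")
            for sp in retained
        },
        "convergence_trait": cfg.convergence_trait,
        "divergence_trait": cfg.divergence_trait,
        "filtering_strength": cfg.filtering_strength,
        "min_separation": cfg.min_separation,
        "rng_seed": cfg.rng_seed,
        "n_species_retained": len(retained),
        "mean_richness": float(richness.mean()),
    }
    return cover, trait_table, ground_truth
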