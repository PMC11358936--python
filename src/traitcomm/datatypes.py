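"""Core domain types for relevé (vegetation-plot) community data.

A relevé table records species cover in fixed plots, either on the
seven-point Braun-Blanquet cover-abundance scale (``r``, ``+``, ``1`` … ``5``)
or directly as percent cover.  A trait table describes the species pool with
typed plant functional traits (categorical, continuous or circular).  The
classes here are thin, validated wrappers around :class:`pandas.DataFrame`
so every downstream computation stays label-keyed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven-point Braun-Blanquet cover-abundance alphabet.
BB_ALPHABET = ("r", "+", "1", "2", "3", "4", "5")

#: Van der Maarel midpoint conversion of Braun-Blanquet codes to percent cover.
#: ``r`` converts to 0 % but still counts as a presence.
BB_TO_PERCENT = {
    "r": 0.0,
    "+": 0.1,
    "1": 5.0,
    "2": 17.5,
    "3": 37.5,
    "4": 62.5,
    "5": 87.5,
}

#: Separator for multi-state categorical trait values (e.g. a species with
#: two clonal growth organ types is coded ``"CGO9|CGO10"``).
MULTI_STATE_SEP = "|"

TRAIT_TYPES = ("categorical", "continuous", "circular")


class ValidationError(ValueError):
    """Raised when an input table violates a domain invariant."""


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} labels: {dupes}")


@dataclass
class CoverMatrix:
    """Plots × species cover observations on a single scale.

    ``values`` holds Braun-Blanquet code strings (``scale_kind='braun_blanquet'``)
    or floats in [0, 100] (``scale_kind='percent'``); absent cells are NaN/None —
    absence is *not* the same as the code ``r`` (presence at 0 % cover).
    """

    values: pd.DataFrame
    scale_kind: str  # 'braun_blanquet' | 'percent'

    def __post_init__(self) -> None:
        if self.scale_kind not in ("braun_blanquet", "percent"):
            raise ValidationError(f"unknown scale_kind {self.scale_kind!r}")
        _check_unique(self.values.index, "plot")
        _check_unique(self.values.columns, "species")
        if self.scale_kind == "braun_blanquet":
            for plot in self.values.index:
                for sp in self.values.columns:
                    cell = self.values.at[plot, sp]
                    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                        continue
                    if str(cell) not in BB_ALPHABET:
                        raise ValidationError(
                            f"unknown Braun-Blanquet code {cell!r} at "
                            f"(plot={plot!r}, species={sp!r})"
                        )
        else:
            vals = self.values.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 100):
                bad = np.argwhere((vals < 0) | (vals > 100))
                plot, sp = self.values.index[bad[0][0]], self.values.columns[bad[0][1]]
                raise ValidationError(
                    f"percent cover outside [0, 100] at (plot={plot!r}, species={sp!r})"
                )

    @property
    def plot_ids(self) -> list:
        return list(self.values.index)

    @property
    def species_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class PercentCoverMatrix:
    """Plots × species percent cover with an explicit presence mask.

    The mask distinguishes a recorded species at 0 % cover (Braun-Blanquet
    ``r``) from true absence, which matters for co-occurrence analysis.
    """

    values: pd.DataFrame   # float, 0.0 where absent or recorded at 0 %
    presence: pd.DataFrame  # bool

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.presence.index) or not self.values.columns.equals(
            self.presence.columns
        ):
            raise ValidationError("values and presence must share labels")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("percent matrix must be finite (absence is 0 + mask)")
        if vals.min() < 0 or vals.max() > 100:
            raise ValidationError("percent cover outside [0, 100]")
        if ((vals > 0) & ~self.presence.to_numpy(dtype=bool)).any():
            raise ValidationError("positive cover recorded for an absent species")

    @property
    def plot_ids(self) -> list:
        return list(self.values.index)

    @property
    def species_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class TraitSpec:
    """Declaration of one trait: its type, classes (if categorical) and units.

    ``group`` names the trait group used for per-group dissimilarity and FD;
    it defaults to the trait's own name (the CSR components C, S, R keep
    their own groups so each strategy axis gets its own FD index).
    """

    name: str
    type: str
    classes: tuple = ()
    unit: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.type not in TRAIT_TYPES:
            raise ValidationError(f"trait {self.name!r}: unknown type {self.type!r}")
        if self.type == "categorical" and not self.classes:
            raise ValidationError(f"categorical trait {self.name!r} declares no classes")
        self.classes = tuple(self.classes)
        if not self.group:
            self.group = self.name

    @property
    def expanded_columns(self) -> list:
        """Column labels this trait contributes to the expanded numeric matrix."""
        if self.type == "categorical":
            return list(self.classes)
        return [self.name]


@dataclass
class TraitSchema:
    """Ordered declaration of all traits in a trait table."""

    traits: list  # list[TraitSpec]

    def __post_init__(self) -> None:
        _check_unique([t.name for t in self.traits], "trait")
        cols = self.expanded_columns
        _check_unique(cols, "expanded trait column")

    def __iter__(self):
        return iter(self.traits)

    def __getitem__(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [t.name for t in self.traits]

    @property
    def expanded_columns(self) -> list:
        out = []
        for t in self.traits:
            out.extend(t.expanded_columns)
        return out

    @property
    def groups(self) -> list:
        """Distinct trait groups in schema order."""
        seen, out = set(), []
        for t in self.traits:
            if t.group not in seen:
                seen.add(t.group)
                out.append(t.group)
        return out

    def traits_in_group(self, group: str) -> list:
        found = [t for t in self.traits if t.group == group]
        if not found:
            raise KeyError(f"unknown trait group {group!r}")
        return found

    def continuous_like_traits(self) -> list:
        """Continuous and circular traits (the scan candidates)."""
        return [t for t in self.traits if t.type in ("continuous", "circular")]


@dataclass
class TraitTable:
    """Species × traits values, typed by a :class:`TraitSchema`.

    Missing values are NaN (continuous/circular) or NaN/empty (categorical).
    Categorical cells are class labels, optionally multi-state joined by ``|``.
    """

    values: pd.DataFrame
    schema: TraitSchema

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "species")
        missing_cols = [n for n in self.schema.names if n not in self.values.columns]
        if missing_cols:
            raise ValidationError(f"trait columns missing from table: {missing_cols}")
        for spec in self.schema:
            col = self.values[spec.name]
            for sp, cell in col.items():
                if _is_missing(cell):
                    continue
                if spec.type == "categorical":
                    states = str(cell).split(MULTI_STATE_SEP)
                    bad = [s for s in states if s not in spec.classes]
                    if bad:
                        raise ValidationError(
                            f"trait {spec.name!r}, species {sp!r}: value(s) {bad} "
                            f"not in declared classes {list(spec.classes)}"
                        )
                else:
                    x = float(cell)
                    if not np.isfinite(x):
                        raise ValidationError(
                            f"trait {spec.name!r}, species {sp!r}: non-finite value"
                        )
                    if spec.type == "circular" and not (0.0 <= x < 360.0):
                        raise ValidationError(
                            f"circular trait {spec.name!r}, species {sp!r}: "
                            f"{x} outside [0, 360)"
                        )

    @property
    def species_ids(self) -> list:
        return list(self.values.index)


def _is_missing(cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and np.isnan(cell):
        return True
    if isinstance(cell, str) and cell.strip() == "":
        return True
    return False


@dataclass
class GroupAssignment:
    """Per-species dominance classification with the thresholds that produced it.

    Labels: ``dominant`` (max plot cover strictly above the dominance
    threshold), ``subordinate`` (max cover at least the inclusion threshold),
    ``excluded`` (never reached the inclusion threshold).
    """

    labels: pd.Series          # species -> label
    max_cover: pd.Series       # species -> max percent cover over plots
    inclusion_pct: float
    dominance_pct: float

    LABELS = ("dominant", "subordinate", "excluded")

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(self.LABELS)
        if bad:
            raise ValidationError(f"unknown group labels {bad}")

    def species(self, label: str) -> list:
        if label not in self.LABELS:
            raise KeyError(label)
        return list(self.labels.index[self.labels == label])

    @property
    def counts(self) -> dict:
        return {lab: int((self.labels == lab).sum()) for lab in self.LABELS}


@dataclass
class AnalysisConfig:
    """Knobs of the end-to-end pipeline, all echoed into the run log."""

    inclusion_threshold_pct: float = 1.0
    dominance_threshold_pct: float = 25.0
    n_permutations: int = 999
    rng_seed: int = 0
    cooccurrence_method: str = "jaccard"   # 'jaccard' | 'phi'
    dissimilarity_range_basis: str = "pooled"  # 'pooled' | 'subset'
    alpha: float = 0.05
    welch: bool = False
    standardize_pca: bool = True

    def __post_init__(self) -> None:
        if self.inclusion_threshold_pct <= 0 or self.dominance_threshold_pct <= 0:
            raise ValidationError("thresholds must be positive")
        if self.dominance_threshold_pct < self.inclusion_threshold_pct:
            raise ValidationError("dominance threshold must be >= inclusion threshold")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.cooccurrence_method not in ("jaccard", "phi"):
            raise ValidationError(f"unknown cooccurrence method {self.cooccurrence_method!r}")
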