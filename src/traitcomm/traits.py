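"""Trait-matrix expansion and mixed-type trait dissimilarity.

Categorical traits become one 0/1 indicator column per class (multi-state
values set several indicators, which clonal-trait databases require);
continuous and circular traits keep a single column.  Per trait group,
species × species dissimilarities are Gower-style and live in [0, 1]:
continuous traits are range-normalised absolute differences, circular
traits use the half-circle-normalised circular distance, and a categorical
group is the mean absolute difference of its indicator vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    MULTI_STATE_SEP,
    TraitSchema,
    TraitTable,
    ValidationError,
    _is_missing,
)


@dataclass
class TraitMatrixExpanded:
    """Species × numeric trait columns after categorical → indicator expansion."""

    values: pd.DataFrame
    column_source: dict  # expanded column -> source trait name
    schema: TraitSchema

    @property
    def species_ids(self) -> list:
        return list(self.values.index)

    @property
    def column_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class TraitDissimilarityMatrix:
    """Symmetric species dissimilarities for one trait group, in [0, 1]."""

    values: pd.DataFrame
    trait_group: str
    metric: str  # descriptor: how the dissimilarity was built/normalised

    @property
    def species_ids(self) -> list:
        return list(self.values.index)


def expand_traits(t: TraitTable) -> TraitMatrixExpanded:
    """Expand a typed trait table into the numeric indicator/value matrix.

    Each categorical class becomes a 0/1 column (1 marks occurrence of the
    state; missing source values propagate NaN across the trait's columns);
    continuous and circular traits pass through as single columns.
    """
    cols = {}
    source = {}
    for spec in t.schema:
        if spec.type == "categorical":
            for cls in spec.classes:
                ind = pd.Series(0.0, index=t.values.index)
                for sp, cell in t.values[spec.name].items():
                    if _is_missing(cell):
                        ind[sp] = np.nan
                    elif cls in str(cell).split(MULTI_STATE_SEP):
                        ind[sp] = 1.0
                cols[cls] = ind
                source[cls] = spec.name
        else:
            cols[spec.name] = t.values[spec.name].astype(float)
            source[spec.name] = spec.name
    values = pd.DataFrame(cols, index=t.values.index)
    return TraitMatrixExpanded(values=values, column_source=source, schema=t.schema)


def circular_distance(a: float, b: float) -> float:
    """Shortest angular distance between two directions, in [0, 180] degrees."""
    a, b = float(a), float(b)
    for x in (a, b):
        if not (0.0 <= x < 360.0):
            raise ValidationError(f"circular value {x} outside [0, 360)")
    d = abs(a - b)
    return min(d, 360.0 - d)


def _circular_distance_matrix(x: np.ndarray) -> np.ndarray:
    d = np.abs(x[:, None] - x[None, :])
    return np.minimum(d, 360.0 - d)


def trait_dissimilarity(
    t: TraitTable,
    trait_group: str,
    subset=None,
    range_basis=None,
) -> TraitDissimilarityMatrix:
    """Species × species dissimilarity matrix for one trait group.

    Parameters
    ----------
    t : TraitTable
    trait_group : str
        A group name from the schema (a source trait, or C/S/R).
    subset : sequence, optional
        Species to include (default all).  Range normalisation of continuous
        traits uses ``range_basis`` species if given, else the subset — pass
        the full retained pool as ``range_basis`` to put group-restricted
        matrices on a shared scale.
    """
    specs = t.schema.traits_in_group(trait_group)
    species = list(subset) if subset is not None else list(t.values.index)
    missing_sp = [s for s in species if s not in t.values.index]
    if missing_sp:
        raise ValidationError(f"species not in trait table: {missing_sp}")
    basis = list(range_basis) if range_basis is not None else species
    n = len(species)

    # one [0,1] distance layer per trait in the group; NaN marks pairs
    # undefined under pairwise deletion
    layers = []
    descriptors = []
    for spec in specs:
        if spec.type == "categorical":
            layer = _categorical_layer(t, spec, species)
            descriptors.append(f"{spec.name}:indicator-mean-mismatch")
        elif spec.type == "circular":
            vals = t.values.loc[species, spec.name].astype(float).to_numpy()
            layer = _circular_distance_matrix(vals) / 180.0
            layer[np.isnan(vals)[:, None] | np.isnan(vals)[None, :]] = np.nan
            descriptors.append(f"{spec.name}:circular/180")
        else:
            vals = t.values.loc[species, spec.name].astype(float).to_numpy()
            bvals = t.values.loc[basis, spec.name].astype(float).to_numpy()
            rng = np.nanmax(bvals) - np.nanmin(bvals)
            if np.isnan(rng) or not np.any(np.isfinite(vals)):
                raise ValidationError(
                    f"trait {spec.name!r}: all values missing in subset/basis"
                )
            if rng == 0:
                warnings.warn(
                    f"trait {spec.name!r} has zero range in normalisation basis; "
                    "dissimilarities are all zero",
                    stacklevel=2,
                )
                layer = np.zeros((n, n))
            else:
                layer = np.abs(vals[:, None] - vals[None, :]) / rng
            layer[np.isnan(vals)[:, None] | np.isnan(vals)[None, :]] = np.nan
            descriptors.append(f"{spec.name}:range-normalised(basis={len(basis)}sp)")
        layers.append(layer)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pair slices
        stack = np.nanmean(np.stack(layers), axis=0)
    np.fill_diagonal(stack, 0.0)
    df = pd.DataFrame(stack, index=species, columns=species)
    return TraitDissimilarityMatrix(
        values=df, trait_group=trait_group, metric="; ".join(descriptors)
    )


def _categorical_layer(t: TraitTable, spec, species) -> np.ndarray:
    """Mean absolute indicator difference over the trait's classes, NaN for
    pairs where either species' value is missing."""
    k = len(spec.classes)
    ind = np.zeros((len(species), k))
    miss = np.zeros(len(species), dtype=bool)
    for i, sp in enumerate(species):
        cell = t.values.at[sp, spec.name]
        if _is_missing(cell):
            miss[i] = True
            continue
        states = str(cell).split(MULTI_STATE_SEP)
        for j, cls in enumerate(spec.classes):
            if cls in states:
                ind[i, j] = 1.0
    layer = np.abs(ind[:, None, :] - ind[None, :, :]).mean(axis=2)
    layer[miss[:, None] | miss[None, :]] = np.nan
    return layer
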