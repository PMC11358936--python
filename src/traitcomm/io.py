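"""CSV/YAML readers and writers for the pipeline's artifact types.

CSV is the single exchange format.  Relevé tables are accepted wide (first
column plot labels, header row species labels) or long (plot, species,
value — detected by a 3-column header); the trait schema travels as a YAML
sidecar next to the trait values CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    BB_ALPHABET,
    CoverMatrix,
    TraitSchema,
    TraitSpec,
    TraitTable,
    ValidationError,
)

_ABSENT = {"", "na", "nan", "none", "absent"}


def _parse_cell(raw: str, scale_kind: str, where: str):
    s = str(raw).strip()
    if s.lower() in _ABSENT:
        return np.nan
    if scale_kind == "braun_blanquet":
        if s not in BB_ALPHABET:
            raise ValidationError(f"unknown Braun-Blanquet code {s!r} at {where}")
        return s
    try:
        return float(s)
    except ValueError:
        raise ValidationError(f"non-numeric percent cover {s!r} at {where}") from None


def read_cover_matrix(path, scale_kind: str = "braun_blanquet") -> CoverMatrix:
    """Read a relevé table, auto-detecting wide vs long dialect.

    A three-column file whose second header field is ``species`` is read
    long-form (plot, species, value); anything else is wide (first column
    plot labels, remaining header fields species labels).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows) < 2:
        raise ValidationError(f"{path}: empty cover table")
    header = [c.strip() for c in rows[0]]

    if len(header) == 3 and header[1].lower() == "species":
        seen = {}
        for ln, row in enumerate(rows[1:], start=2):
            plot, sp, raw = (c.strip() for c in row)
            if (plot, sp) in seen:
                raise ValidationError(
                    f"{path}:{ln}: duplicate (plot={plot!r}, species={sp!r})"
                )
            seen[(plot, sp)] = _parse_cell(raw, scale_kind, f"{path}:{ln}")
        plots = list(dict.fromkeys(p for p, _ in seen))
        species = list(dict.fromkeys(s for _, s in seen))
        values = pd.DataFrame(np.nan, index=plots, columns=species, dtype=object)
        for (plot, sp), v in seen.items():
            values.at[plot, sp] = v
    else:
        species = header[1:]
        plots, data = [], []
        for ln, row in enumerate(rows[1:], start=2):
            if len(row) != len(header):
                raise ValidationError(f"{path}:{ln}: ragged row")
            plots.append(row[0].strip())
            data.append(
                [
                    _parse_cell(c, scale_kind, f"{path}:{ln} species={species[j]!r}")
                    for j, c in enumerate(row[1:])
                ]
            )
        values = pd.DataFrame(data, index=plots, columns=species, dtype=object)

    if scale_kind == "percent":
        values = values.astype(float)
    return CoverMatrix(values=values, scale_kind=scale_kind)


def write_cover_matrix(m: CoverMatrix, path) -> None:
    out = m.values.copy()
    out.index.name = "plot"
    out.to_csv(path, na_rep="")


def read_trait_schema(path) -> TraitSchema:
    """Read the YAML trait-schema sidecar."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    traits = [
        TraitSpec(
            name=entry["name"],
            type=entry["type"],
            classes=tuple(entry.get("classes", ())),
            unit=entry.get("unit", ""),
            group=entry.get("group", ""),
        )
        for entry in raw["traits"]
    ]
    return TraitSchema(traits=traits)


def write_trait_schema(schema: TraitSchema, path) -> None:
    doc = {
        "traits": [
            {
                "name": t.name,
                "type": t.type,
                **({"classes": list(t.classes)} if t.classes else {}),
                **({"unit": t.unit} if t.unit else {}),
                **({"group": t.group} if t.group != t.name else {}),
            }
            for t in schema
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_trait_table(path, schema_path) -> TraitTable:
    """Read trait values CSV (first column species) plus its schema sidecar."""
    schema = read_trait_schema(schema_path)
    df = pd.read_csv(path, index_col=0)
    for spec in schema:
        if spec.name not in df.columns:
            raise ValidationError(f"{path}: missing trait column {spec.name!r}")
        if spec.type == "categorical":
            df[spec.name] = df[spec.name].astype(object)
        else:
            df[spec.name] = pd.to_numeric(df[spec.name], errors="raise")
    return TraitTable(values=df[schema.names], schema=schema)


def write_trait_table(t: TraitTable, values_path, schema_path) -> None:
    out = t.values.copy()
    out.index.name = "species"
    out.to_csv(values_path, na_rep="")
    write_trait_schema(t.schema, schema_path)


def write_ground_truth(gt: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(gt, fh, sort_keys=True)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
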