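"""Default dry-grassland trait schema.

Fourteen plant functional traits of the kind recorded for European
semi-natural grassland floras: Raunkiaer life form, growth form, plant
height, specific leaf area (SLA), leaf dry matter content (LDMC), flowering
start (circular, degrees around the year), flowering length, clonal growth
organ (CGO) type, CGO connection persistence, number of clonal offspring
shoots, lateral spread, CGO role, bud-bank layer, and the Grime CSR
strategy expressed as three continuous scores.  Binary expansion of the
five categorical traits takes the matrix from 14 traits to 35 numeric
columns (24 class indicators + 7 continuous + 1 circular + C/S/R).
"""

from .datatypes import TraitSchema, TraitSpec

LIFE_FORM_CLASSES = ("LF_ch", "LF_ge", "LF_he", "LF_th")
GROWTH_FORM_CLASSES = ("GF_tuss", "GF_rose", "GF_le_st", "GF_ro_le")
CGO_TYPE_CLASSES = (
    "CGO1",   # stolon
    "CGO9",   # epigeogenous rhizome
    "CGO10",  # hypogeogenous rhizome
    "CGO12",  # belowground stem tuber
    "CGO13",  # bulb
    "CGO14",  # root splitter
    "CGO15",  # root with adventitious buds
    "CGO16",  # root tuber
)
CGO_ROLE_CLASSES = ("Role_1", "Role_2", "Role_3", "Role_4")
BUD_BANK_CLASSES = ("NoBB1", "NoBB2", "NoBB0", "NoBB01")


def default_schema() -> TraitSchema:
    """The 14-trait grassland schema whose binary expansion has 35 columns."""
    return TraitSchema(
        traits=[
            TraitSpec("life_form", "categorical", LIFE_FORM_CLASSES),
            TraitSpec("growth_form", "categorical", GROWTH_FORM_CLASSES),
            TraitSpec("P_height", "continuous", unit="cm"),
            TraitSpec("SLA", "continuous", unit="mm2/mg"),
            TraitSpec("LDMC", "continuous", unit="mg/g"),
            TraitSpec("F_start", "circular", unit="deg"),
            TraitSpec("F_length", "continuous", unit="months"),
            TraitSpec("CGO_type", "categorical", CGO_TYPE_CLASSES),
            TraitSpec("Persist_CGO", "continuous", unit="yr"),
            TraitSpec("NoCloSh", "continuous", unit="shoots"),
            TraitSpec("Lat_spread", "continuous", unit="m"),
            TraitSpec("CGO_role", "categorical", CGO_ROLE_CLASSES),
            TraitSpec("bud_bank", "categorical", BUD_BANK_CLASSES),
            TraitSpec("C", "continuous", group="C"),
            TraitSpec("S", "continuous", group="S"),
            TraitSpec("R", "continuous", group="R"),
        ]
    )
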