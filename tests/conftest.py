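import numpy as np
import pandas as pd
import pytest

from traitcomm import (
    CoverMatrix,
    SimulationConfig,
    TraitSchema,
    TraitSpec,
    TraitTable,
    classify_species,
    generate_community,
    to_percent,
)


@pytest.fixture(scope="session")
def default_community():
    """One default synthetic community, shared across tests (seed 42)."""
    return generate_community(SimulationConfig(rng_seed=42))


@pytest.fixture(scope="session")
def default_percent(default_community):
    cover, _, _ = default_community
    return to_percent(cover)


@pytest.fixture(scope="session")
def default_assignment(default_percent):
    return classify_species(default_percent)


@pytest.fixture
def tiny_bb_cover():
    """2 plots × 3 species Braun-Blanquet matrix exercising presence vs absence."""
    values = pd.DataFrame(
        [["+", "2", np.nan], ["r", "5", "1"]],
        index=["p1", "p2"],
        columns=["sp1", "sp2", "sp3"],
        dtype=object,
    )
    return CoverMatrix(values=values, scale_kind="braun_blanquet")


@pytest.fixture
def two_trait_table():
    """Small typed trait table: one categorical, one continuous, one circular."""
    schema = TraitSchema(
        traits=[
            TraitSpec("colour", "categorical", ("red", "green", "blue")),
            TraitSpec("height", "continuous", unit="cm"),
            TraitSpec("phase", "circular", unit="deg"),
        ]
    )
    values = pd.DataFrame(
        {
            "colour": ["red", "red", "blue"],
            "height": [10.0, 20.0, 30.0],
            "phase": [350.0, 10.0, 180.0],
        },
        index=["a", "b", "c"],
    )
    return TraitTable(values=values, schema=schema)
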