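from __future__ import annotations

import pytest
from hypothesis import strategies as st

from tablesim.io_setups import (
    SURFACE_HEIGHT,
    SURFACE_WIDTH,
    InstrumentPlacement,
    SetupCollection,
    TableSetup,
)


def placement(iid: str, x: float, y: float, angle: float = 0.0) -> InstrumentPlacement:
    return InstrumentPlacement(instrument_id=iid, label=iid, x=x, y=y, angle=angle)


def make_setup(setup_id: str, clinic_id: str, *placements) -> TableSetup:
    return TableSetup(setup_id=setup_id, clinic_id=clinic_id, placements=list(placements))


@pytest.fixture
def single_pair():
    """The worked single-shared-instrument pair: d_trans=5, d_rot=20."""
    a = make_setup("a", "c1", placement("I1", 0, 0, 0))
    b = make_setup("b", "c2", placement("I1", 3, 4, 20))
    return a, b


# --- hypothesis strategies -------------------------------------------------

coords_x = st.floats(min_value=0, max_value=SURFACE_WIDTH, allow_nan=False)
coords_y = st.floats(min_value=0, max_value=SURFACE_HEIGHT, allow_nan=False)
angles = st.floats(min_value=0, max_value=359.999, allow_nan=False)
instrument_ids = st.sampled_from([f"I{k}" for k in range(6)])

placements_st = st.builds(
    InstrumentPlacement,
    instrument_id=instrument_ids,
    label=st.text(
        alphabet=st.characters(codec="utf-8", exclude_categories=("C",)), max_size=8
    ),
    x=coords_x,
    y=coords_y,
    angle=angles,
)


def setups_st(min_placements: int = 0, max_placements: int = 6):
    return st.builds(
        TableSetup,
        setup_id=st.uuids().map(lambda u: f"s{u.hex[:8]}"),
        clinic_id=st.sampled_from(["c1", "c2", "c3"]),
        placements=st.lists(placements_st, min_size=min_placements, max_size=max_placements),
    )


def collections_st(min_setups: int = 2, max_setups: int = 5):
    return st.lists(
        setups_st(), min_size=min_setups, max_size=max_setups,
        unique_by=lambda s: s.setup_id,
    ).map(SetupCollection)
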