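"""Shared synthetic fixtures (rendered once per session where expensive)."""

import numpy as np
import pandas as pd
import pytest

from py1h import fixtures


def make_screen(n_events=100, seed=0, mix=None, design="2AD"):
    """A one-bait screen with a planted event mix."""
    rng = np.random.default_rng(seed)
    if mix is None:
        mix = {
            "obligate-cooperative": 25,
            "enhanced-cooperative": 5,
            "TF1-antagonized": 15,
            "TF2-antagonized": 15,
            "independent": 20,
            "none": 20,
        }
    events = [e for e, n in mix.items() for _ in range(n)]
    assert len(events) == n_events
    rng.shuffle(events)
    pairs = [f"P{i:03d}" for i in range(n_events)]
    truth = fixtures.ScreenTruth(
        baits=["bait0"],
        pairs=pairs,
        events={("bait0", p): e for p, e in zip(pairs, events)},
        design=design,
    )
    return truth


@pytest.fixture(scope="session")
def screen_plate():
    """Rendered 100-event 2-AD screen plate with its truth tables."""
    truth = make_screen(seed=0)
    plates_t, expected = fixtures.gen_screen(truth, seed=1)
    pt = plates_t["bait0"]
    image, table = fixtures.gen_plate(pt)
    return {"truth": truth, "plate_truth": pt, "image": image, "table": table, "expected": expected}


@pytest.fixture(scope="session")
def measurement_table():
    """A small hand-checkable measurement table: 2 empties + 2 strains."""
    rows = []
    # empties: I=0.2, A=100 each colony
    for strain in ("empty_00", "empty_01"):
        for i in range(4):
            rows.append((strain, "empty", 100, 0.2, ""))
    # strain q1: I=0.5, A=100; strain q2: I=0.1 (the plate minimum), A=50
    for i in range(4):
        rows.append(("q1", "pair", 100, 0.5, ""))
    for i in range(4):
        rows.append(("q2", "pair", 50, 0.1, ""))
    return pd.DataFrame(rows, columns=["strain", "strain_class", "area", "intensity", "flag"])
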