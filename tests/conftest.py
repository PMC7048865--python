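import pytest

from driftlink.pipeline import ScreenConfig
from driftlink.simulate import TABLE1_ROWS, fig1_scenario, fig2_scenario, simulate_dataset


def match_reference_rows(rows, rt_tol=0.05, ccs_tol=1.0):
    """Pair report rows 1:1 with the reference species table.

    Two reference isomers share (name, rt) and differ only in CCS, so the
    match uses all three coordinates.  Returns {reference tuple: row} and
    asserts the pairing is a bijection.
    """
    matched = {}
    used = set()
    for ref in TABLE1_ROWS:
        name, _formula, rt, _mz, ccs, _counts = ref
        candidates = [
            row
            for row in rows
            if id(row) not in used
            and row.name == name
            and abs(row.rt - rt) <= rt_tol
            and (row.ccs_mean is None or abs(row.ccs_mean - ccs) <= ccs_tol)
        ]
        assert len(candidates) == 1, (name, rt, ccs, len(candidates))
        matched[ref] = candidates[0]
        used.add(id(candidates[0]))
    assert len(rows) == len(TABLE1_ROWS), "unexpected extra report rows"
    return matched


@pytest.fixture(scope="session")
def fig1_frames():
    """Noise-free worked-example run: DCF-Glc-Mal family at rt 6.8 / 28.66 ms."""
    return simulate_dataset(fig1_scenario())


@pytest.fixture(scope="session")
def fig2_frames():
    """Noise-free worked-example run: DCF-Lac-OH-Glc-GlcA at rt 4.1 / 31.74 ms."""
    return simulate_dataset(fig2_scenario())


@pytest.fixture()
def config():
    return ScreenConfig()
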