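"""Neutral-loss decomposition, hit assembly and replicate aggregation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from driftlink.annotate import (
    DEFAULT_CAPS,
    MetaboliteHit,
    aggregate_hits,
    annotate_precursor,
    decompose_delta,
)
from driftlink.chem import BACKBONES, MODIFICATIONS, compose, ion_mz
from driftlink.iodata import Feature


def _oracle_decompositions(delta, ref_mass, tol_ppm, caps):
    """Independent exhaustive enumeration over the residue caps.

    Residue masses are summed atom-by-atom here (not via Modification
    arithmetic) so the check does not share a code path with the
    implementation.
    """
    atomic = {"C": 12.0, "H": 1.0078250319, "O": 15.9949146221}
    residue_atoms = {
        "OH": {"O": 1},
        "Glc": {"C": 6, "H": 10, "O": 5},
        "GlcA": {"C": 6, "H": 8, "O": 6},
        "Mal": {"C": 3, "H": 2, "O": 3},
    }
    masses = {
        name: sum(atomic[el] * n for el, n in atoms.items())
        for name, atoms in residue_atoms.items()
    }
    names = list(residue_atoms)
    hits = set()
    for counts in itertools.product(*(range(caps[n] + 1) for n in names)):
        total = sum(masses[n] * c for n, c in zip(names, counts))
        if abs(delta - total) <= tol_ppm * 1e-6 * ref_mass:
            hits.add(tuple((n, c) for n, c in zip(names, counts) if c))
    return hits


class TestDecomposeDelta:
    def test_fig1_delta_assigns_glc_mal(self):
        decomps = decompose_delta(248.0548, ref_mass=544.0788, tol_ppm=10)
        assert decomps, "delta should be assignable"
        assert decomps[0].as_dict() == {"Glc": 1, "Mal": 1}

    def test_zero_delta_is_empty_multiset(self):
        decomps = decompose_delta(0.0, ref_mass=296.0240)
        assert decomps[0].mods == ()

    def test_glc_glca_delta(self):
        delta = MODIFICATIONS["Glc"].delta_mass + MODIFICATIONS["GlcA"].delta_mass
        decomps = decompose_delta(delta, ref_mass=632.0942, tol_ppm=5)
        assert decomps[0].as_dict() == {"Glc": 1, "GlcA": 1}
        assert decomps[0].ppm == pytest.approx(0.0, abs=1e-9)

    def test_unassignable_delta_empty(self):
        assert decompose_delta(10.0, ref_mass=306.0) == []

    def test_matches_exhaustive_oracle_on_delta_grid(self):
        caps = {"OH": 2, "Glc": 2, "GlcA": 1, "Mal": 2, "H2O-loss": 0}
        rng = np.random.default_rng(2026)
        exact = np.array(
            [15.9949, 86.0004, 162.0528, 176.0321, 248.0532, 338.0849, 340.1005]
        )
        deltas = np.concatenate(
            [
                rng.uniform(0.0, 600.0, size=3000),
                # exact residue sums and near misses around them
                np.repeat(exact, 8) + rng.uniform(-2e-3, 2e-3, size=exact.size * 8),
            ]
        )
        for delta in deltas:
            ref = 300.0 + delta
            got = {
                d.mods for d in decompose_delta(delta, ref, tol_ppm=5, caps=caps)
            }
            expected = _oracle_decompositions(delta, ref, 5, caps)
            assert got == expected, delta

    @given(st.floats(min_value=0.0, max_value=600.0))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_reducing_tolerance_never_adds(self, delta):
        ref = 300.0 + delta
        tight = {d.mods for d in decompose_delta(delta, ref, tol_ppm=2)}
        loose = {d.mods for d in decompose_delta(delta, ref, tol_ppm=10)}
        assert tight <= loose

    def test_sorted_by_abs_ppm_then_size(self):
        decomps = decompose_delta(340.10, ref_mass=640.0, tol_ppm=200)
        ranks = [(abs(d.ppm), d.size) for d in decomps]
        assert ranks == sorted(ranks)


class TestAnnotatePrecursor:
    def _feature(self, mz, rt=5.0, dt=25.0):
        return Feature(rt_apex=rt, dt_apex=dt, mz=mz, intensity=5000.0)

    def test_fig2_precursor(self):
        hit = annotate_precursor(
            self._feature(632.0942, rt=4.1, dt=31.74), BACKBONES["DCF-Lac-OH"]
        )
        assert hit.name == "DCF-Lac-OH-Glc-GlcA"
        assert hit.formula == "C26H27Cl2NO13"

    def test_fig1_precursor(self):
        hit = annotate_precursor(self._feature(544.0788, rt=6.8), BACKBONES["DCF"])
        assert hit.name == "DCF-Glc-Mal"
        assert hit.formula == "C23H23Cl2NO10"

    def test_parent_drug_has_empty_multiset(self):
        hit = annotate_precursor(
            self._feature(BACKBONES["DCF"].fragment_mz), BACKBONES["DCF"]
        )
        assert hit.name == "DCF"
        assert hit.modifications == {}
        assert hit.delta_ppm == pytest.approx(0.0, abs=1e-9)

    def test_unassignable_returns_none(self):
        assert (
            annotate_precursor(self._feature(700.0000), BACKBONES["DCF"]) is None
        )

    def test_round_trip_identity_over_all_cap_multisets(self):
        """Every composable multiset is recovered at 0 ppm from its exact m/z."""
        caps = DEFAULT_CAPS
        names = ["OH", "Glc", "GlcA", "Mal"]
        for backbone in BACKBONES.values():
            for counts in itertools.product(*(range(caps[n] + 1) for n in names)):
                mods = {n: c for n, c in zip(names, counts) if c}
                comp = compose(backbone, mods)
                mz = ion_mz(comp.formula)
                hit = annotate_precursor(self._feature(mz), backbone)
                assert hit is not None, (backbone.name, mods)
                assert hit.modifications == mods, (backbone.name, mods)
                assert hit.name == comp.name
                assert abs(hit.delta_ppm) < 1e-6


class TestAggregateHits:
    def _hit(self, name="DCF-Glc-Mal", rt=6.7, dt=27.5, mz=544.0770, sample="onion",
             replicate=0, ccs=211.6):
        return MetaboliteHit(
            name=name,
            formula="C23H23Cl2NO10",
            backbone="DCF",
            modifications={"Glc": 1, "Mal": 1},
            mz_observed=mz,
            mz_theoretical=544.0772,
            delta_ppm=-0.4,
            rt=rt,
            dt=dt,
            ccs=ccs,
            sample=sample,
            replicate=replicate,
        )

    def test_three_replicates_merge_to_one_row(self):
        hits = [self._hit(replicate=r) for r in range(3)]
        rows = aggregate_hits(hits)
        assert len(rows) == 1
        assert rows[0].n_detections == 3
        assert rows[0].presence == {"onion": True}
        assert rows[0].ccs_rsd == pytest.approx(0.0)

    def test_distinct_rt_isomers_stay_separate(self):
        hits = [self._hit(rt=3.5, dt=28.4), self._hit(rt=3.6, dt=27.9)]
        # 0.1 min apart but drift-resolved by ~0.5 ms -> two rows
        hits[1].dt = hits[0].dt + 0.5
        rows = aggregate_hits(hits)
        assert len(rows) == 2

    def test_same_rt_drift_resolved_isomers_stay_separate(self):
        hits = [self._hit(rt=3.0, dt=28.0), self._hit(rt=3.0, dt=28.7)]
        assert len(aggregate_hits(hits)) == 2

    def test_rows_sorted_by_descending_mz(self):
        hits = [
            self._hit(),
            self._hit(name="DCF", mz=296.0244, rt=8.6, dt=21.0),
        ]
        hits[1].formula = "C14H11Cl2NO2"
        hits[1].mz_theoretical = 296.0240
        rows = aggregate_hits(hits)
        assert [r.name for r in rows] == ["DCF-Glc-Mal", "DCF"]

    def test_presence_map_covers_requested_samples(self):
        rows = aggregate_hits([self._hit()], samples=["onion", "maize"])
        assert rows[0].presence == {"onion": True, "maize": False}
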