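"""Anchoring, co-drift grouping, precursor selection and corroboration."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from driftlink.chem import BACKBONES
from driftlink.iodata import Feature
from driftlink.linker import (
    co_drift_group,
    corroborate,
    find_anchors,
    select_precursor,
)
from driftlink.peaks import detect_features


def _feat(mz, dt, rt=5.0, intensity=1000.0):
    return Feature(rt_apex=rt, dt_apex=dt, mz=mz, intensity=intensity)


class TestFindAnchors:
    def test_fig1_anchor(self, fig1_frames):
        features = detect_features(fig1_frames)
        anchors = find_anchors(features, BACKBONES)
        assert len(anchors) == 1
        anchor = anchors[0]
        assert anchor.backbone.name == "DCF"
        assert anchor.dt == pytest.approx(28.66)
        assert anchor.mz == pytest.approx(296.0249)
        assert abs(anchor.rt_apex - 6.8) <= 0.02

    def test_fig2_anchor(self, fig2_frames):
        features = detect_features(fig2_frames)
        anchors = find_anchors(features, BACKBONES)
        assert len(anchors) == 1
        anchor = anchors[0]
        assert anchor.backbone.name == "DCF-Lac-OH"
        assert anchor.dt == pytest.approx(31.74)
        assert anchor.mz == pytest.approx(294.0087)

    def test_no_match_is_empty(self):
        features = [_feat(700.0, 25.0), _feat(650.0, 22.0)]
        assert find_anchors(features, BACKBONES) == []

    def test_coeluting_same_backbone_resolved_by_drift(self):
        """Two conjugates sharing a backbone at one rt give two anchors."""
        frag = BACKBONES["DCF-OH"].fragment_mz
        features = [
            _feat(frag, 25.0, rt=3.0, intensity=2000.0),
            _feat(frag, 28.0, rt=3.0, intensity=1500.0),
        ]
        anchors = find_anchors(features, BACKBONES)
        assert sorted(a.dt for a in anchors) == [25.0, 28.0]

    def test_duplicate_spots_merge_to_most_intense(self):
        frag = BACKBONES["DCF"].fragment_mz
        features = [
            _feat(frag, 25.00, rt=5.00, intensity=2000.0),
            _feat(frag * (1 + 2e-6), 25.03, rt=5.02, intensity=500.0),
        ]
        anchors = find_anchors(features, BACKBONES)
        assert len(anchors) == 1
        assert anchors[0].intensity == 2000.0


class TestCoDriftGroup:
    def test_fig2_membership(self, fig2_frames):
        features = detect_features(fig2_frames)
        anchor = find_anchors(features, BACKBONES)[0]
        group = co_drift_group(features, anchor, dt_tol_ms=0.05)
        assert [round(f.mz, 4) for f in group.members] == [
            294.0087,
            456.0610,
            632.0942,
        ]
        assert all(abs(f.mz - 679.5136) > 1 for f in group.members)

    def test_anchor_alone_is_singleton(self):
        anchor = find_anchors([_feat(296.0240, 28.0)], BACKBONES)[0]
        group = co_drift_group([anchor.feature], anchor)
        assert group.members == [anchor.feature]

    def test_infinite_tolerance_keeps_all_coeluters(self, fig2_frames):
        features = detect_features(fig2_frames)
        anchor = find_anchors(features, BACKBONES)[0]
        group = co_drift_group(features, anchor, dt_tol_ms=1e9)
        assert len(group.members) == len(
            [f for f in features if abs(f.rt_apex - anchor.rt_apex) <= 0.1]
        )

    @given(st.floats(min_value=0.01, max_value=2.0), st.floats(min_value=1.0, max_value=5.0))
    @settings(max_examples=50, deadline=None)
    def test_shrinking_tolerance_never_adds_members(self, tol, factor):
        features = [
            _feat(300.0 + i, 25.0 + 0.2 * i, intensity=100.0 + i) for i in range(10)
        ]
        anchor = find_anchors(features + [_feat(296.0240, 25.5)], BACKBONES)[0]
        small = co_drift_group(features, anchor, dt_tol_ms=tol)
        large = co_drift_group(features, anchor, dt_tol_ms=tol * factor)
        assert set(id(f) for f in small.members) <= set(id(f) for f in large.members)


class TestSelectPrecursor:
    def test_fig1_precursor(self, fig1_frames):
        features = detect_features(fig1_frames)
        anchor = find_anchors(features, BACKBONES)[0]
        group = co_drift_group(features, anchor)
        assert select_precursor(group).mz == pytest.approx(544.0788)

    def test_fig2_precursor_rejects_more_intense_interferent(self, fig2_frames):
        features = detect_features(fig2_frames)
        # the interferent is the most intense ion at this rt...
        top = max(
            (f for f in features if abs(f.rt_apex - 4.1) < 0.1),
            key=lambda f: f.intensity,
        )
        assert top.mz == pytest.approx(679.5136)
        # ...but the drift-linked precursor is the metabolite
        anchor = find_anchors(features, BACKBONES)[0]
        group = co_drift_group(features, anchor)
        assert select_precursor(group).mz == pytest.approx(632.0942)

    def test_permutation_invariance(self):
        features = [_feat(300.0 + i, 25.0, intensity=50.0 * i) for i in range(8)]
        features.append(_feat(296.0240, 25.0, intensity=999.0))
        anchor = find_anchors(features, BACKBONES)[0]
        chosen = []
        for seed in range(5):
            shuffled = features[:]
            random.Random(seed).shuffle(shuffled)
            group = co_drift_group(shuffled, anchor)
            chosen.append(select_precursor(group).mz)
        assert len(set(chosen)) == 1

    def test_tie_breaks_on_intensity_then_drift(self):
        a = _feat(500.0, 25.0, intensity=100.0)
        b = _feat(500.0, 25.02, intensity=300.0)
        anchor = find_anchors([_feat(296.0240, 25.0)], BACKBONES)[0]
        group = co_drift_group([a, b, anchor.feature], anchor, dt_tol_ms=0.1)
        assert select_precursor(group) is b

    def test_empty_group_errors(self, fig1_frames):
        features = detect_features(fig1_frames)
        anchor = find_anchors(features, BACKBONES)[0]
        group = co_drift_group(features, anchor)
        group.members = []
        with pytest.raises(ValueError):
            select_precursor(group)


class TestCorroborate:
    def test_fig2_losses(self, fig2_frames):
        features = detect_features(fig2_frames)
        anchor = find_anchors(features, BACKBONES)[0]
        group = co_drift_group(features, anchor)
        precursor = select_precursor(group)
        notes = corroborate(group, precursor)
        assert len(notes) == 1  # the 456.0610 intermediate
        labels = notes[0].labels
        assert any("GlcA loss" in lab for lab in labels)
        assert any("anchor + Glc" in lab for lab in labels)

    def test_fig1_water_losses_and_adduct_fragment(self, fig1_frames):
        features = detect_features(fig1_frames)
        anchor = find_anchors(features, BACKBONES)[0]
        group = co_drift_group(features, anchor)
        precursor = select_precursor(group)
        joined = {
            round(n.mz, 4): "; ".join(n.labels) for n in corroborate(group, precursor)
        }
        assert "H2O loss" in joined[526.0682]
        assert "2xH2O loss" in joined[508.0577]
        assert "C2H2O" in joined[338.0355]

    def test_unrelated_member_flagged(self):
        anchor_feat = _feat(296.0240, 25.0)
        stray = _feat(430.0, 25.0)
        precursor = _feat(544.0772, 25.0)
        anchor = find_anchors([anchor_feat], BACKBONES)[0]
        group = co_drift_group([anchor_feat, stray, precursor], anchor)
        notes = corroborate(group, precursor)
        assert len(notes) == 1
        assert not notes[0].explained
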