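"""Drift-time-aligned fragment -> precursor linking.

The core trick of the screen: in all-ions acquisition every ion is
fragmented *after* the drift tube, so a precursor and all of its fragments
share one drift time, while co-eluting matrix ions drift at their own,
different times.  Anchoring on the characteristic backbone fragment and
collecting all co-eluting, co-drifting features therefore isolates exactly
one metabolite's ion family — and the intact precursor is simply the
highest-m/z member of that family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .chem import Backbone, Modification, MODIFICATIONS, parse_formula
from .iodata import Feature

__all__ = [
    "Anchor",
    "CoDriftGroup",
    "FragmentAnnotation",
    "find_anchors",
    "co_drift_group",
    "select_precursor",
    "corroborate",
]

_WATER_MASS = parse_formula("H2O").monoisotopic_mass
_KETENE_MASS = parse_formula("C2H2O").monoisotopic_mass


@dataclass
class Anchor:
    """A characteristic backbone fragment located in (rt, dt, m/z)."""

    backbone: Backbone
    rt_apex: float
    dt: float
    mz: float
    intensity: float
    feature: Feature


@dataclass
class CoDriftGroup:
    """All features at one chromatographic peak sharing the anchor's drift time."""

    anchor: Anchor
    members: List[Feature]
    dt_tol_ms: float


@dataclass
class FragmentAnnotation:
    """A non-anchor, non-precursor group member with its loss assignment."""

    mz: float
    labels: List[str] = field(default_factory=list)

    @property
    def explained(self) -> bool:
        return bool(self.labels)


def find_anchors(
    features: Sequence[Feature],
    backbones: Mapping[str, Backbone],
    frag_tol_ppm: float = 10.0,
    rt_merge_min: float = 0.06,
    dt_merge_ms: float = 0.1,
) -> List[Anchor]:
    """Locate characteristic-fragment features for each backbone.

    Every feature matching a backbone's fragment m/z within ``frag_tol_ppm``
    is an anchor candidate.  Candidates of the same backbone that coincide
    in retention time *and* drift time are duplicates of one fragment spot
    and are merged (most intense wins); candidates at the same rt but
    different drift times stay separate, because co-eluting conjugates that
    share a backbone are resolved by the drift dimension alone.
    """
    anchors: List[Anchor] = []
    for backbone in backbones.values():
        target = backbone.fragment_mz
        window = frag_tol_ppm * 1e-6 * target
        candidates = [f for f in features if abs(f.mz - target) <= window]
        candidates.sort(key=lambda f: -f.intensity)
        chosen: List[Feature] = []
        for cand in candidates:
            if any(
                abs(cand.rt_apex - c.rt_apex) <= rt_merge_min
                and abs(cand.dt_apex - c.dt_apex) <= dt_merge_ms
                for c in chosen
            ):
                continue
            chosen.append(cand)
        for feat in chosen:
            anchors.append(
                Anchor(
                    backbone=backbone,
                    rt_apex=feat.rt_apex,
                    dt=feat.dt_apex,
                    mz=feat.mz,
                    intensity=feat.intensity,
                    feature=feat,
                )
            )
    anchors.sort(key=lambda a: (a.rt_apex, a.dt, a.mz))
    return anchors


def co_drift_group(
    features: Sequence[Feature],
    anchor: Anchor,
    dt_tol_ms: float = 0.05,
    rt_bounds: Optional[Tuple[float, float]] = None,
    rt_half_window: float = 0.1,
) -> CoDriftGroup:
    """Collect features co-eluting with the anchor at its drift time.

    Members are all features inside the chromatographic bounds whose drift
    time lies within ``dt_tol_ms`` of the anchor's; everything else at the
    peak is matrix and is excluded.  Members are sorted by m/z.
    """
    if dt_tol_ms <= 0:
        raise ValueError("dt_tol_ms must be positive")
    if rt_bounds is None:
        rt_bounds = (anchor.rt_apex - rt_half_window, anchor.rt_apex + rt_half_window)
    lo, hi = rt_bounds
    members = [
        f
        for f in features
        if lo <= f.rt_apex <= hi and abs(f.dt_apex - anchor.dt) <= dt_tol_ms
    ]
    if anchor.feature not in members:
        members.append(anchor.feature)
    members.sort(key=lambda f: f.mz)
    return CoDriftGroup(anchor=anchor, members=members, dt_tol_ms=dt_tol_ms)


def select_precursor(group: CoDriftGroup) -> Feature:
    """The intact precursor: the group member with the highest m/z.

    Fragments can only be lighter than the molecule they came from, so the
    heaviest co-drifting ion is the intact metabolite.  Ties break on higher
    intensity, then lower drift time (deterministic, arbitrary).
    """
    if not group.members:
        raise ValueError("cannot select a precursor from an empty group")
    return max(group.members, key=lambda f: (f.mz, f.intensity, -f.dt_apex))


def corroborate(
    group: CoDriftGroup,
    precursor: Feature,
    modifications: Mapping[str, Modification] = MODIFICATIONS,
    tol_ppm: float = 10.0,
    max_water_losses: int = 2,
) -> List[FragmentAnnotation]:
    """Explain the intermediate group members as neutral losses.

    Each member between the anchor and the precursor is checked against the
    residue library as a loss from the precursor, against water-loss
    multiples, and as a residue gain (or ketene adduct) relative to the
    anchor fragment.  Members matching nothing are flagged unexplained.
    """
    anchor = group.anchor
    annotations: List[FragmentAnnotation] = []
    residues = [
        (mod.name, mod.delta_formula.monoisotopic_mass)
        for mod in modifications.values()
        if mod.sign > 0
    ]
    for member in group.members:
        if member is anchor.feature or member is precursor:
            continue
        note = FragmentAnnotation(mz=member.mz)
        loss = precursor.mz - member.mz
        gain = member.mz - anchor.mz
        tol_loss = tol_ppm * 1e-6 * precursor.mz
        tol_gain = tol_ppm * 1e-6 * member.mz
        for name, mass in residues:
            if abs(loss - mass) <= tol_loss:
                note.labels.append(f"{name} loss from precursor")
            if abs(gain - mass) <= tol_gain:
                note.labels.append(f"anchor + {name}")
        for n in range(1, max_water_losses + 1):
            if abs(loss - n * _WATER_MASS) <= tol_loss:
                note.labels.append("H2O loss" if n == 1 else f"{n}xH2O loss")
        if abs(gain - _KETENE_MASS) <= tol_gain:
            note.labels.append(f"[{anchor.backbone.name}+C2H2O+H]+ fragment")
        annotations.append(note)
    return annotations
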