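"""Neutral-loss decomposition and metabolite hit assembly.

Once the intact precursor of an ion family is known, the mass difference to
the theoretical backbone fragment is decomposed combinatorially into a
multiset of conjugation residues (glucosyl, glucuronyl, malonyl, hydroxyl,
optionally water loss).  Each surviving decomposition names a tentative
metabolite; assignments are compositional only — positional isomers share a
name, as is standard for screening-level annotation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .chem import (
    Backbone,
    MODIFICATIONS,
    Modification,
    compose,
    ion_mz,
    ppm_error,
)
from .iodata import Feature, ReportRow

__all__ = [
    "DEFAULT_CAPS",
    "Decomposition",
    "MetaboliteHit",
    "decompose_delta",
    "annotate_precursor",
    "aggregate_hits",
]

#: Default per-residue caps beyond the backbone (observed maxima in plant
#: phase-II conjugation of diclofenac); water loss is carried by the lactam
#: backbones and disabled here by default.
DEFAULT_CAPS: Dict[str, int] = {"OH": 2, "Glc": 2, "GlcA": 1, "Mal": 2, "H2O-loss": 0}


@dataclass(frozen=True)
class Decomposition:
    """One residue multiset explaining a precursor-minus-backbone delta."""

    mods: Tuple[Tuple[str, int], ...]
    delta_mass: float
    ppm: float

    @property
    def size(self) -> int:
        return sum(n for _, n in self.mods)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.mods)


@dataclass
class MetaboliteHit:
    """A named, formula-assigned metabolite with its supporting evidence."""

    name: str
    formula: str
    backbone: str
    modifications: Dict[str, int]
    mz_observed: float
    mz_theoretical: float
    delta_ppm: float
    rt: float
    dt: float
    ccs: Optional[float] = None
    delta_mz_observed: Optional[float] = None
    fragments: List[str] = field(default_factory=list)
    alternatives: List[str] = field(default_factory=list)
    sample: Optional[str] = None
    replicate: int = 0


def decompose_delta(
    delta_mass: float,
    ref_mass: float,
    library: Mapping[str, Modification] = MODIFICATIONS,
    tol_ppm: float = 5.0,
    caps: Optional[Mapping[str, int]] = None,
) -> List[Decomposition]:
    """All residue multisets whose summed mass matches ``delta_mass``.

    The tolerance is evaluated on the precursor mass scale ``ref_mass`` (a
    5 ppm window on a 600 Da precursor is 3 mDa regardless of how small the
    delta itself is).  Results are sorted by |ppm| then multiset size; an
    empty list means the delta is unassignable within the caps.
    """
    if ref_mass <= 0:
        raise ValueError("ref_mass must be positive")
    if caps is None:
        caps = DEFAULT_CAPS
    names: List[str] = []
    masses: List[float] = []
    ranges: List[range] = []
    for name, mod in library.items():
        cap = caps.get(name, mod.default_max_count)
        if cap < 0:
            raise ValueError(f"negative cap for modification {name!r}")
        names.append(name)
        masses.append(mod.delta_mass)
        ranges.append(range(cap + 1))
    tol = tol_ppm * 1e-6 * ref_mass
    out: List[Decomposition] = []
    for counts in itertools.product(*ranges):
        total = sum(m * c for m, c in zip(masses, counts))
        if abs(delta_mass - total) <= tol:
            mods = tuple((n, c) for n, c in zip(names, counts) if c)
            out.append(
                Decomposition(
                    mods=mods,
                    delta_mass=total,
                    ppm=(delta_mass - total) / ref_mass * 1e6,
                )
            )
    out.sort(key=lambda d: (abs(d.ppm), d.size))
    return out


def annotate_precursor(
    precursor: Feature,
    backbone: Backbone,
    library: Mapping[str, Modification] = MODIFICATIONS,
    tol_ppm: float = 5.0,
    caps: Optional[Mapping[str, int]] = None,
    anchor_mz_observed: Optional[float] = None,
) -> Optional[MetaboliteHit]:
    """Turn a selected precursor into a named metabolite hit.

    The delta between the observed precursor m/z and the *theoretical*
    backbone fragment m/z is decomposed; the best decomposition (smallest
    |ppm|, then smallest multiset) becomes the hit and the rest are kept as
    alternative names.  Returns ``None`` when nothing matches — the family
    is drug-related (it produced the fragment) but not explainable within
    the residue caps.
    """
    delta = precursor.mz - backbone.fragment_mz
    decomps = decompose_delta(delta, precursor.mz, library, tol_ppm, caps)
    if not decomps:
        return None
    best = decomps[0]
    composition = compose(backbone, best.as_dict(), library, caps)
    theoretical = ion_mz(composition.formula, z=1)
    alternatives = [
        compose(backbone, d.as_dict(), library, caps).name for d in decomps[1:]
    ]
    return MetaboliteHit(
        name=composition.name,
        formula=composition.formula.hill(),
        backbone=backbone.name,
        modifications=best.as_dict(),
        mz_observed=precursor.mz,
        mz_theoretical=theoretical,
        delta_ppm=ppm_error(precursor.mz, theoretical),
        rt=precursor.rt_apex,
        dt=precursor.dt_apex,
        ccs=precursor.ccs,
        delta_mz_observed=(
            precursor.mz - anchor_mz_observed
            if anchor_mz_observed is not None
            else None
        ),
        alternatives=alternatives,
    )


def aggregate_hits(
    hits: Sequence[MetaboliteHit],
    rt_window: float = 0.15,
    dt_window: float = 0.4,
    samples: Optional[Sequence[str]] = None,
) -> List[ReportRow]:
    """Merge replicate/sample hits into report rows.

    Hits sharing a name are clustered greedily in (retention time, drift
    time); same-name hits at a distinct retention time *or* a distinct
    drift time stay separate rows — isomeric conjugates can co-elute and
    differ only in their mobility.  Each row carries the detection count,
    CCS mean and relative standard deviation, and the per-sample presence
    map.  Rows are ordered by descending observed m/z.
    """
    by_name: Dict[str, List[MetaboliteHit]] = {}
    for hit in hits:
        by_name.setdefault(hit.name, []).append(hit)
    rows: List[ReportRow] = []
    for name in by_name:
        clusters: List[List[MetaboliteHit]] = []
        for hit in sorted(by_name[name], key=lambda h: (h.rt, h.dt)):
            placed = False
            for cluster in clusters:
                rt0 = float(np.mean([h.rt for h in cluster]))
                dt0 = float(np.mean([h.dt for h in cluster]))
                if abs(hit.rt - rt0) <= rt_window and abs(hit.dt - dt0) <= dt_window:
                    cluster.append(hit)
                    placed = True
                    break
            if not placed:
                clusters.append([hit])
        for cluster in clusters:
            mz_mean = float(np.mean([h.mz_observed for h in cluster]))
            theo = cluster[0].mz_theoretical
            ccs_values = [h.ccs for h in cluster if h.ccs is not None]
            ccs_mean = float(np.mean(ccs_values)) if ccs_values else None
            ccs_rsd = (
                float(np.std(ccs_values) / np.mean(ccs_values) * 100.0)
                if len(ccs_values) > 1
                else (0.0 if ccs_values else None)
            )
            presence = {h.sample: True for h in cluster if h.sample is not None}
            rows.append(
                ReportRow(
                    name=name,
                    formula=cluster[0].formula,
                    rt=float(np.mean([h.rt for h in cluster])),
                    mz_observed=mz_mean,
                    delta_ppm=ppm_error(mz_mean, theo),
                    ccs_mean=ccs_mean,
                    ccs_rsd=ccs_rsd,
                    n_detections=len(cluster),
                    presence=presence,
                )
            )
    rows.sort(key=lambda r: -r.mz_observed)
    if samples is not None:
        for row in rows:
            row.presence = {s: row.presence.get(s, False) for s in samples}
    return rows
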