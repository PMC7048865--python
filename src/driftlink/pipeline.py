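"""End-to-end screen: frames -> features -> anchors -> groups -> hits -> report.

One function per granularity: :func:`screen_frames` processes a single run
and returns hits; :func:`run_screen` processes a whole study (many runs),
aggregates replicate hits into report rows and produces a decision log that
mirrors the manual evaluation narrative (which spots were linked, which
were excluded on drift time, which deltas were decomposed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .annotate import DEFAULT_CAPS, MetaboliteHit, aggregate_hits, annotate_precursor
from .ccs import CCSCalibration, dt_to_ccs
from .chem import BACKBONES, MODIFICATIONS, Backbone, Modification
from .iodata import FrameTable, ReportRow
from .linker import co_drift_group, corroborate, find_anchors, select_precursor
from .peaks import detect_features

__all__ = ["ScreenConfig", "screen_frames", "run_screen"]


@dataclass
class ScreenConfig:
    """All tunable thresholds of the screen, with screening defaults.

    Tolerances: ``frag_tol_ppm`` for anchoring the characteristic fragment,
    ``dt_tol_ms`` for co-drift grouping, ``precursor_tol_ppm`` for residue
    decomposition of the precursor delta and ``loss_tol_ppm`` for
    corroborating intermediate fragments.  Feature-extraction filters follow
    the standard screening settings (intensity >= 100, rt 2-10 min,
    charge <= 3).
    """

    eic_tol_ppm: float = 20.0
    frag_tol_ppm: float = 10.0
    dt_tol_ms: float = 0.05
    precursor_tol_ppm: float = 5.0
    loss_tol_ppm: float = 10.0
    min_intensity: float = 100.0
    rt_range: Tuple[float, float] = (2.0, 10.0)
    max_charge: int = 3
    rt_half_window: float = 0.1
    singleton_relax_factor: float = 2.0
    agg_rt_window: float = 0.15
    agg_dt_window: float = 0.4
    caps: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CAPS))
    backbones: Mapping[str, Backbone] = field(default_factory=lambda: dict(BACKBONES))
    modifications: Mapping[str, Modification] = field(
        default_factory=lambda: dict(MODIFICATIONS)
    )

    def __post_init__(self) -> None:
        for key in (
            "eic_tol_ppm",
            "frag_tol_ppm",
            "dt_tol_ms",
            "precursor_tol_ppm",
            "loss_tol_ppm",
            "min_intensity",
        ):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")


def screen_frames(
    frames: FrameTable,
    config: Optional[ScreenConfig] = None,
    calibration: Optional[CCSCalibration] = None,
    sample: Optional[str] = None,
    replicate: int = 0,
    log: Optional[List[str]] = None,
) -> List[MetaboliteHit]:
    """Screen one acquisition run for drug-related ion families."""
    cfg = config or ScreenConfig()
    if log is None:
        log = []
    features = detect_features(
        frames,
        min_intensity=cfg.min_intensity,
        rt_range=cfg.rt_range,
        max_charge=cfg.max_charge,
    )
    run_label = f"{sample or 'run'}/r{replicate}"
    log.append(f"[{run_label}] {len(frames)} records -> {len(features)} features")
    anchors = find_anchors(features, cfg.backbones, cfg.frag_tol_ppm)
    hits: List[MetaboliteHit] = []
    for anchor in anchors:
        group = co_drift_group(
            features,
            anchor,
            dt_tol_ms=cfg.dt_tol_ms,
            rt_half_window=cfg.rt_half_window,
        )
        if len(group.members) == 1 and cfg.singleton_relax_factor > 1.0:
            # A backbone fragment must come from some precursor.  Before
            # concluding the anchor IS the intact parent, retry with a
            # relaxed drift window (measurement precision), which can only
            # extend a singleton group, never override a found precursor.
            relaxed = co_drift_group(
                features,
                anchor,
                dt_tol_ms=cfg.dt_tol_ms * cfg.singleton_relax_factor,
                rt_half_window=cfg.rt_half_window,
            )
            if len(relaxed.members) > 1:
                group = relaxed
                log.append(
                    f"[{run_label}] anchor {anchor.backbone.name} @ rt "
                    f"{anchor.rt_apex:.2f}: singleton group extended at relaxed "
                    f"drift tolerance {relaxed.dt_tol_ms:.2f} ms"
                )
        precursor = select_precursor(group)
        excluded = [
            f
            for f in features
            if abs(f.rt_apex - anchor.rt_apex) <= cfg.rt_half_window
            and f not in group.members
        ]
        log.append(
            f"[{run_label}] anchor {anchor.backbone.name} @ rt {anchor.rt_apex:.2f} "
            f"min, dt {anchor.dt:.2f} ms: {len(group.members)} co-drifting member(s) "
            f"{[round(f.mz, 4) for f in group.members]}, "
            f"{len(excluded)} co-eluting ion(s) excluded on drift time"
        )
        hit = annotate_precursor(
            precursor,
            anchor.backbone,
            cfg.modifications,
            tol_ppm=cfg.precursor_tol_ppm,
            caps=cfg.caps,
            anchor_mz_observed=anchor.mz,
        )
        if hit is None:
            log.append(
                f"[{run_label}]   precursor {precursor.mz:.4f}: delta "
                f"{precursor.mz - anchor.backbone.fragment_mz:.4f} unassignable "
                f"within caps"
            )
            continue
        notes = corroborate(
            group, precursor, cfg.modifications, tol_ppm=cfg.loss_tol_ppm
        )
        hit.fragments = [
            f"{note.mz:.4f}: {'; '.join(note.labels) if note.labels else 'unexplained'}"
            for note in notes
        ]
        if calibration is not None:
            hit.ccs = dt_to_ccs(calibration, precursor.dt_apex, precursor.mz, 1)
        hit.sample = sample
        hit.replicate = replicate
        log.append(
            f"[{run_label}]   precursor {precursor.mz:.4f} -> {hit.name} "
            f"({hit.formula}, {hit.delta_ppm:+.1f} ppm)"
        )
        hits.append(hit)
    # one hit per (name, rt neighbourhood) per run: drop weaker duplicates
    deduped: Dict[Tuple[str, float], MetaboliteHit] = {}
    for hit in hits:
        key = (hit.name, round(hit.rt, 1))
        prev = deduped.get(key)
        if prev is None or abs(hit.delta_ppm) < abs(prev.delta_ppm):
            deduped[key] = hit
    return list(deduped.values())


def run_screen(
    runs: Iterable[Tuple[Optional[str], int, FrameTable]],
    config: Optional[ScreenConfig] = None,
    calibration: Optional[CCSCalibration] = None,
) -> Tuple[List[MetaboliteHit], List[ReportRow], List[str]]:
    """Screen a study of runs and aggregate hits into report rows."""
    cfg = config or ScreenConfig()
    log: List[str] = []
    hits: List[MetaboliteHit] = []
    samples: List[str] = []
    for sample, replicate, frames in runs:
        if sample is not None and sample not in samples:
            samples.append(sample)
        hits.extend(
            screen_frames(frames, cfg, calibration, sample, replicate, log)
        )
    rows = aggregate_hits(
        hits,
        rt_window=cfg.agg_rt_window,
        dt_window=cfg.agg_dt_window,
        samples=samples or None,
    )
    log.append(f"aggregated {len(hits)} hit(s) into {len(rows)} report row(s)")
    return hits, rows, log
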