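"""Synthetic all-ions LC-DTIM frame generator with ground truth.

Emulates the data shape the screen consumes: for every metabolite present
in a run, a Gaussian chromatographic profile of the intact precursor plus
co-drifting fragment ions (identical drift time — fragmentation happens
after the drift tube), on a regular retention-time grid, with matrix
interferents at unrelated drift times and a sub-threshold noise floor.

Three fixed scenarios reproduce the published worked examples:

* ``fig1_scenario`` — the DCF-Glc-Mal family at rt 6.8 min / DT 28.66 ms,
  with water-loss and ketene-adduct satellites and lower-DT matrix ions;
* ``fig2_scenario`` — the DCF-Lac-OH-Glc-GlcA family at rt 4.1 min /
  DT 31.74 ms, with a more intense co-eluting interferent at m/z 679.5136
  at a different drift time;
* ``table1_scenario`` — all 31 reference species (parent drug + 30
  metabolites) with their printed retention times, observed m/z, CCS and
  per-plant presence across 9 root-extract samples in triplicate.

Drift times derive from CCS through a fixed single-field calibration
obtained by an exact fit through the two worked-example anchor points, so
CCS values measured back from the simulated data land on the printed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ccs import CalibrationReference, CCSCalibration, ccs_to_dt, fit_single_field
from .chem import BACKBONES, MODIFICATIONS, compose, parse_metabolite_name
from .iodata import FrameTable, FRAME_COLUMNS

__all__ = [
    "SAMPLES",
    "TABLE1_ROWS",
    "DEFAULT_CALIBRATION",
    "SimSpecies",
    "Interferent",
    "SimConfig",
    "SimConfigError",
    "simulate_dataset",
    "simulate_study",
    "truth_table",
    "fig1_scenario",
    "fig2_scenario",
    "table1_scenario",
    "random_scenario",
]

#: The nine root-extract samples, in report column order.
SAMPLES = (
    "salad",
    "tomato",
    "onion",
    "millet",
    "sorghum",
    "maize",
    "pea",
    "amaranth",
    "rice",
)

#: Reference ground truth for the 31-species recovery scenario:
#: (name, formula, rt min, observed m/z, CCS A^2, replicate detections per
#: sample).  Detection counts not divisible by three indicate a replicate
#: missing from the last-listed positive sample.
TABLE1_ROWS: List[Tuple[str, str, float, float, float, Tuple[int, ...]]] = [
    ("DCF-OH-Glc-Glc-Mal-Mal", "C32H35Cl2NO19", 4.9, 808.1252, 264.5, (3, 0, 3, 0, 0, 0, 0, 3, 0)),
    ("DCF-Glc-Glc-Mal-Mal", "C32H35Cl2NO18", 6.3, 792.1314, 250.5, (0, 0, 3, 0, 0, 0, 0, 0, 0)),
    ("DCF-OH-Glc-Glc-Mal", "C29H33Cl2NO16", 5.4, 722.1257, 249.4, (0, 3, 0, 0, 0, 0, 0, 0, 0)),
    ("DCF-OH-Glc-Glc-Mal", "C29H33Cl2NO16", 5.3, 722.1253, 258.7, (0, 0, 0, 0, 0, 0, 0, 0, 3)),
    ("DCF-OH-Glc-Glc-Mal", "C29H33Cl2NO16", 4.1, 722.1250, 255.8, (3, 3, 3, 0, 3, 3, 0, 3, 3)),
    ("DCF-Glc-GlcA-Mal", "C29H31Cl2NO16", 6.0, 720.1100, 248.2, (0, 0, 0, 0, 0, 0, 0, 3, 0)),
    ("DCF-Glc-Glc-Mal", "C29H33Cl2NO15", 5.8, 706.1302, 243.9, (0, 3, 3, 0, 3, 0, 0, 0, 3)),
    ("DCF-Glc-Glc-Mal", "C29H33Cl2NO15", 6.4, 706.1295, 245.7, (0, 0, 0, 0, 3, 0, 0, 0, 0)),
    ("DCF-Glc-Glc-Mal", "C29H33Cl2NO15", 6.3, 706.1291, 253.6, (0, 0, 0, 0, 0, 2, 0, 0, 0)),
    ("DCF-Lac-OH-Glc-Glc-Mal", "C29H31Cl2NO15", 5.2, 704.1139, 253.7, (0, 0, 0, 0, 3, 0, 0, 0, 3)),
    ("DCF-OH-Glc-GlcA", "C26H29Cl2NO14", 5.6, 650.1049, 233.7, (0, 0, 0, 0, 0, 3, 0, 0, 0)),
    ("DCF-OH-Glc-GlcA", "C26H29Cl2NO14", 4.2, 650.1047, 234.1, (0, 0, 0, 0, 0, 3, 0, 0, 0)),
    ("DCF-OH-Glc-Glc", "C26H31Cl2NO13", 4.1, 636.1251, 229.5, (0, 3, 0, 0, 0, 0, 0, 0, 0)),
    ("DCF-OH-Glc-Glc", "C26H31Cl2NO13", 3.0, 636.1250, 234.1, (0, 0, 0, 0, 0, 3, 2, 0, 0)),
    ("DCF-OH-Glc-Glc", "C26H31Cl2NO13", 3.0, 636.1248, 229.1, (0, 0, 0, 3, 3, 0, 0, 0, 3)),
    ("DCF-Glc-GlcA", "C26H29Cl2NO13", 5.3, 634.1088, 235.5, (0, 0, 0, 0, 0, 0, 0, 3, 0)),
    ("DCF-Lac-OH-Glc-GlcA", "C26H27Cl2NO13", 4.1, 632.0943, 233.4, (0, 0, 0, 0, 0, 3, 0, 0, 0)),
    ("DCF-Glc-Glc", "C26H31Cl2NO12", 5.2, 620.1299, 232.1, (0, 3, 0, 0, 0, 0, 0, 0, 0)),
    ("DCF-Lac-OH-Glc-Glc", "C26H29Cl2NO12", 5.4, 618.1140, 229.7, (0, 3, 0, 3, 3, 3, 3, 3, 0)),
    ("DCF-Lac-Glc-Glc", "C26H29Cl2NO11", 5.4, 602.1189, 230.5, (3, 3, 2, 0, 0, 0, 0, 0, 0)),
    ("DCF-OH-Glc-Mal", "C23H23Cl2NO11", 5.7, 560.0724, 214.2, (3,) * 9),
    ("DCF-Glc-Mal", "C23H23Cl2NO10", 6.7, 544.0770, 211.6, (3, 3, 3, 3, 3, 3, 3, 2, 0)),
    ("DCF-Lac-OH-Glc-Mal", "C23H21Cl2NO10", 5.5, 542.0618, 210.8, (3, 0, 3, 3, 3, 3, 3, 3, 3)),
    ("DCF-diOH-Glc", "C20H21Cl2NO9", 3.5, 490.0650, 216.2, (0, 3, 0, 0, 0, 0, 0, 0, 0)),
    ("DCF-diOH-Glc", "C20H21Cl2NO9", 3.6, 490.0670, 212.4, (0, 0, 0, 3, 3, 3, 3, 0, 0)),
    ("DCF-OH-Glc", "C20H21Cl2NO8", 4.9, 474.0720, 211.4, (3,) * 9),
    ("DCF-Lac-OH-Glc", "C20H19Cl2NO7", 4.7, 456.0614, 197.5, (0, 0, 0, 3, 3, 3, 3, 3, 3)),
    ("DCF-OH", "C14H11Cl2NO3", 7.9, 312.0191, 164.4, (3,) * 9),
    ("DCF", "C14H11Cl2NO2", 8.6, 296.0244, 159.3, (3,) * 9),
    ("DCF-Lac-OH", "C14H9Cl2NO2", 7.6, 294.0088, 159.5, (3, 3, 0, 3, 3, 3, 3, 3, 3)),
    ("DCF-Lac", "C14H9Cl2NO", 7.6, 278.0139, 154.6, (3,) * 9),
]

#: Fixed single-field calibration anchored on the two worked-example ion
#: families: (m/z 544.0788, 211.6 A^2) at 28.66 ms and (m/z 632.0942,
#: 233.4 A^2) at 31.74 ms.
DEFAULT_CALIBRATION: CCSCalibration = fit_single_field(
    [
        CalibrationReference(mz=544.0788, z=1, ccs=211.6, dt_ms=28.66),
        CalibrationReference(mz=632.0942, z=1, ccs=233.4, dt_ms=31.74),
    ]
)


class SimConfigError(ValueError):
    """Invalid simulation configuration (e.g. species outside the gradient)."""


@dataclass(frozen=True)
class SimSpecies:
    """One ground-truth ion family.

    ``mz`` is the precursor m/z actually emitted (an "observed" value may be
    given to emulate instrument bias; otherwise callers pass the theoretical
    value).  Drift time comes from ``dt_ms`` when given, else from ``ccs``
    through the configured calibration.  ``fragments`` lists (m/z, relative
    intensity) satellites that share the precursor's drift time.
    ``presence`` maps sample name -> number of detecting replicates; ``None``
    means present in every run.
    """

    name: str
    rt_apex: float
    mz: float
    intensity: float = 5000.0
    ccs: Optional[float] = None
    dt_ms: Optional[float] = None
    fragments: Tuple[Tuple[float, float], ...] = ()
    presence: Optional[Dict[str, int]] = None

    def drift_time(self, cal: CCSCalibration) -> float:
        if self.dt_ms is not None:
            return self.dt_ms
        if self.ccs is None:
            raise SimConfigError(f"species {self.name!r} has neither dt_ms nor ccs")
        return ccs_to_dt(cal, self.ccs, self.mz, 1)


@dataclass(frozen=True)
class Interferent:
    """A fixed matrix ion: one chromatographic peak at its own drift time."""

    rt_apex: float
    dt_ms: float
    mz: float
    intensity: float


@dataclass
class SimConfig:
    """Full description of a simulated acquisition (or study of runs)."""

    species: List[SimSpecies]
    interferents: List[Interferent] = field(default_factory=list)
    n_random_interferents: int = 0
    interferent_mz_range: Tuple[float, float] = (250.0, 780.0)
    interferent_dt_range: Tuple[float, float] = (18.0, 40.0)
    interferent_min_dt_offset: float = 0.5
    n_noise_specks: int = 0
    dt_jitter_ms: float = 0.0
    mz_noise_ppm: float = 0.0
    noise_floor: float = 10.0
    seed: int = 0
    calibration: CCSCalibration = DEFAULT_CALIBRATION
    rt_min: float = 0.0
    rt_max: float = 13.0
    rt_step: float = 0.0185  # ~0.9 frames per second
    peak_sigma_min: float = 0.05
    samples: Optional[Tuple[str, ...]] = None
    replicates: int = 1

    def __post_init__(self) -> None:
        for sp in self.species:
            if not (self.rt_min <= sp.rt_apex <= self.rt_max):
                raise SimConfigError(
                    f"species {sp.name!r} rt {sp.rt_apex} outside gradient "
                    f"[{self.rt_min}, {self.rt_max}]"
                )


def _gaussian_profile(
    cfg: SimConfig, rt_apex: float, height: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Sampled chromatographic peak on the regular rt grid, floor-trimmed."""
    sigma = cfg.peak_sigma_min
    half = 4.0 * sigma
    i0 = int(np.ceil(max(cfg.rt_min, rt_apex - half) / cfg.rt_step))
    i1 = int(np.floor(min(cfg.rt_max, rt_apex + half) / cfg.rt_step))
    grid = np.round(np.arange(i0, i1 + 1) * cfg.rt_step, 6)
    profile = height * np.exp(-0.5 * ((grid - rt_apex) / sigma) ** 2)
    keep = profile >= cfg.noise_floor
    return grid[keep], profile[keep]


def _emit_family(
    cfg: SimConfig,
    rng: np.random.Generator,
    rt_apex: float,
    dt_base: float,
    ions: Sequence[Tuple[float, float]],
    records: List[Tuple[float, float, float, float]],
) -> None:
    for mz, height in ions:
        grid, profile = _gaussian_profile(cfg, rt_apex, height)
        for rt, inten in zip(grid, profile):
            dt = dt_base + (
                rng.normal(0.0, cfg.dt_jitter_ms) if cfg.dt_jitter_ms > 0 else 0.0
            )
            mz_i = mz * (
                1.0 + (rng.normal(0.0, cfg.mz_noise_ppm) * 1e-6 if cfg.mz_noise_ppm > 0 else 0.0)
            )
            records.append((rt, dt, mz_i, inten))


def _species_in_run(
    cfg: SimConfig, sample: Optional[str], replicate: int
) -> List[SimSpecies]:
    out = []
    for sp in cfg.species:
        if sp.presence is None or sample is None:
            out.append(sp)
        elif replicate < sp.presence.get(sample, 0):
            out.append(sp)
    return out


def _avoid_mzs() -> List[float]:
    return [b.fragment_mz for b in BACKBONES.values()]


def simulate_dataset(
    cfg: SimConfig, sample: Optional[str] = None, replicate: int = 0
) -> FrameTable:
    """Render one acquisition run to a frame table.

    The configuration seed (combined with the sample and replicate indices)
    fixes the output bit-for-bit.  Random interferents are drawn away from
    every true family's drift time by at least ``interferent_min_dt_offset``
    and away from the backbone fragment m/z windows, emulating matrix ions
    unrelated to the drug.
    """
    sample_idx = cfg.samples.index(sample) if (cfg.samples and sample) else 0
    rng = np.random.default_rng([cfg.seed, sample_idx, replicate])
    records: List[Tuple[float, float, float, float]] = []
    present = _species_in_run(cfg, sample, replicate)
    species_dts = []
    for sp in present:
        dt_base = sp.drift_time(cfg.calibration)
        species_dts.append(dt_base)
        ions = [(sp.mz, sp.intensity)]
        ions.extend((mz, rel * sp.intensity) for mz, rel in sp.fragments)
        _emit_family(cfg, rng, sp.rt_apex, dt_base, ions, records)
    for intf in cfg.interferents:
        _emit_family(
            cfg, rng, intf.rt_apex, intf.dt_ms, [(intf.mz, intf.intensity)], records
        )
    avoid = _avoid_mzs()
    for _ in range(cfg.n_random_interferents):
        rt_apex = round(
            rng.uniform(2.2, 9.8) / cfg.rt_step
        ) * cfg.rt_step
        for _attempt in range(100):
            dt = rng.uniform(*cfg.interferent_dt_range)
            if all(abs(dt - d) >= cfg.interferent_min_dt_offset for d in species_dts):
                break
        for _attempt in range(100):
            mz = rng.uniform(*cfg.interferent_mz_range)
            if all(abs(mz - a) > 0.05 for a in avoid):
                break
        height = float(rng.uniform(120.0, 8000.0))
        _emit_family(cfg, rng, rt_apex, dt, [(mz, height)], records)
    for _ in range(cfg.n_noise_specks):
        records.append(
            (
                round(rng.uniform(cfg.rt_min, cfg.rt_max) / cfg.rt_step) * cfg.rt_step,
                rng.uniform(*cfg.interferent_dt_range),
                rng.uniform(*cfg.interferent_mz_range),
                rng.uniform(cfg.noise_floor, 99.0),
            )
        )
    df = pd.DataFrame(records, columns=list(FRAME_COLUMNS))
    metadata = {
        "collision_energy_V": 5.0,
        "drift_gas": "N2",
        "polarity": "positive",
        "sample": sample,
        "replicate": replicate,
    }
    return FrameTable(df, metadata)


def simulate_study(cfg: SimConfig) -> Iterator[Tuple[str, int, FrameTable]]:
    """Yield (sample, replicate, frames) for every run of a multi-sample study."""
    samples = cfg.samples or (None,)
    for sample in samples:
        for replicate in range(cfg.replicates):
            yield sample, replicate, simulate_dataset(cfg, sample, replicate)


def truth_table(cfg: SimConfig) -> pd.DataFrame:
    """Ground-truth species table for a configuration (one row per species)."""
    rows = []
    for sp in cfg.species:
        rows.append(
            {
                "name": sp.name,
                "rt_min": sp.rt_apex,
                "mz": sp.mz,
                "dt_ms": sp.drift_time(cfg.calibration),
                "ccs": sp.ccs,
                "intensity": sp.intensity,
                "n_expected": (
                    sum(sp.presence.values()) if sp.presence else cfg.replicates
                ),
            }
        )
    return pd.DataFrame(rows)


_WATER = 18.0105646219  # monoisotopic H2O, for satellite arithmetic


def fig1_scenario() -> SimConfig:
    """The first worked example: DCF-Glc-Mal in an onion extract.

    One family at rt 6.8 min, drift time 28.66 ms: precursor 544.0788,
    backbone fragment 296.0249, two water losses and the ketene-adduct
    satellite; matrix ions co-elute at clearly lower drift times, some of
    them heavier than the precursor.  Noise off — the fixture is exact.
    """
    precursor = 544.0788
    species = SimSpecies(
        name="DCF-Glc-Mal",
        rt_apex=6.8,
        mz=precursor,
        intensity=8000.0,
        dt_ms=28.66,
        fragments=(
            (296.0249, 0.50),
            (round(precursor - _WATER, 4), 0.15),
            (round(precursor - 2 * _WATER, 4), 0.08),
            (338.0355, 0.12),
        ),
    )
    interferents = [
        Interferent(6.80, 24.10, 609.2803, 6000.0),
        Interferent(6.80, 22.90, 420.1500, 3000.0),
        Interferent(6.78, 25.50, 337.1000, 2500.0),
        Interferent(6.82, 23.30, 571.3000, 1500.0),
        Interferent(6.80, 26.20, 499.2000, 1200.0),
    ]
    return SimConfig(species=[species], interferents=interferents, seed=11)


def fig2_scenario() -> SimConfig:
    """The second worked example: DCF-Lac-OH-Glc-GlcA in a maize extract.

    Family at rt 4.1 min, drift time 31.74 ms with members 294.0087,
    456.0610 and 632.0942 (losses of a glucuronyl and a glucosyl residue);
    the most abundant co-eluting ion, m/z 679.5136, sits at a different
    drift time and must be rejected.  Noise off.
    """
    species = SimSpecies(
        name="DCF-Lac-OH-Glc-GlcA",
        rt_apex=4.1,
        mz=632.0942,
        intensity=5000.0,
        dt_ms=31.74,
        fragments=((294.0087, 0.60), (456.0610, 0.35)),
    )
    interferents = [
        Interferent(4.10, 35.21, 679.5136, 20000.0),
        Interferent(4.10, 27.40, 415.2100, 4000.0),
        Interferent(4.12, 29.00, 550.6000, 2000.0),
    ]
    return SimConfig(species=[species], interferents=interferents, seed=12)


def _table1_species() -> List[SimSpecies]:
    species = []
    for i, (name, formula, rt, mz_obs, ccs, counts) in enumerate(TABLE1_ROWS):
        backbone, mods = parse_metabolite_name(name)
        composition = compose(backbone, mods)
        if composition.formula.hill() != formula:
            raise SimConfigError(
                f"ground-truth formula mismatch for {name}: "
                f"{composition.formula.hill()} != {formula}"
            )
        fragments: Tuple[Tuple[float, float], ...] = ()
        if mods:  # conjugates emit their characteristic backbone fragment
            fragments = ((round(backbone.fragment_mz, 4), 0.40),)
        species.append(
            SimSpecies(
                name=name,
                rt_apex=rt,
                mz=mz_obs,
                intensity=3000.0 + 150.0 * i,
                ccs=ccs,
                fragments=fragments,
                presence=dict(zip(SAMPLES, counts)),
            )
        )
    return species


def table1_scenario(
    seed: int = 17, dt_jitter_ms: float = 0.03, mz_noise_ppm: float = 1.0
) -> SimConfig:
    """The 31-species recovery scenario: 9 samples x 3 replicates.

    Species carry their printed retention time, observed m/z, CCS and
    per-plant presence; drift times follow from CCS through the fixed
    calibration.  Default noise levels: 0.03 ms drift jitter and 1 ppm m/z
    noise per record, plus random matrix interferents and sub-threshold
    noise specks per run.
    """
    return SimConfig(
        species=_table1_species(),
        n_random_interferents=40,
        n_noise_specks=30,
        dt_jitter_ms=dt_jitter_ms,
        mz_noise_ppm=mz_noise_ppm,
        seed=seed,
        samples=tuple(SAMPLES),
        replicates=3,
    )


def random_scenario(
    seed: int = 0, n_species: int = 5, dt_jitter_ms: float = 0.03, mz_noise_ppm: float = 1.0
) -> SimConfig:
    """A randomized single-run scenario drawn from the reference species."""
    rng = np.random.default_rng(seed)
    pool = _table1_species()
    idx = rng.choice(len(pool), size=min(n_species, len(pool)), replace=False)
    chosen = [replace(pool[int(i)], presence=None) for i in idx]
    return SimConfig(
        species=chosen,
        n_random_interferents=25,
        n_noise_specks=20,
        dt_jitter_ms=dt_jitter_ms,
        mz_noise_ppm=mz_noise_ppm,
        seed=seed,
    )
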