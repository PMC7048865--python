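"""Single-field drift-time <-> collision-cross-section conversion.

A drift-tube ion-mobility measurement at one fixed field relates the drift
time of an ion linearly to its collision cross section (CCS) once charge and
reduced mass are factored out:

    dt = beta * gamma * CCS + t_fix,      gamma = sqrt(m M / (m + M)) / z

where m is the ion's neutral monoisotopic mass, M the drift-gas mass
(nitrogen by default) and z the charge.  ``beta`` absorbs field strength,
gas density and temperature; ``t_fix`` is the mobility-independent transit
time outside the drift region.  Both are obtained from a tune-mix-style
calibration: reference ions of known CCS measured once at the working field.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import PROTON_MASS

__all__ = [
    "GAS_MASS_N2",
    "CalibrationError",
    "CalibrationReference",
    "CCSCalibration",
    "reduced_mass_term",
    "fit_single_field",
    "dt_to_ccs",
    "ccs_to_dt",
]

#: Monoisotopic mass of N2 (Da), the default drift gas.
GAS_MASS_N2 = 28.00615


class CalibrationError(ValueError):
    """Too few or degenerate reference points for a single-field fit."""


@dataclass(frozen=True)
class CalibrationReference:
    """One tune-mix reference ion: m/z, charge, published CCS, measured DT."""

    mz: float
    z: int
    ccs: float
    dt_ms: float

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError("reference charge must be >= 1")
        if self.ccs <= 0:
            raise ValueError("reference CCS must be positive")


@dataclass(frozen=True)
class CCSCalibration:
    """Fitted single-field model ``dt = beta * gamma * ccs + t_fix``.

    ``beta`` is in ms per (A^2 * sqrt(Da)); ``t_fix`` in ms.  The label of
    the drift gas travels with the calibration so reported values can be
    tagged (e.g. DT-CCS in N2).
    """

    beta: float
    t_fix: float
    drift_gas_mass: float = GAS_MASS_N2
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if not (self.beta > 0):
            raise CalibrationError("beta must be positive")
        if not math.isfinite(self.residual_rms):
            raise CalibrationError("residual RMS must be finite")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(
                {
                    "beta": self.beta,
                    "t_fix": self.t_fix,
                    "drift_gas_mass": self.drift_gas_mass,
                    "residual_rms": self.residual_rms,
                },
                handle,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CCSCalibration":
        with open(path, "r", encoding="utf-8") as handle:
            payload = json.load(handle)
        return cls(**payload)


def reduced_mass_term(mz: float, z: int = 1, gas_mass: float = GAS_MASS_N2) -> float:
    """Charge-normalized reduced-mass factor gamma.

    Strictly increasing in the ion mass and strictly decreasing in charge.
    The ion's neutral mass is recovered from m/z under the proton-adduct
    convention (m = mz*z - z*m_p).
    """
    if z < 1:
        raise ValueError("charge must be >= 1")
    m_ion = mz * z - z * PROTON_MASS
    if m_ion <= 0:
        raise ValueError(f"non-physical ion mass for mz={mz}, z={z}")
    return math.sqrt(m_ion * gas_mass / (m_ion + gas_mass)) / z


def fit_single_field(
    refs: Sequence[CalibrationReference], gas_mass: float = GAS_MASS_N2
) -> CCSCalibration:
    """Least-squares single-field calibration from reference ions.

    Requires at least two references with distinct gamma*CCS abscissae;
    degenerate designs raise :class:`CalibrationError`.
    """
    if len(refs) < 2:
        raise CalibrationError(
            f"single-field calibration needs >= 2 references, got {len(refs)}"
        )
    x = np.array([reduced_mass_term(r.mz, r.z, gas_mass) * r.ccs for r in refs])
    y = np.array([r.dt_ms for r in refs])
    if np.ptp(x) < 1e-9 * max(1.0, float(np.abs(x).max())):
        raise CalibrationError("degenerate references: gamma*CCS values coincide")
    beta, t_fix = np.polyfit(x, y, 1)
    residuals = y - (beta * x + t_fix)
    rms = float(np.sqrt(np.mean(residuals**2)))
    return CCSCalibration(
        beta=float(beta), t_fix=float(t_fix), drift_gas_mass=gas_mass, residual_rms=rms
    )


def dt_to_ccs(cal: CCSCalibration, dt_ms: float, mz: float, z: int = 1) -> float:
    """Convert a measured drift time to CCS (A^2) under a calibration."""
    if dt_ms <= cal.t_fix:
        raise ValueError(
            f"drift time {dt_ms} ms does not exceed t_fix {cal.t_fix} ms"
        )
    gamma = reduced_mass_term(mz, z, cal.drift_gas_mass)
    return (dt_ms - cal.t_fix) / (cal.beta * gamma)


def ccs_to_dt(cal: CCSCalibration, ccs: float, mz: float, z: int = 1) -> float:
    """Inverse of :func:`dt_to_ccs`: predicted drift time for a CCS."""
    if ccs <= 0:
        raise ValueError("CCS must be positive")
    gamma = reduced_mass_term(mz, z, cal.drift_gas_mass)
    return cal.beta * gamma * ccs + cal.t_fix
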