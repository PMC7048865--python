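"""Elemental formula arithmetic and the diclofenac conjugation library.

Everything downstream of the instrument rests on exact monoisotopic
arithmetic: the characteristic backbone fragments are matched by theoretical
m/z, neutral losses are decomposed into conjugation residues by mass, and
every reported hit carries a ppm error against its composed formula.  The
atomic mass table is fixed here (most-abundant-isotope masses, proton-adduct
convention, electron mass ignored) so that printed values round-trip at the
4-decimal convention used throughout metabolite screening reports.

The shipped library covers diclofenac (DCF) and its three phase-I backbones
(DCF-OH, DCF-Lac, DCF-Lac-OH) plus the phase-II conjugation residues seen in
plant metabolism: glucosyl (Glc), glucuronyl (GlcA), malonyl (Mal),
hydroxylation (OH) and water loss.  Other drugs can be screened by loading a
different backbone/modification library from YAML.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterator, Mapping, Optional, Tuple

import yaml

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ISOTOPE_SPACING",
    "Formula",
    "FormulaError",
    "CompositionError",
    "parse_formula",
    "ion_mz",
    "neutral_mass_from_mz",
    "ppm_error",
    "Backbone",
    "Modification",
    "BACKBONES",
    "MODIFICATIONS",
    "compose",
    "Composition",
    "canonical_name",
    "parse_metabolite_name",
    "cl2_pattern_score",
    "load_library",
    "dump_library",
]

#: Monoisotopic masses (Da) of the most abundant isotope of each supported
#: element.  Fixed values; reproduces the 4-dp report convention exactly.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Cl": 34.96885271,
    "Na": 22.9897692820,
    "S": 31.9720711744,
}

#: Mass of a proton (Da).  [M+H]+ adduct convention; electron mass ignored.
PROTON_MASS = 1.007276467

#: 13C-12C spacing (Da) used for charge inference from isotopologue peaks.
ISOTOPE_SPACING = 1.0033548378

#: IUPAC isotopic abundances of chlorine.
_CL35_ABUNDANCE = 0.7576
_CL37_ABUNDANCE = 0.2424

#: Theoretical (M+2)/M intensity ratio of a species carrying two chlorines.
CL2_M2_RATIO = 2.0 * _CL37_ABUNDANCE / _CL35_ABUNDANCE


class FormulaError(ValueError):
    """Malformed formula string, unsupported element, or invalid counts."""


class CompositionError(ValueError):
    """A backbone/modification combination that is chemically impossible."""


class Formula(Mapping[str, int]):
    """Immutable element -> count map with monoisotopic mass semantics.

    Counts are strictly positive; zero counts are dropped on construction and
    negative counts rejected.  Two formulas compare equal iff all counts are
    equal.  Addition and subtraction operate element-wise; subtraction that
    would drive any count negative raises :class:`FormulaError`.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int]):
        clean: Dict[str, int] = {}
        for element, n in counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unsupported element {element!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for element {element!r}")
            if n:
                clean[element] = n
        self._counts = dict(sorted(clean.items()))

    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == dict(other)
        return NotImplemented

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for element, n in other.items():
            merged[element] = merged.get(element, 0) + n
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for element, n in other.items():
            merged[element] = merged.get(element, 0) - n
            if merged[element] < 0:
                raise FormulaError(
                    f"subtraction leaves negative {element} count"
                )
        return Formula(merged)

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    @property
    def monoisotopic_mass(self) -> float:
        """Sum of the monoisotopic masses of all atoms (Da)."""
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self._counts.items())

    def hill(self) -> str:
        """Canonical Hill-order serialization (C, H, then alphabetical)."""
        counts = dict(self._counts)
        parts = []
        if "C" in counts:
            for el in ("C", "H"):
                if el in counts:
                    n = counts.pop(el)
                    parts.append(el if n == 1 else f"{el}{n}")
        for el in sorted(counts):
            n = counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"


_ELEMENT_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string such as ``"C14H11Cl2NO2"``.

    Repeated element tokens accumulate.  Raises :class:`FormulaError` naming
    the offending token for malformed input or unsupported elements.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: Dict[str, int] = {}
    while pos < len(text):
        match = _ELEMENT_TOKEN.match(text, pos)
        if match is None or not match.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token {text[pos:]!r}"
            )
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(
                f"unsupported element {element!r} in formula {text!r}"
            )
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(
                f"zero count for element {element!r} in formula {text!r}"
            )
        counts[element] = counts.get(element, 0) + n
        pos = match.end()
    return Formula(counts)


def ion_mz(formula: Formula, z: int = 1, n_protons: Optional[int] = None) -> float:
    """m/z of the protonated ion ``[M + n_protons·H]^z+``.

    Positive-mode proton-adduct convention: ``(M + n·m_p) / z`` where the
    neutral monoisotopic mass M is taken from the fixed atomic table and the
    electron mass is ignored.  ``n_protons`` defaults to ``z``.
    """
    if z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    if n_protons is None:
        n_protons = z
    return (formula.monoisotopic_mass + n_protons * PROTON_MASS) / z


def neutral_mass_from_mz(mz: float, z: int = 1) -> float:
    """Neutral monoisotopic mass implied by an [M+zH]^z+ ion."""
    if z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return mz * z - z * PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass deviation in ppm; observed heavier than theory is positive."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class Backbone:
    """A stable drug-derived core that survives collision-induced dissociation.

    ``base`` and ``n_hydroxyl`` factor the name into the dehydration state
    ("DCF" vs "DCF-Lac") and the hydroxylation count, which drives canonical
    naming of composed metabolites ("DCF-diOH-Glc" rather than "DCF-OH-OH-Glc").
    """

    name: str
    base: str
    n_hydroxyl: int
    neutral_formula: Formula

    @property
    def fragment_mz(self) -> float:
        """Theoretical m/z of the protonated characteristic fragment."""
        return ion_mz(self.neutral_formula, z=1)


@dataclass(frozen=True)
class Modification:
    """A conjugation residue (or loss) added to a backbone during metabolism."""

    name: str
    delta_formula: Formula
    sign: int = 1
    default_max_count: int = 2

    @property
    def delta_mass(self) -> float:
        """Signed mass change (Da) contributed per occurrence."""
        return self.sign * self.delta_formula.monoisotopic_mass


def _backbone(name: str, base: str, n_oh: int, formula: str) -> Backbone:
    return Backbone(name, base, n_oh, parse_formula(formula))


#: The four shipped diclofenac backbones, in library order.
BACKBONES: Dict[str, Backbone] = {
    b.name: b
    for b in (
        _backbone("DCF", "DCF", 0, "C14H11Cl2NO2"),
        _backbone("DCF-OH", "DCF", 1, "C14H11Cl2NO3"),
        _backbone("DCF-Lac", "DCF-Lac", 0, "C14H9Cl2NO"),
        _backbone("DCF-Lac-OH", "DCF-Lac", 1, "C14H9Cl2NO2"),
    )
}

#: Shipped conjugation residues, in canonical naming order.
MODIFICATIONS: Dict[str, Modification] = {
    m.name: m
    for m in (
        Modification("OH", parse_formula("O"), 1, 2),
        Modification("Glc", parse_formula("C6H10O5"), 1, 2),
        Modification("GlcA", parse_formula("C6H8O6"), 1, 1),
        Modification("Mal", parse_formula("C3H2O3"), 1, 2),
        Modification("H2O-loss", parse_formula("H2O"), -1, 2),
    )
}

_RESIDUE_ORDER = ("Glc", "GlcA", "Mal")


def canonical_name(base: str, n_hydroxyl: int, mods: Mapping[str, int]) -> str:
    """Compositional metabolite name: base, hydroxylation, then residues.

    Suffix order is fixed by library order (OH before Glc before GlcA before
    Mal) and is independent of attachment sites — positional isomers share a
    name.  Two hydroxyls render as "diOH".
    """
    parts = [base]
    if n_hydroxyl == 1:
        parts.append("OH")
    elif n_hydroxyl == 2:
        parts.append("diOH")
    elif n_hydroxyl > 2:
        parts.append(f"{n_hydroxyl}OH")
    for residue in _RESIDUE_ORDER:
        parts.extend([residue] * mods.get(residue, 0))
    parts.extend(["H2O-loss"] * mods.get("H2O-loss", 0))
    return "-".join(parts)


@dataclass(frozen=True)
class Composition:
    """A composed metabolite: neutral formula plus canonical name."""

    formula: Formula
    name: str


def compose(
    backbone: Backbone,
    mods: Mapping[str, int],
    library: Mapping[str, Modification] = MODIFICATIONS,
    caps: Optional[Mapping[str, int]] = None,
) -> Composition:
    """Add a modification multiset to a backbone.

    Returns the composed neutral formula and the canonical name.  Raises
    :class:`CompositionError` for unknown modifications, counts above the
    per-modification cap, or a subtraction driving an element count negative.
    """
    formula = backbone.neutral_formula
    n_oh = backbone.n_hydroxyl
    residue_counts: Dict[str, int] = {}
    for name, count in mods.items():
        if count < 0:
            raise CompositionError(f"negative count for modification {name!r}")
        if count == 0:
            continue
        if name not in library:
            raise CompositionError(f"unknown modification {name!r}")
        mod = library[name]
        cap = caps.get(name, mod.default_max_count) if caps else mod.default_max_count
        if count > cap:
            raise CompositionError(
                f"modification {name!r} count {count} exceeds cap {cap}"
            )
        try:
            if mod.sign >= 0:
                formula = formula + mod.delta_formula * count
            else:
                formula = formula - mod.delta_formula * count
        except FormulaError as exc:
            raise CompositionError(
                f"applying {count}x {name!r} to {backbone.name}: {exc}"
            ) from exc
        if name == "OH":
            n_oh += count
        else:
            residue_counts[name] = count
    return Composition(formula, canonical_name(backbone.base, n_oh, residue_counts))


_NAME_TOKENS = {"OH": ("OH", 1), "diOH": ("OH", 2)}


def parse_metabolite_name(
    name: str, backbones: Mapping[str, Backbone] = BACKBONES
) -> Tuple[Backbone, Dict[str, int]]:
    """Invert :func:`canonical_name`: split a name into backbone + multiset.

    The most-hydroxylated matching backbone claims the name (so
    "DCF-diOH-Glc" maps to backbone DCF-OH plus one extra OH), mirroring how
    the characteristic fragment anchors naming in the screen.
    """
    tokens = name.split("-")
    if tokens[0] != "DCF":
        raise CompositionError(f"name {name!r} does not start with a known base")
    base = "DCF"
    i = 1
    if len(tokens) > 1 and tokens[1] == "Lac":
        base = "DCF-Lac"
        i = 2
    n_oh = 0
    mods: Dict[str, int] = {}
    for token in tokens[i:]:
        if token in _NAME_TOKENS:
            n_oh += _NAME_TOKENS[token][1]
        elif token in _RESIDUE_ORDER:
            mods[token] = mods.get(token, 0) + 1
        else:
            raise CompositionError(f"unknown token {token!r} in name {name!r}")
    backbone_name = base + ("-OH" if n_oh >= 1 else "")
    backbone = backbones[backbone_name]
    extra_oh = n_oh - backbone.n_hydroxyl
    if extra_oh:
        mods["OH"] = extra_oh
    return backbone, mods


def cl2_pattern_score(intensity_m: float, intensity_m2: float) -> float:
    """Plausibility score in [0, 1] for a dichlorinated isotope pattern.

    Compares the observed (M+2)/M intensity ratio with the theoretical
    two-chlorine binomial ratio (~0.64).  Returns 1 at the theoretical ratio
    and decays monotonically (Gaussian in the relative deviation, width 25%).
    """
    if intensity_m < 0 or intensity_m2 < 0:
        raise ValueError("intensities must be non-negative")
    if intensity_m == 0:
        raise ValueError("M intensity is zero: ratio undefined")
    ratio = intensity_m2 / intensity_m
    rel_dev = (ratio - CL2_M2_RATIO) / CL2_M2_RATIO
    import math

    return math.exp(-0.5 * (rel_dev / 0.25) ** 2)


def load_library(path) -> Tuple[Dict[str, Backbone], Dict[str, Modification]]:
    """Load backbone and modification libraries from a YAML config.

    Expected layout::

        backbones:
          DCF: {formula: C14H11Cl2NO2, base: DCF, hydroxyls: 0}
        modifications:
          Glc: {formula: C6H10O5, max_count: 2}
          H2O-loss: {formula: H2O, sign: -1, max_count: 2}
    """
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or "backbones" not in raw:
        raise FormulaError(f"library file {path} lacks a 'backbones' section")
    backbones = {}
    for name, spec in raw["backbones"].items():
        backbones[name] = Backbone(
            name=name,
            base=str(spec.get("base", name)),
            n_hydroxyl=int(spec.get("hydroxyls", 0)),
            neutral_formula=parse_formula(spec["formula"]),
        )
    modifications = {}
    for name, spec in raw.get("modifications", {}).items():
        modifications[name] = Modification(
            name=name,
            delta_formula=parse_formula(spec["formula"]),
            sign=int(spec.get("sign", 1)),
            default_max_count=int(spec.get("max_count", 2)),
        )
    return backbones, modifications


def dump_library(
    path,
    backbones: Mapping[str, Backbone] = BACKBONES,
    modifications: Mapping[str, Modification] = MODIFICATIONS,
) -> None:
    """Write libraries to YAML in the :func:`load_library` layout."""
    payload = {
        "backbones": {
            b.name: {
                "formula": b.neutral_formula.hill(),
                "base": b.base,
                "hydroxyls": b.n_hydroxyl,
            }
            for b in backbones.values()
        },
        "modifications": {
            m.name: {
                "formula": m.delta_formula.hill(),
                "sign": m.sign,
                "max_count": m.default_max_count,
            }
            for m in modifications.values()
        },
    }
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)
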