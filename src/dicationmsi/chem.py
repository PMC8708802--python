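"""Elemental-formula algebra, exact masses and isotope patterns.

Everything downstream — adduct m/z prediction, mass-shift annotation,
spectral-accuracy checks — reduces to arithmetic on elemental compositions.
This module provides that arithmetic:

* :class:`ElementalFormula` — an immutable element→count map with
  element-wise addition and subtraction.
* :class:`IsotopeTable` — isotope masses and natural abundances (NIST),
  shipped as a plain-text data file, plus the electron mass and the
  reference 13C abundance used for carbon-count estimation.
* :func:`monoisotopic_mass`, :func:`ion_mz` — exact masses with explicit
  electron-mass bookkeeping (an ion's m/z is shifted by one electron mass
  per charge relative to the neutral composition; at four-decimal m/z this
  is not optional).
* :func:`isotope_pattern` — aggregated (unit-resolution) isotopologue
  distribution by per-element convolution.
* :func:`estimate_carbon_count` / :func:`spectral_accuracy_score` —
  carbon-number estimation from the M+1/M ratio and validation of an
  observed envelope against theory ("spectral accuracy").

Masses are monoisotopic Daltons throughout; average masses are out of scope.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementalFormula",
    "FormulaError",
    "IsotopeTable",
    "IonSpecies",
    "default_table",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "isotope_pattern",
    "estimate_carbon_count",
    "SpectralAccuracyResult",
    "spectral_accuracy_score",
]

#: Electron rest mass in Da (CODATA).
ELECTRON_MASS = 0.000548579909

#: Mass of a proton (H+) in Da: mass(1H) − electron mass.
PROTON_MASS = 1.00727646677


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid formula algebra."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula(Mapping[str, int]):
    """Immutable elemental composition (element symbol → atom count).

    Supports element-wise ``+`` and ``-``; subtraction that would drive any
    count negative raises :class:`FormulaError`. Zero counts are dropped so
    equal compositions compare (and hash) equal regardless of construction.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | Iterable[Tuple[str, int]]):
        items = dict(counts)
        clean: Dict[str, int] = {}
        for elem, n in items.items():
            if not isinstance(n, (int, np.integer)):
                raise FormulaError(f"count for {elem!r} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for {elem!r}: {n}")
            if n > 0:
                clean[str(elem)] = int(n)
        self._counts = clean

    @classmethod
    def from_string(cls, text: str) -> "ElementalFormula":
        return parse_formula(text)

    # Mapping interface -------------------------------------------------
    def __getitem__(self, elem: str) -> int:
        return self._counts[elem]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, elem: str, default: int = 0) -> int:
        return self._counts.get(elem, default)

    # Algebra ------------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self._counts)
        for elem, n in other.items():
            merged[elem] = merged.get(elem, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self._counts)
        for elem, n in other.items():
            new = merged.get(elem, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction yields negative {elem} count ({new}) "
                    f"in {self} - {other}"
                )
            merged[elem] = new
        return ElementalFormula(merged)

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(sorted(self._counts.items())))

    def n_atoms(self) -> int:
        return sum(self._counts.values())

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        parts = []
        for elem in self._hill_order():
            n = self._counts[elem]
            parts.append(elem if n == 1 else f"{elem}{n}")
        return "".join(parts)

    def _hill_order(self) -> List[str]:
        elems = sorted(self._counts)
        ordered = [e for e in ("C", "H") if e in self._counts]
        ordered += [e for e in elems if e not in ("C", "H")]
        return ordered

    def __repr__(self) -> str:
        return f"ElementalFormula({str(self)!r})"


@dataclass
class IsotopeTable:
    """Isotope masses (Da) and natural abundances per element.

    ``c13_reference_abundance`` is the 13C fraction used by
    :func:`estimate_carbon_count`; it defaults to 0.0111 (the "~1.11%"
    convention common in spectral-accuracy work) and is configurable
    independently of the natural-abundance data used for pattern
    computation.
    """

    isotopes: Dict[str, List[Tuple[float, float]]]
    c13_reference_abundance: float = 0.0111

    def __post_init__(self) -> None:
        for elem, rows in self.isotopes.items():
            total = sum(ab for _, ab in rows)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"abundances for {elem} sum to {total}, not 1")
            if any(mass <= 0 for mass, _ in rows):
                raise ValueError(f"non-positive isotope mass for {elem}")

    @classmethod
    def from_tsv(cls, path=None, **kwargs) -> "IsotopeTable":
        """Load from the packaged table (or ``path``): element, nominal, mass, abundance."""
        if path is None:
            source = resources.files("dicationmsi.data").joinpath("isotopes.tsv")
            text = source.read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        isotopes: Dict[str, List[Tuple[float, float]]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            elem, _nominal, mass, ab = line.split("\t")
            isotopes.setdefault(elem, []).append((float(mass), float(ab)))
        for rows in isotopes.values():
            rows.sort()
        return cls(isotopes=isotopes, **kwargs)

    def elements(self) -> Iterable[str]:
        return self.isotopes.keys()

    def principal_mass(self, elem: str) -> float:
        """Mass of the most abundant (for C/H/N/O/P/S/F also lightest) isotope."""
        try:
            rows = self.isotopes[elem]
        except KeyError:
            raise KeyError(f"element {elem!r} not in isotope table") from None
        return max(rows, key=lambda r: r[1])[0]


_DEFAULT_TABLE: Optional[IsotopeTable] = None


def default_table() -> IsotopeTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = IsotopeTable.from_tsv()
    return _DEFAULT_TABLE


def parse_formula(text: str) -> ElementalFormula:
    """Parse ``"C2NH7O4P"``-style strings into an :class:`ElementalFormula`.

    Element symbols may appear in any order and repeat (counts accumulate).
    No parentheses, hydrates, isotope labels or charges: charge belongs on
    :class:`IonSpecies`. An explicit count must be a positive integer.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    known = set(default_table().elements())
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        elem, digits = m.group(1), m.group(2)
        if elem not in known:
            raise FormulaError(f"unknown element symbol {elem!r} in {text!r}")
        if digits == "":
            n = 1
        else:
            n = int(digits)
            if n <= 0:
                raise FormulaError(f"explicit count must be positive in {text!r}")
        counts[elem] = counts.get(elem, 0) + n
        pos = m.end()
    return ElementalFormula(counts)


def _as_formula(f) -> ElementalFormula:
    return f if isinstance(f, ElementalFormula) else parse_formula(str(f))


def monoisotopic_mass(f, table: Optional[IsotopeTable] = None) -> float:
    """Exact mass of the all-principal-isotope composition, in Da."""
    f = _as_formula(f)
    if len(f) == 0:
        raise FormulaError("empty formula has no monoisotopic mass")
    table = table or default_table()
    return sum(n * table.principal_mass(elem) for elem, n in f.items())


def ion_mz(f, charge: int, table: Optional[IsotopeTable] = None) -> float:
    """m/z of an ion with the given *neutral-composition* formula and charge.

    ``(monoisotopic_mass − charge × m_e) / |charge|``: a cation is lighter
    than its composition by one electron per charge, an anion heavier.
    """
    if charge == 0:
        raise ValueError("charge must be non-zero")
    mass = monoisotopic_mass(f, table)
    return (mass - charge * ELECTRON_MASS) / abs(charge)


@dataclass(frozen=True)
class IonSpecies:
    """A charged species: neutral-composition formula + charge + label."""

    formula: ElementalFormula
    charge: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("IonSpecies charge must be non-zero")

    @property
    def mz(self) -> float:
        return ion_mz(self.formula, self.charge)


def _atom_power(base_a: np.ndarray, base_s: np.ndarray, n: int, depth: int):
    """(abundance, abundance·mass-offset) polynomials for n identical atoms.

    Repeated squaring with truncation at ``depth`` nucleon-offset bins.
    """
    res_a = np.zeros(depth)
    res_a[0] = 1.0
    res_s = np.zeros(depth)
    cur_a, cur_s = base_a.copy(), base_s.copy()
    while n:
        if n & 1:
            res_a, res_s = _conv_pair(res_a, res_s, cur_a, cur_s, depth)
        n >>= 1
        if n:
            cur_a, cur_s = _conv_pair(cur_a, cur_s, cur_a, cur_s, depth)
    return res_a, res_s


def _conv_pair(a1, s1, a2, s2, depth):
    a = np.convolve(a1, a2)[:depth]
    s = (np.convolve(s1, a2) + np.convolve(a1, s2))[:depth]
    return a, s


def isotope_pattern(
    f,
    n_peaks: int = 3,
    table: Optional[IsotopeTable] = None,
) -> List[Tuple[float, float]]:
    """Aggregated isotope pattern: ``[(mass offset Da, relative abundance)]``.

    Isotopologues are binned by nucleon-count offset (M, M+1, M+2, ...), the
    resolution regime of Orbitrap-class instruments where the 13C, 2H, 15N
    and 17O M+1 species merge into one peak. Each bin's mass offset is the
    abundance-weighted mean over its isotopologues; abundances are scaled so
    the base (most abundant) peak is 1. The first entry is the monoisotopic
    peak at offset 0.
    """
    if n_peaks < 2:
        raise ValueError("n_peaks must be >= 2")
    f = _as_formula(f)
    if len(f) == 0:
        raise FormulaError("empty formula has no isotope pattern")
    table = table or default_table()

    depth = n_peaks
    total_a = np.zeros(depth)
    total_a[0] = 1.0
    total_s = np.zeros(depth)
    for elem, n in f.items():
        rows = table.isotopes[elem]
        mono = table.principal_mass(elem)
        nominal0 = round(mono)
        base_a = np.zeros(depth)
        base_s = np.zeros(depth)
        for mass, ab in rows:
            k = round(mass) - nominal0
            if 0 <= k < depth:
                base_a[k] += ab
                base_s[k] += ab * (mass - mono)
        a, s = _atom_power(base_a, base_s, n, depth)
        total_a, total_s = _conv_pair(total_a, total_s, a, s, depth)

    base = total_a.max()
    out: List[Tuple[float, float]] = []
    for k in range(depth):
        if total_a[k] > 0:
            offset = total_s[k] / total_a[k]
        else:
            offset = k * 1.003355  # nominal 13C spacing for empty bins
        out.append((float(offset), float(total_a[k] / base)))
    return out


def estimate_carbon_count(
    m1_rel_abundance: float,
    c13_abundance: Optional[float] = None,
    table: Optional[IsotopeTable] = None,
) -> int:
    """Estimate carbon number from the M+1/M abundance ratio.

    The merged M+1 peak is treated as entirely 13C-driven and divided by the
    reference 13C abundance (default 0.0111, i.e. ~1.11%). The estimate
    carries a small positive bias from 2H/15N/17O contributions, largely
    offset by the reference abundance sitting above the natural 13C/12C
    ratio — for CHNOPS metabolites the net error stays within about one
    carbon up to C50.
    """
    if m1_rel_abundance < 0:
        raise ValueError("M+1 relative abundance cannot be negative")
    if m1_rel_abundance > 1.2:
        raise ValueError("M+1 relative abundance above 1.2 is not physical here")
    if c13_abundance is None:
        c13_abundance = (table or default_table()).c13_reference_abundance
    return int(round(m1_rel_abundance / c13_abundance))


@dataclass
class SpectralAccuracyResult:
    """Outcome of comparing an observed envelope to the theoretical pattern.

    ``passed`` is ``True``/``False`` when the M+1 peak was evaluable, and
    ``None`` when the monoisotopic or M+1 peak could not be located (the
    caller should treat that as "untested", not as failure).
    """

    matched: bool
    deviations: Dict[str, float] = field(default_factory=dict)
    passed: Optional[bool] = None
    observed_relative: Dict[str, float] = field(default_factory=dict)
    theoretical_relative: Dict[str, float] = field(default_factory=dict)
    estimated_carbons: Optional[int] = None
    message: str = ""


def spectral_accuracy_score(
    observed: Sequence[Tuple[float, float]],
    f,
    tol_ppm: float = 2.5,
    charge: int = 1,
    m1_threshold: float = 0.20,
    n_peaks: int = 3,
    table: Optional[IsotopeTable] = None,
) -> SpectralAccuracyResult:
    """Validate an observed isotope envelope against the theoretical pattern.

    ``observed`` is a centroided peak list ``[(m/z, abundance)]``; ``f`` is
    the *ion composition* (e.g. the full adduct formula) at ``charge``. The
    monoisotopic peak is located within ``tol_ppm``; M+1 (and M+2 when
    present) are paired with theory and the relative deviation
    ``|obs − theory| / theory`` reported per peak. Pass requires the M+1
    deviation ≤ ``m1_threshold`` (default 20%). A missing monoisotopic peak
    yields a no-match result rather than an exception.
    """
    table = table or default_table()
    f = _as_formula(f)
    mono_mz = ion_mz(f, charge, table)
    peaks = [(float(mz), float(ab)) for mz, ab in observed]

    def find(target: float) -> Optional[Tuple[float, float]]:
        best = None
        for mz, ab in peaks:
            if abs(mz - target) / target * 1e6 <= tol_ppm:
                if best is None or ab > best[1]:
                    best = (mz, ab)
        return best

    mono = find(mono_mz)
    if mono is None or mono[1] <= 0:
        return SpectralAccuracyResult(matched=False, message="monoisotopic peak not found")

    theory = isotope_pattern(f, n_peaks=n_peaks, table=table)
    result = SpectralAccuracyResult(matched=True)
    for k in range(1, len(theory)):
        offset, th_rel = theory[k]
        if th_rel <= 0:
            continue
        label = f"M+{k}"
        obs_peak = find(mono[0] + offset / abs(charge))
        result.theoretical_relative[label] = th_rel
        if obs_peak is None:
            continue
        obs_rel = obs_peak[1] / mono[1]
        result.observed_relative[label] = obs_rel
        result.deviations[label] = abs(obs_rel - th_rel) / th_rel

    if "M+1" not in result.deviations:
        result.message = "M+1 peak not found; spectral accuracy untested"
        return result
    m1_obs = result.observed_relative["M+1"]
    if 0 <= m1_obs <= 1.2:
        result.estimated_carbons = estimate_carbon_count(m1_obs, table=table)
    result.passed = result.deviations["M+1"] <= m1_threshold
    return result
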