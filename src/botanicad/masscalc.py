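"""Exact-mass arithmetic, bounded formula search, and adulterant screening.

Monoisotopic element masses come from the NIST table bundled with pyteomics.
Ion m/z values are electron-mass corrected: the charged species is lighter
(positive ions) or heavier (negative ions) by one electron per charge, which
matters at the fourth decimal place for high-resolution work.

The adulterant screen encodes the standard grape-authenticity markers:
A-type proanthocyanidin dimers ([M-H]- 575.1189, present in peanut skin and
pine bark) versus B-type dimers ([M-H]- 577.1345, the genuine grape-seed
linkage). The marker values are configuration literals as printed in common
reference material; they sit ~1 ppm from values recomputed with current
constants, so screens should use tolerances of a few ppm.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from pyteomics.mass import nist_mass

from .errors import FormulaError, ParameterError

ELECTRON_MASS = 0.00054857990907  # Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: monoisotopic (most abundant isotope) masses, Da
_ELEMENT_MASS = {el: data[0][0] for el, data in nist_mass.items()}

# adduct name -> (atom delta applied to the neutral, signed charge)
_ADDUCTS = {
    "[M+H]+": ({"H": 1}, 1),
    "[M-H]-": ({"H": -1}, -1),
    "[M+Na]+": ({"Na": 1}, 1),
    "[M-H2O+H]+": ({"H": -1, "O": -1}, 1),
}

#: default grape-seed authenticity markers: (name, m/z, polarity)
DEFAULT_MARKERS = (
    ("A-type proanthocyanidin dimer", 575.1189, "neg"),
    ("B-type proanthocyanidin dimer", 577.1345, "neg"),
)


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse a Hill-notation formula into element counts.

    Underscore-delimited input ("C_15_H_16_O_6") is tolerated and treated
    as equivalent to the plain form ("C15H16O6").
    """
    if isinstance(formula, Mapping):
        counts = {el: int(n) for el, n in formula.items() if n}
        if not counts:
            raise FormulaError("empty formula")
        for el in counts:
            if el not in _ELEMENT_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if counts[el] < 0:
                raise FormulaError(f"negative count for {el}")
        return counts
    text = str(formula).replace("_", "").strip()
    if not text:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r}")
        el, num = match.groups()
        if el not in _ELEMENT_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {formula!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = match.end()
    if pos != len(text) or not counts:
        raise FormulaError(f"cannot parse formula {formula!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Hill notation: C first, H second, then remaining elements A-Z."""
    parts = []
    rest = sorted(el for el in counts if el not in ("C", "H") and counts[el])
    order = [el for el in ("C", "H") if counts.get(el)] + rest
    for el in order:
        n = counts[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Neutral monoisotopic mass in Da (most abundant isotope of each element)."""
    counts = parse_formula(formula)
    return sum(_ELEMENT_MASS[el] * n for el, n in counts.items())


def _normalize_adduct(adduct: str) -> str:
    return adduct.replace("−", "-").replace(" ", "")


def ion_mz(formula: str | Mapping[str, int], adduct: str = "[M-H]-") -> float:
    """m/z of an adduct ion, electron-mass corrected.

    m/z = (M + delta - z * m_e) / |z| where delta is the atom delta of the
    adduct and z the signed charge.
    """
    key = _normalize_adduct(adduct)
    if key not in _ADDUCTS:
        raise ParameterError(f"unsupported adduct {adduct!r}")
    delta_atoms, charge = _ADDUCTS[key]
    mass = monoisotopic_mass(formula)
    delta = sum(_ELEMENT_MASS[el] * n for el, n in delta_atoms.items())
    return (mass + delta - charge * ELECTRON_MASS) / abs(charge)


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """(observed - theoretical) / theoretical * 1e6. Round to 1 dp for reports."""
    if theoretical_mz <= 0:
        raise ParameterError("theoretical m/z must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def rdbe(formula: str | Mapping[str, int]) -> float:
    """Rings-plus-double-bond equivalents: C - H/2 + N/2 + 1."""
    counts = parse_formula(formula)
    return counts.get("C", 0) - counts.get("H", 0) / 2 + counts.get("N", 0) / 2 + 1


@dataclass(frozen=True)
class FormulaCandidate:
    """One neutral-formula assignment for an observed ion."""

    formula: str
    theoretical_mz: float
    ppm_error: float
    rdbe: float

    @property
    def counts(self) -> dict[str, int]:
        return parse_formula(self.formula)


DEFAULT_BOUNDS = {"C": 40, "H": 60, "N": 3, "O": 20}


def find_formulas(
    observed_mz: float,
    adduct: str = "[M-H]-",
    tol_ppm: float = 5.0,
    element_bounds: Mapping[str, int] | None = None,
    rdbe_range: tuple[float, float] = (-0.5, 40.0),
) -> list[FormulaCandidate]:
    """Exhaustively enumerate neutral formulas matching an observed ion m/z.

    All element-count combinations within ``element_bounds`` are considered;
    the hydrogen count is solved analytically from the mass window, so the
    search cost scales with the non-hydrogen bound box only. Candidates are
    filtered by |ppm| <= tol_ppm and rdbe within ``rdbe_range`` and returned
    sorted by |ppm| ascending, ties broken by smaller atom count.
    """
    if tol_ppm < 0:
        raise ParameterError("tol_ppm must be >= 0")
    bounds = dict(DEFAULT_BOUNDS if element_bounds is None else element_bounds)
    h_max = bounds.pop("H", 0)
    for el in bounds:
        if el not in _ELEMENT_MASS:
            raise FormulaError(f"unknown element symbol {el!r}")
    key = _normalize_adduct(adduct)
    if key not in _ADDUCTS:
        raise ParameterError(f"unsupported adduct {adduct!r}")
    delta_atoms, charge = _ADDUCTS[key]
    delta = sum(_ELEMENT_MASS[el] * n for el, n in delta_atoms.items())
    # neutral-mass target and absolute window
    target = observed_mz * abs(charge) - delta + charge * ELECTRON_MASS
    tol_da = tol_ppm * 1e-6 * observed_mz * abs(charge)
    m_h = _ELEMENT_MASS["H"]

    elements = sorted(bounds)
    ranges = [range(bounds[el] + 1) for el in elements]
    out: list[FormulaCandidate] = []
    for combo in itertools.product(*ranges):
        base = sum(_ELEMENT_MASS[el] * n for el, n in zip(elements, combo))
        if base > target + tol_da:
            continue
        h_lo = int(-(-(target - tol_da - base) // m_h))  # ceil
        h_hi = int((target + tol_da - base) // m_h)
        for h in range(max(h_lo, 0), min(h_hi, h_max) + 1):
            counts = {el: n for el, n in zip(elements, combo) if n}
            if h:
                counts["H"] = h
            if not counts:
                continue
            try:
                theo = ion_mz(counts, adduct)
            except FormulaError:
                continue
            err = ppm_error(observed_mz, theo)
            if abs(err) > tol_ppm:
                continue
            dbe = rdbe(counts)
            if not (rdbe_range[0] <= dbe <= rdbe_range[1]):
                continue
            out.append(
                FormulaCandidate(
                    formula=format_formula(counts),
                    theoretical_mz=theo,
                    ppm_error=err,
                    rdbe=dbe,
                )
            )
    out.sort(key=lambda c: (abs(c.ppm_error), sum(c.counts.values()), c.formula))
    return out


def adulterant_screen(
    ms_features: Iterable,
    markers: Sequence[tuple[str, float, str]] = DEFAULT_MARKERS,
    tol_ppm: float = 5.0,
    min_intensity: float = 0.0,
) -> dict[str, str]:
    """Narrow-mass marker screen over an MS feature list.

    A marker is "detected" iff any feature of matching polarity lies within
    ``tol_ppm`` of the marker m/z with intensity >= ``min_intensity``.
    """
    if not markers:
        raise ParameterError("marker list must be non-empty")
    feats = list(ms_features)
    verdicts: dict[str, str] = {}
    for name, mz, polarity in markers:
        tol_da = tol_ppm * 1e-6 * mz
        hit = any(
            f.polarity == polarity
            and abs(f.mz - mz) <= tol_da
            and f.intensity >= min_intensity
            for f in feats
        )
        verdicts[name] = "detected" if hit else "absent"
    return verdicts
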