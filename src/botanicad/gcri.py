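"""Kovats retention indexing and FID quantitation for the volatile fraction.

Retention indexes use the van den Dool-Kratz linear form appropriate for
temperature-programmed GC: an analyte bracketed by n-alkanes with carbon
numbers n_i < n_j is assigned

    RI = 100 * (n_i + (n_j - n_i) * (rt - rt_i) / (rt_j - rt_i)),

so every ladder alkane Cn maps to exactly 100 n, and ladders with gaps
(e.g. C7 -> C9) interpolate across the carbon-number gap. No silent
extrapolation: retention times outside the ladder span raise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError, ParameterError
from .quant import fit_response_factor
from .traces import Peak


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane retention ladder: (carbon_number, rt_min) pairs."""

    pairs: tuple[tuple[int, float], ...]

    def __init__(self, pairs: Sequence[tuple[int, float]]) -> None:
        ordered = tuple((int(n), float(rt)) for n, rt in pairs)
        if len(ordered) < 2:
            raise InputError("a ladder needs at least two alkanes")
        carbons = [n for n, _ in ordered]
        rts = [rt for _, rt in ordered]
        if any(n < 5 for n in carbons):
            raise InputError("ladder carbon numbers must be >= 5")
        if sorted(carbons) != carbons or len(set(carbons)) != len(carbons):
            raise InputError("carbon numbers must be strictly increasing")
        if sorted(rts) != rts or len(set(rts)) != len(rts):
            raise InputError("ladder retention times must be strictly increasing")
        object.__setattr__(self, "pairs", ordered)

    @property
    def carbons(self) -> np.ndarray:
        return np.array([n for n, _ in self.pairs])

    @property
    def rts(self) -> np.ndarray:
        return np.array([rt for _, rt in self.pairs])


def kovats_ri(rt_min: float, ladder: AlkaneLadder) -> float:
    """Retention index of an analyte eluting at ``rt_min``."""
    rts = ladder.rts
    carbons = ladder.carbons
    if rt_min < rts[0] or rt_min > rts[-1]:
        raise InputError(
            f"rt {rt_min:.3f} min outside ladder span "
            f"[{rts[0]:.3f}, {rts[-1]:.3f}] - refusing to extrapolate"
        )
    j = int(np.searchsorted(rts, rt_min, side="right"))
    if j == len(rts):  # exactly the last alkane
        return 100.0 * float(carbons[-1])
    i = max(j - 1, 0)
    if rts[i] == rt_min:
        return 100.0 * float(carbons[i])
    n_i, n_j = carbons[i], carbons[i + 1]
    return 100.0 * (n_i + (n_j - n_i) * (rt_min - rts[i]) / (rts[i + 1] - rts[i]))


def ri_to_rt(ri: float, ladder: AlkaneLadder) -> float:
    """Inverse of :func:`kovats_ri` (linear within each ladder segment)."""
    carbons = ladder.carbons
    rts = ladder.rts
    if ri < 100.0 * carbons[0] or ri > 100.0 * carbons[-1]:
        raise InputError("retention index outside ladder span")
    idx = 100.0 * carbons.astype(float)
    j = int(np.searchsorted(idx, ri, side="right"))
    if j == len(idx):
        return float(rts[-1])
    i = max(j - 1, 0)
    if idx[i] == ri:
        return float(rts[i])
    frac = (ri - idx[i]) / (idx[i + 1] - idx[i])
    return float(rts[i] + frac * (rts[i + 1] - rts[i]))


def quantify_fid(
    fid_peaks: Sequence[Peak],
    ladder_standards: Sequence[tuple[float, float]],
    sample_mass_ug: float,
) -> tuple[list[float], list[float], float]:
    """Quantify volatile FID peaks against pooled hydrocarbon standards.

    ``ladder_standards`` are (area, injected mass ug) pairs for the alkane
    mix; a single through-origin response factor is pooled across them, as in
    the CAD quantitation. Returns (masses ug, percents of sample mass,
    volatile mass balance percent).
    """
    if sample_mass_ug <= 0:
        raise ParameterError("sample mass must be positive")
    if len(ladder_standards) < 1:
        raise ParameterError("need at least one FID standard")
    pts = list(ladder_standards)
    if len(pts) == 1:
        area, mass = pts[0]
        if area <= 0 or mass <= 0:
            raise ParameterError("standard area and mass must be positive")
        slope = area / mass
    else:
        slope = fit_response_factor(pts, channel="FID").slope
    masses = [p.area / slope for p in fid_peaks]
    percents = [100.0 * m / sample_mass_ug for m in masses]
    return masses, percents, round(float(sum(percents)), 1)


def match_by_ri(
    fid_ri: Sequence[float], ms_ri: Sequence[float], tol_ri: float = 10.0
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of FID and MS peaks by retention index.

    Pairs are taken in order of increasing |delta RI|; each peak matches at
    most once and only within ``tol_ri``.
    """
    if tol_ri <= 0:
        raise ParameterError("tol_ri must be > 0")
    candidates = sorted(
        (
            (abs(a - b), i, j)
            for i, a in enumerate(fid_ri)
            for j, b in enumerate(ms_ri)
            if abs(a - b) <= tol_ri
        ),
    )
    used_f: set[int] = set()
    used_m: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_f or j in used_m:
            continue
        pairs.append((i, j))
        used_f.add(i)
        used_m.add(j)
    return sorted(pairs)
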