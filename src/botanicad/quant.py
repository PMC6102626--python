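"""Universal response-factor calibration, per-dose quantitation, and TTC logic.

A charged aerosol detector responds to the mass of non-volatile analyte
reaching the nebulizer, largely independent of structure, so a single
response factor (peak area per microgram injected) fitted on a handful of
flavan-3-ol standards can quantify every peak in the chromatogram —
including the polymeric tannin hump. Regression is through the origin:
zero mass gives zero aerosol signal, and the standards span decades of
concentration.

Per-analyte safety thresholds derive from a threshold of toxicological
concern (TTC): with the default 90 ug/person/day (Cramer Class III) on a
210 mg daily dose, any constituent at or above 90 ug per dose —
equivalently 0.04 % or 400 ppm of the extract after conservative one-
significant-figure rounding — requires identification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import CalibrationError, ParameterError
from .traces import Peak


@dataclass(frozen=True)
class ResponseFactor:
    """Pooled detector response: peak area per microgram injected."""

    slope: float
    r_squared: float
    channel: str = "CAD"
    standards_used: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError("response-factor slope must be positive")


@dataclass(frozen=True)
class DoseContext:
    """Daily dose and TTC, with the derived per-analyte reporting thresholds."""

    dose_mg: float = 210.0
    ttc_ug: float = 90.0

    def __post_init__(self) -> None:
        if self.dose_mg <= 0 or self.ttc_ug <= 0:
            raise ParameterError("dose and TTC must be positive")

    @property
    def threshold_percent(self) -> float:
        return ttc_threshold(self)[0]

    @property
    def threshold_ppm(self) -> float:
        return ttc_threshold(self)[1]


@dataclass
class QuantifiedPeak:
    """A peak with its injected mass and per-dose amount."""

    peak: Peak
    injected_mass_ug: float
    amount_ug_per_dose: float
    above_ttc: bool = False

    def __post_init__(self) -> None:
        if self.amount_ug_per_dose < 0:
            raise ParameterError("amount must be >= 0")


def fit_response_factor(
    standards: Sequence[tuple[float, float]],
    channel: str = "CAD",
    names: Iterable[str] = (),
) -> ResponseFactor:
    """Through-origin least squares over pooled (area, injected mass) points.

    One slope is fitted across all standards — the universality assumption.
    r^2 is the uncentered coefficient of determination of the through-origin
    fit.
    """
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise CalibrationError("need at least 2 (area, mass) standard points")
    areas, masses = pts[:, 0], pts[:, 1]
    if np.any(masses <= 0):
        raise CalibrationError("standard masses must be positive")
    if np.all(areas == 0):
        raise CalibrationError("all standard areas are zero")
    slope = float(np.dot(areas, masses) / np.dot(masses, masses))
    resid = areas - slope * masses
    ss_tot = float(np.dot(areas, areas))
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 0.0
    return ResponseFactor(
        slope=slope, r_squared=max(min(r2, 1.0), 0.0), channel=channel,
        standards_used=tuple(names),
    )


def peak_amount(
    area: float,
    rf: ResponseFactor,
    sample_conc_ug_per_ml: float,
    injection_vol_ul: float,
    dose_mg: float,
) -> tuple[float, float]:
    """Convert a peak area into (injected mass ug, amount ug per dose).

    injected mass = area / slope; the mass fraction of the injected sample
    load scales to the daily dose: amount = fraction * dose_mg * 1000.
    """
    if min(sample_conc_ug_per_ml, injection_vol_ul, dose_mg) <= 0:
        raise ParameterError("concentration, volume, and dose must be positive")
    if rf.slope <= 0:
        raise CalibrationError("response factor slope must be positive")
    injected_mass = area / rf.slope
    total_load = sample_conc_ug_per_ml * injection_vol_ul / 1000.0
    fraction = injected_mass / total_load
    return injected_mass, fraction * dose_mg * 1000.0


def quantify_peak(
    peak: Peak,
    rf: ResponseFactor,
    sample_conc_ug_per_ml: float,
    injection_vol_ul: float,
    ctx: DoseContext,
) -> QuantifiedPeak:
    mass, amount = peak_amount(
        peak.area, rf, sample_conc_ug_per_ml, injection_vol_ul, ctx.dose_mg
    )
    return QuantifiedPeak(
        peak=peak,
        injected_mass_ug=mass,
        amount_ug_per_dose=amount,
        above_ttc=amount >= ctx.ttc_ug,
    )


def _floor_1sf(x: float) -> float:
    """Round down to one significant figure (conservative reporting)."""
    if x <= 0:
        return 0.0
    exp = math.floor(math.log10(x))
    scaled = x / 10**exp
    return math.floor(scaled + 1e-9) * 10.0**exp


def ttc_threshold(ctx: DoseContext) -> tuple[float, float]:
    """Per-analyte threshold as (percent of dose, ppm), rounded conservatively.

    percent = ttc / (dose * 1000) * 100, floored to one significant figure so
    that the reported cut-off never exceeds the exact ratio; ppm = percent * 1e4.
    """
    percent = _floor_1sf(ctx.ttc_ug / (ctx.dose_mg * 1000.0) * 100.0)
    return percent, percent * 1e4


def flag_above_ttc(
    amounts_ug_per_dose: Sequence[float], ctx: DoseContext
) -> list[bool]:
    """True where the per-dose amount reaches the TTC (inclusive at equality).

    The comparison is on the unrounded ug/dose scale; the rounded ppm figure
    is reporting-only.
    """
    if any(a < 0 for a in amounts_ug_per_dose):
        raise ParameterError("amounts must be >= 0")
    return [a >= ctx.ttc_ug for a in amounts_ug_per_dose]


def mass_balance(component_fractions_percent: Sequence[float]) -> tuple[float, bool]:
    """Sum of per-component mass percentages, reported to one decimal.

    Returns (balance, over_accounted) where the flag warns when the sum
    exceeds 100.5 %.
    """
    for p in component_fractions_percent:
        if not (0.0 <= p <= 100.0):
            raise ParameterError("component fractions must be within [0, 100]")
    total = round(float(sum(component_fractions_percent)), 1)
    return total, total > 100.5


DEFAULT_ZONES = (("polar", 0.0, 8.0), ("polyphenol", 8.0, 60.0), ("nonpolar", 60.0, 75.0))


def class_fractions(
    peaks: Sequence[QuantifiedPeak | Peak],
    zones: Sequence[tuple[str, float, float]] = DEFAULT_ZONES,
    channel: str | None = None,
) -> dict[str, float]:
    """Share of total peak area per retention-time zone (compound class).

    Zones must be non-overlapping; each peak is assigned by apex RT. Used to
    contrast class composition seen by an unbiased detector (CAD) against a
    chromophore-dependent one (UV).
    """
    zs = sorted(zones, key=lambda z: z[1])
    for (_, a0, a1), (_, b0, _) in zip(zs[:-1], zs[1:]):
        if a1 > b0 + 1e-12:
            raise ParameterError("zones must not overlap")
        if a0 >= a1:
            raise ParameterError("zone start must precede zone end")
    totals = {name: 0.0 for name, _, _ in zs}
    grand = 0.0
    for qp in peaks:
        pk = qp.peak if isinstance(qp, QuantifiedPeak) else qp
        if channel is not None and pk.channel != channel:
            continue
        for name, z0, z1 in zs:
            if z0 <= pk.apex_rt_min < z1:
                totals[name] += pk.area
                grand += pk.area
                break
        else:
            raise ParameterError(
                f"peak at {pk.apex_rt_min:.2f} min falls outside all zones"
            )
    if grand == 0:
        return {name: 0.0 for name in totals}
    return {name: 100.0 * v / grand for name, v in totals.items()}


def zone_area_fractions(
    trace, zones: Sequence[tuple[str, float, float]] = DEFAULT_ZONES
) -> dict[str, float]:
    """Area-under-the-curve share per retention zone for a whole trace.

    Operates on a baseline-corrected trace; zone bounds are clipped to the
    trace span. This is the detector-comparison view (e.g. UV vs CAD class
    composition) when individual peaks are not needed.
    """
    from .traces import integrate  # deferred: quant is imported by traces users

    t0, t1 = float(trace.time_min[0]), float(trace.time_min[-1])
    totals: dict[str, float] = {}
    for name, z0, z1 in zones:
        lo, hi = max(z0, t0), min(z1, t1)
        totals[name] = integrate(trace, lo, hi, "fixed-zero") if lo < hi else 0.0
    grand = sum(totals.values())
    if grand <= 0:
        return {name: 0.0 for name in totals}
    return {name: 100.0 * v / grand for name, v in totals.items()}
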