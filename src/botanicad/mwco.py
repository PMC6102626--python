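"""Tannin polymer-size analysis from molecular-weight-cutoff filtration series.

Passing an extract through an ultrafiltration membrane of nominal cutoff c
removes constituents heavier than c; the CAD signal lost over an analysis
window (default 10-50 min, where the polymeric material elutes) therefore
estimates the mass fraction above the cutoff. Successive differences of the
loss series over an increasing cutoff ladder bin the polymer mass
distribution:

    bin(< c1)        = 100 - loss(c1)
    bin(ci .. ci+1)  = loss(ci) - loss(ci+1)
    bin(> c_max)     = loss(c_max)

Measured losses can be slightly non-monotone under noise; differences are
clipped at zero (with a validation warning) so bins stay non-negative and
sum to exactly 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import InputError, ParameterError
from .traces import Trace, integrate

DEFAULT_LOSS_WINDOW = (10.0, 50.0)


@dataclass(frozen=True)
class CutoffSeries:
    """Loss percentages over an analysis window for increasing MWCO cutoffs."""

    cutoffs_da: tuple[float, ...]
    loss_percent: tuple[float, ...]
    window_min: tuple[float, float] = DEFAULT_LOSS_WINDOW

    def __post_init__(self) -> None:
        if len(self.cutoffs_da) != len(self.loss_percent) or not self.cutoffs_da:
            raise InputError("cutoffs and losses must be equal-length, non-empty")
        if list(self.cutoffs_da) != sorted(set(self.cutoffs_da)):
            raise InputError("cutoffs must be strictly increasing")
        if any(c <= 0 for c in self.cutoffs_da):
            raise ParameterError("cutoffs must be positive")
        if any(not (0.0 <= l <= 100.0) for l in self.loss_percent):
            raise InputError("losses must lie in [0, 100]")


def loss_series(
    full_trace: Trace,
    filtered_traces: Mapping[float, Trace],
    window_min: tuple[float, float] = DEFAULT_LOSS_WINDOW,
) -> CutoffSeries:
    """Percent CAD signal lost per cutoff: 100 * (1 - filtered/full area)."""
    lo, hi = window_min
    full_area = integrate(full_trace, lo, hi, "fixed-zero")
    if full_area <= 0:
        raise InputError("full-extract trace has no signal in the loss window")
    cutoffs = sorted(filtered_traces)
    losses = []
    for c in cutoffs:
        tr = filtered_traces[c]
        if tr.time_min.shape != full_trace.time_min.shape or not np.allclose(
            tr.time_min, full_trace.time_min
        ):
            raise InputError("filtered traces must share the full trace's time axis")
        area = integrate(tr, lo, hi, "fixed-zero")
        losses.append(float(np.clip(100.0 * (1.0 - area / full_area), 0.0, 100.0)))
    return CutoffSeries(tuple(float(c) for c in cutoffs), tuple(losses), window_min)


def size_distribution(series: CutoffSeries) -> tuple[list[float], bool]:
    """Mass-fraction bins (<c1, c1-c2, ..., >c_max) from a loss series.

    Returns (bins, monotone_warning). Bins are clipped at zero when the
    measured losses are non-monotone, then renormalized by construction:
    the clipped differences always sum to 100.
    """
    losses = np.asarray(series.loss_percent, dtype=float)
    warning = bool(np.any(np.diff(losses) > 0))
    # enforce non-increasing losses via a running minimum before differencing
    monotone = np.minimum.accumulate(losses)
    bins = [100.0 - monotone[0]]
    bins.extend(monotone[i] - monotone[i + 1] for i in range(len(monotone) - 1))
    bins.append(monotone[-1])
    bins = [float(max(b, 0.0)) for b in bins]
    return bins, warning


def strip_polyphenols(library, config, rng=None) -> Trace:
    """Qualitative PVPP-treatment emulation: render the CAD trace with all
    polyphenol- and tannin-class constituents removed (PVPP binds both)."""
    from .synth import render_trace  # local import to avoid a cycle

    kept = [c for c in library if c.klass not in ("polyphenol", "tannin")]
    return render_trace(
        kept, "CAD", config.time_axis(), config.rf_area_per_ug,
        config.injection_vol_ul, baseline=config.baseline_level,
    )
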