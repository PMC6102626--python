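"""Seeded synthetic multi-detector datasets with known ground truth.

The generator emulates the analytical signature of a proanthocyanidin-rich
botanical extract (a grape-seed extract profile) across every channel the
pipeline consumes:

* a CAD chromatogram: dozens of narrow Gaussian constituent peaks over a
  noisy baseline plus one broad "tannin hump" (15-45 min) built from many
  wide, low Gaussians of polymeric members;
* a UV chromatogram of the same library, weighted by per-constituent
  chromophore strength (salts, sugars and fatty acids vanish under UV);
* accurate-mass MS features in both polarities, co-eluting with their parent
  CAD peaks, plus deliberately retention-shifted decoy features that must be
  rejected by apex alignment;
* a GC-FID volatile fraction with an n-alkane ladder for Kovats retention
  indexing;
* a molecular-weight-cutoff (MWCO) filtration series whose signal losses are
  driven by a latent log-normal polymer-size distribution.

Class mass fractions default to a tannin-dominated composition (~72 %
tannin, ~8 % other polyphenols, ~17 % polar, ~1 % nonpolar, 2.6 % volatile)
so that a CAD-vs-UV class comparison and the overall mass balance behave
like real extract data. Tannin member masses are equal-mass quantile draws
from the log-normal, which makes measured MWCO losses converge to the
closed-form survival function at O(1/n_members).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import masscalc
from .errors import ParameterError
from .gcri import AlkaneLadder, ri_to_rt
from .traces import Peak, Trace

POLARITIES = ("pos", "neg")


@dataclass(frozen=True)
class ConstituentSpec:
    """One ground-truth constituent of the synthetic extract."""

    name: str
    formula: str | None
    klass: str  # polar | polyphenol | nonpolar | volatile | tannin
    rt_min: float
    conc_ug_per_ml: float
    peak_sigma_min: float
    uv_response_weight: float = 0.0
    ionizes_pos: bool = False
    ionizes_neg: bool = False
    mw_da: float | None = None
    cad_peak: int | None = None
    kovats_ri: float | None = None

    def __post_init__(self) -> None:
        if self.rt_min <= 0:
            raise ParameterError(f"{self.name}: rt must be > 0")
        if self.conc_ug_per_ml < 0:
            raise ParameterError(f"{self.name}: concentration must be >= 0")
        if self.peak_sigma_min <= 0:
            raise ParameterError(f"{self.name}: peak sigma must be > 0")
        if self.uv_response_weight < 0:
            raise ParameterError(f"{self.name}: UV weight must be >= 0")
        if self.klass == "tannin" and self.mw_da is None:
            raise ParameterError(f"{self.name}: tannin members need mw_da")

    def mass_ug(self, injection_vol_ul: float) -> float:
        return self.conc_ug_per_ml * injection_vol_ul / 1000.0

    def molecular_weight(self) -> float:
        if self.mw_da is not None:
            return self.mw_da
        if self.formula:
            return masscalc.monoisotopic_mass(self.formula)
        return 300.0  # unspecified small molecule


@dataclass(frozen=True)
class MSFeature:
    """One accurate-mass feature: apex RT, m/z, intensity, polarity."""

    rt_min: float
    mz: float
    intensity: float
    polarity: str

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ParameterError(f"polarity must be one of {POLARITIES}")


# --------------------------------------------------------------------------
# default constituent templates: (name, formula, rt, relative weight,
# uv weight, ionizes_pos, ionizes_neg)

POLAR_TEMPLATE = (
    ("mineral salts", None, 1.05, 3500, 0.00, False, False),
    ("monosaccharide", "C6H12O6", 1.45, 3000, 0.00, False, True),
    ("gluconic acid", "C6H12O7", 1.45, 1000, 0.00, False, True),
    ("tartaric acid", "C4H6O6", 1.95, 2700, 0.15, False, True),
    ("disaccharide", "C12H22O11", 1.95, 1000, 0.00, False, True),
    ("malic acid", "C4H6O5", 2.45, 1500, 0.10, False, True),
    ("proline", "C5H9NO2", 2.95, 1000, 0.00, True, False),
    ("citric acid", "C6H8O7", 4.50, 850, 0.10, False, True),
    ("succinic acid", "C4H6O4", 5.60, 850, 0.10, False, True),
    ("tyrosine", "C9H11NO3", 5.60, 400, 0.40, True, True),
    ("choline hexoside", "C11H23NO6", 6.30, 850, 0.00, True, False),
)

POLYPHENOL_TEMPLATE = (
    ("gallic acid", "C7H6O5", 9.50, 750, 0.90, False, True),
    ("glucogallin", "C13H16O10", 16.40, 750, 0.80, False, True),
    ("proanthocyanidin B1", "C30H26O12", 18.60, 1500, 1.00, False, True),
    ("proanthocyanidin B isomer", "C30H26O12", 19.60, 900, 1.00, False, True),
    ("catechin", "C15H14O6", 20.25, 3400, 1.00, False, True),
    ("proanthocyanidin trimer", "C45H38O18", 20.90, 750, 1.00, False, True),
    ("proanthocyanidin B2", "C30H26O12", 21.80, 1600, 1.00, False, True),
    ("proanthocyanidin B isomer 2", "C30H26O12", 22.40, 500, 1.00, False, True),
    ("lariciresinol glucoside", "C26H34O11", 22.40, 250, 0.70, False, True),
    ("epicatechin", "C15H14O6", 23.00, 2900, 1.00, False, True),
    ("(epi)catechin propan-2-ol catabolite", "C15H16O6", 23.60, 480, 0.90, False, True),
    ("dihydrokaempferol hexoside", "C21H22O11", 23.60, 270, 0.90, False, True),
    ("epigallocatechin gallate", "C22H18O11", 24.20, 400, 1.00, False, True),
    ("galloylated proanthocyanidin dimer", "C37H30O16", 24.20, 200, 1.00, False, True),
    ("proanthocyanidin tetramer", "C60H50O24", 24.20, 150, 1.00, False, True),
    ("proanthocyanidin C1", "C45H38O18", 24.80, 1000, 1.00, False, True),
    ("galloylated proanthocyanidin dimer 2", "C37H30O16", 25.40, 1050, 1.00, False, True),
    ("galloylated proanthocyanidin trimer", "C52H42O22", 26.00, 500, 1.00, False, True),
    ("proanthocyanidin pentamer", "C75H62O30", 26.00, 250, 1.00, False, True),
    ("rutin", "C27H30O16", 27.40, 750, 1.00, True, True),
    ("epicatechin gallate", "C22H18O10", 28.00, 750, 1.00, False, True),
    ("catechin gallate", "C22H18O10", 28.60, 500, 1.00, False, True),
    ("embigenin", "C23H24O10", 28.60, 250, 0.90, True, False),
)

NONPOLAR_TEMPLATE = (
    ("ursolic acid", "C30H48O3", 66.70, 600, 0.05, True, False),
    ("linoleic acid", "C18H32O2", 67.30, 400, 0.00, False, True),
)

# volatiles: (name, formula, Kovats RI, relative weight)
VOLATILE_TEMPLATE = (
    ("volatile (C4H6O2, unidentified)", "C4H6O2", 732, 170),
    ("dihydroxyacetone", "C3H6O3", 894, 710),
    ("glycerol", "C3H8O3", 966, 980),
    ("catechol", "C6H6O2", 1188, 850),
    ("4-methylcatechol", "C7H8O2", 1284, 190),
    ("1,2,3-benzenetriol", "C6H6O3", 1362, 770),
    ("volatile (C8H8O3, unidentified)", "C8H8O3", 1593, 620),
    ("volatile (C9H8O3, unidentified)", "C9H8O3", 1801, 230),
    ("minor volatile 1", None, 760, 78),
    ("minor volatile 2", None, 842, 78),
    ("minor volatile 3", None, 1021, 78),
    ("minor volatile 4", None, 1088, 78),
    ("minor volatile 5", None, 1149, 78),
    ("minor volatile 6", None, 1243, 78),
    ("minor volatile 7", None, 1431, 78),
    ("minor volatile 8", None, 1502, 78),
    ("minor volatile 9", None, 1655, 78),
    ("minor volatile 10", None, 1718, 78),
    ("minor volatile 11", None, 1853, 78),
    ("minor volatile 12", None, 1922, 78),
)

MWCO_CUTOFFS = (3000.0, 10000.0, 30000.0, 50000.0, 100000.0)


@dataclass(frozen=True)
class GenerationConfig:
    """All tunables of the synthetic extract; defaults are the study conditions."""

    # LC time axis and sample load
    time_start_min: float = 0.0
    time_end_min: float = 70.0
    dt_min: float = 0.01
    sample_conc_ug_per_ml: float = 10000.0
    injection_vol_ul: float = 10.0
    dose_mg: float = 210.0
    ttc_ug: float = 90.0

    # detector response
    rf_area_per_ug: float = 0.85       # CAD, (pA*min)/ug
    fid_rf_area_per_ug: float = 120.0  # FID, arbitrary
    noise_sd_frac: float = 0.002       # of max clean signal
    baseline_level: float = 0.2

    # composition (mass fractions; renormalized to sum to 1)
    polar_fraction: float = 0.166
    polyphenol_fraction: float = 0.079
    nonpolar_fraction: float = 0.010
    tannin_fraction: float = 0.719
    volatile_fraction: float = 0.026

    # per-class constituent counts (None -> full template)
    n_polar: int | None = None
    n_polyphenol: int | None = None
    n_nonpolar: int | None = None
    n_volatile: int | None = None

    # narrow-peak shape
    sigma_range_min: tuple[float, float] = (0.045, 0.07)

    # tannin hump / polymer-size distribution
    n_tannin_members: int = 100
    tannin_mw_median_da: float = 130000.0
    tannin_mw_sigma_ln: float = 2.0
    tannin_rt_range_min: tuple[float, float] = (20.0, 40.0)
    tannin_sigma_range_min: tuple[float, float] = (1.5, 2.5)
    tannin_window_min: tuple[float, float] = (15.0, 45.0)

    # MS features
    rt_jitter_sd_min: float = 0.01
    n_decoys: int = 3
    decoy_offset_min: float = 0.3
    adulterant_spike: bool = False

    # calibration standards (injected masses, ug)
    standard_levels_ug: tuple[float, ...] = (0.008, 0.04, 0.2, 1.0)
    tannin_standard_levels_ug: tuple[float, ...] = (1.0, 10.0, 100.0)
    calib_noise_frac: float = 0.01

    # GC side
    alkane_carbons: tuple[int, ...] = (6, 7, 9) + tuple(range(10, 26))
    fid_standard_mass_ug: float = 0.05
    fid_area_noise_frac: float = 0.005
    mwco_cutoffs_da: tuple[float, ...] = MWCO_CUTOFFS

    def __post_init__(self) -> None:
        if self.time_start_min >= self.time_end_min or self.dt_min <= 0:
            raise ParameterError("invalid time axis")
        if self.noise_sd_frac < 0 or self.calib_noise_frac < 0:
            raise ParameterError("noise levels must be >= 0")
        for frac in (
            self.polar_fraction, self.polyphenol_fraction, self.nonpolar_fraction,
            self.tannin_fraction, self.volatile_fraction,
        ):
            if frac < 0:
                raise ParameterError("class fractions must be >= 0")
        if self.total_fraction() <= 0:
            raise ParameterError("at least one class fraction must be positive")
        if self.n_tannin_members < 1:
            raise ParameterError("need at least one tannin member")

    def total_fraction(self) -> float:
        return (
            self.polar_fraction + self.polyphenol_fraction + self.nonpolar_fraction
            + self.tannin_fraction + self.volatile_fraction
        )

    @property
    def load_ug(self) -> float:
        """Total injected sample mass on the LC side (plus GC equivalents)."""
        return self.sample_conc_ug_per_ml * self.injection_vol_ul / 1000.0

    def class_fractions(self) -> dict[str, float]:
        tot = self.total_fraction()
        return {
            "polar": self.polar_fraction / tot,
            "polyphenol": self.polyphenol_fraction / tot,
            "nonpolar": self.nonpolar_fraction / tot,
            "tannin": self.tannin_fraction / tot,
            "volatile": self.volatile_fraction / tot,
        }

    def time_axis(self) -> np.ndarray:
        n = int(round((self.time_end_min - self.time_start_min) / self.dt_min)) + 1
        return self.time_start_min + self.dt_min * np.arange(n)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: Mapping) -> "GenerationConfig":
        kwargs = dict(data)
        for key, val in list(kwargs.items()):
            if isinstance(val, list):
                kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        return cls(**kwargs)


@dataclass
class SyntheticDataset:
    """A complete multi-detector dataset plus its ground truth."""

    library: list[ConstituentSpec]
    cad_trace: Trace
    uv_trace: Trace
    ms_features: list[MSFeature]
    gc_fid_peaks: list[Peak]
    alkane_ladder: AlkaneLadder
    mwco_traces: dict[float, Trace]
    truth: pd.DataFrame          # per-constituent masses and per-dose amounts
    ms_truth: pd.DataFrame       # per-feature provenance incl. decoys
    standards: pd.DataFrame      # flavan-3-ol calibration points (area, mass)
    tannin_standards: pd.DataFrame
    fid_standards: pd.DataFrame
    config: GenerationConfig
    seed: int


# --------------------------------------------------------------------------
# rendering


def _gaussian_sum(
    time_min: np.ndarray,
    centers: Sequence[float],
    sigmas: Sequence[float],
    areas: Sequence[float],
) -> np.ndarray:
    y = np.zeros_like(time_min)
    for mu, sig, area in zip(centers, sigmas, areas):
        if area == 0:
            continue
        amp = area / (sig * np.sqrt(2.0 * np.pi))
        y += amp * np.exp(-0.5 * ((time_min - mu) / sig) ** 2)
    return y


def render_trace(
    library: Sequence[ConstituentSpec],
    channel: str,
    time_min: np.ndarray,
    rf_area_per_ug: float,
    injection_vol_ul: float,
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Trace:
    """Render one detector channel as a sum of Gaussians plus baseline/noise.

    Each constituent contributes a Gaussian of area = injected mass x
    response factor x channel weight. The CAD weight is 1 for every
    non-volatile constituent (the universality assumption); UV uses the
    per-constituent chromophore weight; volatiles do not register on the LC
    channels at all.
    """
    if channel not in ("CAD", "UV", "FID"):
        raise ParameterError(f"unknown channel {channel!r}")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    centers, sigmas, areas = [], [], []
    for c in library:
        if channel in ("CAD", "UV"):
            if c.klass == "volatile":
                continue
            weight = 1.0 if channel == "CAD" else c.uv_response_weight
        else:  # FID sees the volatile fraction only
            weight = 1.0 if c.klass == "volatile" else 0.0
        centers.append(c.rt_min)
        sigmas.append(c.peak_sigma_min)
        areas.append(c.mass_ug(injection_vol_ul) * rf_area_per_ug * weight)
    y = _gaussian_sum(time_min, centers, sigmas, areas) + baseline
    if noise_sd > 0:
        if rng is None:
            raise ParameterError("rng required when noise_sd > 0")
        y = y + rng.normal(0.0, noise_sd, size=time_min.size)
    return Trace(time_min, y, channel)


def render_ms_features(
    library: Sequence[ConstituentSpec],
    misalignment_decoys: int = 0,
    rt_jitter_sd: float = 0.0,
    decoy_offset_min: float = 0.3,
    rng: np.random.Generator | None = None,
    adulterant_spike: bool = False,
) -> tuple[list[MSFeature], pd.DataFrame]:
    """Emit adduct features for every ionizing constituent plus RT-shifted decoys.

    Intensities are arbitrary-unit draws uncorrelated with CAD area (MS is
    not quantitative here). Decoys are offset in RT by ``decoy_offset_min``
    from a host peak and are placed so that no constituent apex lies nearby;
    they are recorded in the truth table as non-contributors.
    """
    if misalignment_decoys < 0:
        raise ParameterError("decoy count must be >= 0")
    rng = rng or np.random.default_rng(0)
    feats: list[MSFeature] = []
    rows: list[dict] = []
    narrow = [c for c in library if c.klass not in ("tannin", "volatile")]
    for c in narrow:
        if not c.formula:
            continue
        for polarity, adduct in (("neg", "[M-H]-"), ("pos", "[M+H]+")):
            if polarity == "neg" and not c.ionizes_neg:
                continue
            if polarity == "pos" and not c.ionizes_pos:
                continue
            rt = c.rt_min + (rng.normal(0.0, rt_jitter_sd) if rt_jitter_sd > 0 else 0.0)
            feat = MSFeature(
                rt_min=float(rt),
                mz=float(masscalc.ion_mz(c.formula, adduct)),
                intensity=float(rng.uniform(0.3, 1.0) * 1e6),
                polarity=polarity,
            )
            feats.append(feat)
            rows.append(
                dict(rt_min=feat.rt_min, mz=feat.mz, intensity=feat.intensity,
                     polarity=polarity, parent=c.name, contributor=True)
            )
    apexes = np.array([c.rt_min for c in narrow]) if narrow else np.empty(0)
    hosts = rng.permutation(len(narrow)) if narrow else np.empty(0, dtype=int)
    placed = 0
    for idx in list(hosts) * 3:  # allow several passes if clearance fails
        if placed >= misalignment_decoys:
            break
        host = narrow[int(idx)]
        rt = host.rt_min + decoy_offset_min
        if apexes.size and np.min(np.abs(apexes - rt)) < 0.5 * decoy_offset_min:
            continue
        feat = MSFeature(
            rt_min=float(rt),
            mz=float(rng.uniform(300.0, 800.0)),
            intensity=float(rng.uniform(0.3, 1.0) * 1e6),
            polarity="neg",
        )
        feats.append(feat)
        rows.append(
            dict(rt_min=feat.rt_min, mz=feat.mz, intensity=feat.intensity,
                 polarity="neg", parent=host.name, contributor=False)
        )
        placed += 1
    if placed < misalignment_decoys:
        raise ParameterError("could not place all decoys with RT clearance")
    if adulterant_spike:
        # A-type proanthocyanidin dimer marker, as found in peanut skin / pine bark
        feat = MSFeature(rt_min=21.5, mz=575.1189,
                         intensity=float(rng.uniform(0.3, 1.0) * 1e6), polarity="neg")
        feats.append(feat)
        rows.append(dict(rt_min=feat.rt_min, mz=feat.mz, intensity=feat.intensity,
                         polarity="neg", parent="adulterant spike", contributor=False))
    truth = pd.DataFrame(
        rows, columns=["rt_min", "mz", "intensity", "polarity", "parent", "contributor"]
    )
    return feats, truth


def attenuate_by_cutoff(
    library: Sequence[ConstituentSpec],
    cutoff_da: float,
    config: GenerationConfig,
    rng: np.random.Generator | None = None,
) -> Trace:
    """CAD trace after ultrafiltration: constituents >= cutoff are retained
    on the filter and vanish from the chromatogram."""
    if cutoff_da <= 0:
        raise ParameterError("cutoff must be > 0")
    kept = [c for c in library if c.molecular_weight() < cutoff_da]
    noise_sd = _noise_sd(library, config)
    return render_trace(
        kept, "CAD", config.time_axis(), config.rf_area_per_ug,
        config.injection_vol_ul, noise_sd=noise_sd,
        baseline=config.baseline_level, rng=rng or np.random.default_rng(0),
    )


def _noise_sd(library: Sequence[ConstituentSpec], config: GenerationConfig) -> float:
    if config.noise_sd_frac == 0:
        return 0.0
    clean = render_trace(
        library, "CAD", config.time_axis(), config.rf_area_per_ug,
        config.injection_vol_ul, baseline=config.baseline_level,
    )
    return config.noise_sd_frac * float(clean.signal.max())


# --------------------------------------------------------------------------
# library construction


def _take(template, n: int | None, klass: str, rt_range: tuple[float, float]):
    rows = list(template)
    if n is None or n == len(rows):
        return rows
    if n < 0:
        raise ParameterError("class counts must be >= 0")
    if n <= len(rows):
        return rows[:n]
    # extend with unnamed constituents on a grid that avoids template RTs
    extra = n - len(rows)
    lo, hi = rt_range
    grid = np.linspace(lo, hi, extra + 2)[1:-1]
    taken = {r[2] for r in rows}
    out = rows[:]
    for i, rt in enumerate(grid):
        while any(abs(rt - t) < 0.35 for t in taken):
            rt += 0.18
        taken.add(rt)
        if klass == "volatile":
            out.append((f"synthetic {klass} {i + 1}", None, 700 + 60 * i, 60))
        else:
            out.append((f"synthetic {klass} {i + 1}", None, float(rt), 100, 0.0,
                        False, False))
    return out


def build_library(
    config: GenerationConfig, rng: np.random.Generator
) -> list[ConstituentSpec]:
    """Instantiate the constituent library with masses scaled to the load."""
    fracs = config.class_fractions()
    load = config.load_ug
    vol = config.injection_vol_ul
    specs: list[ConstituentSpec] = []

    lc_classes = {
        "polar": _take(POLAR_TEMPLATE, config.n_polar, "polar", (0.9, 7.5)),
        "polyphenol": _take(
            POLYPHENOL_TEMPLATE, config.n_polyphenol, "polyphenol", (9.0, 34.0)
        ),
        "nonpolar": _take(
            NONPOLAR_TEMPLATE, config.n_nonpolar, "nonpolar", (66.0, 69.5)
        ),
    }
    rt_to_peak: dict[float, int] = {}
    all_rts = sorted(
        {row[2] for rows in lc_classes.values() for row in rows}
    )
    for i, rt in enumerate(all_rts, start=1):
        rt_to_peak[rt] = i
    tannin_peak_id = len(all_rts) + 1

    for klass, rows in lc_classes.items():
        if not rows:
            continue
        total_w = sum(r[3] for r in rows)
        for name, formula, rt, w, uv_w, pos, neg in rows:
            mass = fracs[klass] * load * w / total_w
            sigma = float(rng.uniform(*config.sigma_range_min))
            specs.append(
                ConstituentSpec(
                    name=name, formula=formula, klass=klass, rt_min=rt,
                    conc_ug_per_ml=mass / vol * 1000.0, peak_sigma_min=sigma,
                    uv_response_weight=uv_w, ionizes_pos=pos, ionizes_neg=neg,
                    cad_peak=rt_to_peak[rt],
                )
            )

    # tannin members: equal masses at log-normal quantiles (stratified draw)
    n = config.n_tannin_members
    if fracs["tannin"] > 0:
        dist = stats.lognorm(
            s=config.tannin_mw_sigma_ln, scale=config.tannin_mw_median_da
        )
        quantiles = (np.arange(n) + 0.5) / n
        mws = dist.ppf(quantiles)
        rts = np.linspace(*config.tannin_rt_range_min, n)
        sigmas = np.linspace(*config.tannin_sigma_range_min, n)
        member_mass = fracs["tannin"] * load / n
        for i in range(n):
            specs.append(
                ConstituentSpec(
                    name=f"tannin member {i + 1:03d}", formula="polymer",
                    klass="tannin", rt_min=float(rts[i]),
                    conc_ug_per_ml=member_mass / vol * 1000.0,
                    peak_sigma_min=float(sigmas[i]), uv_response_weight=0.95,
                    mw_da=float(mws[i]), cad_peak=tannin_peak_id,
                )
            )

    # volatiles live on the GC side; RT on the LC axis is irrelevant but must
    # be valid, so reuse the Kovats RI scale divided by 100 as a placeholder.
    vol_rows = _take(VOLATILE_TEMPLATE, config.n_volatile, "volatile", (700, 1950))
    if vol_rows and fracs["volatile"] > 0:
        total_w = sum(r[3] for r in vol_rows)
        for name, formula, ri, w in vol_rows:
            mass = fracs["volatile"] * load * w / total_w
            specs.append(
                ConstituentSpec(
                    name=name, formula=formula, klass="volatile",
                    rt_min=ri / 100.0, conc_ug_per_ml=mass / vol * 1000.0,
                    peak_sigma_min=0.03, kovats_ri=float(ri),
                )
            )
    return specs


def _alkane_ladder(config: GenerationConfig) -> AlkaneLadder:
    # temperature-programmed run: retention roughly linear in carbon number
    pairs = [
        (n, -1.2 + 0.92 * n + 0.004 * n**2) for n in config.alkane_carbons
    ]
    return AlkaneLadder(pairs)


def _truth_table(
    library: Sequence[ConstituentSpec], config: GenerationConfig
) -> pd.DataFrame:
    load = config.load_ug
    rows = []
    tannins = [c for c in library if c.klass == "tannin"]
    for c in library:
        if c.klass == "tannin":
            continue
        mass = c.mass_ug(config.injection_vol_ul)
        rows.append(
            dict(
                name=c.name, klass=c.klass, formula=c.formula or "",
                rt_min=c.rt_min, cad_peak=c.cad_peak if c.cad_peak else -1,
                mass_ug=mass,
                amount_ug_per_dose=mass / load * config.dose_mg * 1000.0,
                mw_da=c.molecular_weight(), uv_weight=c.uv_response_weight,
                kovats_ri=c.kovats_ri if c.kovats_ri else np.nan,
            )
        )
    if tannins:
        mass = sum(t.mass_ug(config.injection_vol_ul) for t in tannins)
        lo, hi = config.tannin_window_min
        rows.append(
            dict(
                name="tannins (polymeric proanthocyanidins)", klass="tannin",
                formula="polymer", rt_min=0.5 * (lo + hi),
                cad_peak=tannins[0].cad_peak, mass_ug=mass,
                amount_ug_per_dose=mass / load * config.dose_mg * 1000.0,
                mw_da=float(np.median([t.mw_da for t in tannins])),
                uv_weight=0.95, kovats_ri=np.nan,
            )
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["cad_peak", "rt_min", "name"]).reset_index(drop=True)


def _standards(
    rng: np.random.Generator, levels: Sequence[float], names: Sequence[str],
    rf: float, noise_frac: float,
) -> pd.DataFrame:
    rows = []
    for name in names:
        for mass in levels:
            area = mass * rf * (1.0 + rng.normal(0.0, noise_frac))
            rows.append(dict(name=name, injected_mass_ug=mass, area=max(area, 0.0)))
    return pd.DataFrame(rows)


def generate_dataset(
    config: GenerationConfig | None = None, seed: int = 0
) -> SyntheticDataset:
    """Generate the full multi-detector dataset for one (config, seed) pair.

    Identical (config, seed) pairs reproduce the dataset bit-for-bit.
    """
    config = config or GenerationConfig()
    rng = np.random.default_rng(seed)
    library = build_library(config, rng)
    t = config.time_axis()
    noise_sd = _noise_sd(library, config)

    cad = render_trace(
        library, "CAD", t, config.rf_area_per_ug, config.injection_vol_ul,
        noise_sd=noise_sd, baseline=config.baseline_level,
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    uv = render_trace(
        library, "UV", t, config.rf_area_per_ug, config.injection_vol_ul,
        noise_sd=noise_sd, baseline=config.baseline_level,
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    ms_features, ms_truth = render_ms_features(
        library, misalignment_decoys=config.n_decoys,
        rt_jitter_sd=config.rt_jitter_sd_min,
        decoy_offset_min=config.decoy_offset_min,
        rng=np.random.default_rng(rng.integers(2**31)),
        adulterant_spike=config.adulterant_spike,
    )
    mwco = {
        float(cutoff): attenuate_by_cutoff(
            library, cutoff, config, rng=np.random.default_rng(rng.integers(2**31))
        )
        for cutoff in config.mwco_cutoffs_da
    }

    ladder = _alkane_ladder(config)
    fid_peaks: list[Peak] = []
    fid_rng = np.random.default_rng(rng.integers(2**31))
    for c in library:
        if c.klass != "volatile":
            continue
        rt = ri_to_rt(c.kovats_ri, ladder)
        mass = c.mass_ug(config.injection_vol_ul)
        area = mass * config.fid_rf_area_per_ug
        if config.fid_area_noise_frac > 0:
            area *= 1.0 + fid_rng.normal(0.0, config.fid_area_noise_frac)
        sigma = c.peak_sigma_min
        fid_peaks.append(
            Peak(
                apex_rt_min=float(rt), start_rt_min=float(rt - 4 * sigma),
                end_rt_min=float(rt + 4 * sigma), area=float(max(area, 0.0)),
                height=float(area / (sigma * np.sqrt(2 * np.pi))),
                channel="FID", label=c.name,
            )
        )
    fid_peaks.sort(key=lambda p: p.apex_rt_min)

    std_rng = np.random.default_rng(rng.integers(2**31))
    standards = _standards(
        std_rng, config.standard_levels_ug,
        ("catechin", "epicatechin", "proanthocyanidin B2", "proanthocyanidin C1"),
        config.rf_area_per_ug, config.calib_noise_frac,
    )
    tannin_standards = _standards(
        std_rng, config.tannin_standard_levels_ug, ("tannin retentate",),
        config.rf_area_per_ug, config.calib_noise_frac,
    )
    fid_standards = _standards(
        std_rng, (config.fid_standard_mass_ug,),
        tuple(f"C{n} alkane" for n in config.alkane_carbons),
        config.fid_rf_area_per_ug, config.calib_noise_frac,
    )

    return SyntheticDataset(
        library=library, cad_trace=cad, uv_trace=uv, ms_features=ms_features,
        gc_fid_peaks=fid_peaks, alkane_ladder=ladder, mwco_traces=mwco,
        truth=_truth_table(library, config), ms_truth=ms_truth,
        standards=standards, tannin_standards=tannin_standards,
        fid_standards=fid_standards, config=config, seed=seed,
    )
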