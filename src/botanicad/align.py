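"""CAD-MS feature alignment and identification-confidence bookkeeping.

A CAD peak often hides several co-eluting components. Candidate contributors
are chosen per ionization polarity from the features present around the peak
window: any feature at >= 20 % of that polarity's most intense in-window
feature is tested for apex alignment, and only features whose apex RT lies
within ``rt_tol`` of the CAD apex are accepted. A feature whose extracted-ion
apex is slightly delayed relative to the CAD apex is thereby rejected even if
it is intense.

Identification confidence follows a five-tier precedence: reference (RT +
accurate mass + MS/MS against a reference standard) > matched (accurate mass
+ MS/MS vs literature/databases) > tentative (supported structure, limited
literature) > partial (formula only) > unknown (no plausible formula).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParameterError
from .synth import MSFeature
from .traces import Peak

TIERS = ("reference", "matched", "tentative", "partial", "unknown")


@dataclass(frozen=True)
class EvidenceFlags:
    """Boolean identification evidence for one constituent."""

    reference_standard_match: bool = False
    literature_db_match: bool = False
    tentative_support: bool = False
    formula_only: bool = False
    formula_assignable: bool = False


@dataclass
class ConstituentRecord:
    """One row of the final constituent table."""

    cad_peak_id: int
    sub_label: str
    rt_min: float
    identification: str
    formula: str | None
    amount_ug_per_dose: float | None
    confidence: str
    contributing_mz: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.confidence not in TIERS:
            raise ParameterError(f"confidence must be one of {TIERS}")


def contributors(
    cad_peak: Peak,
    features: Sequence[MSFeature],
    rel_intensity_threshold: float = 0.20,
    rt_tol_min: float = 0.10,
    window_pad_min: float = 0.25,
) -> tuple[list[MSFeature], list[MSFeature]]:
    """Split in-window MS features into (accepted, rejected) contributor lists.

    The peak window is padded by ``window_pad_min`` so that features whose
    apex falls just past the integration boundary (the classic slightly
    delayed co-eluter) are still evaluated - and rejected - by the apex rule
    rather than silently dropped.
    """
    if not (0 < rel_intensity_threshold <= 1):
        raise ParameterError("rel_intensity_threshold must be in (0, 1]")
    if rt_tol_min <= 0:
        raise ParameterError("rt_tol_min must be > 0")
    lo = cad_peak.start_rt_min - window_pad_min
    hi = cad_peak.end_rt_min + window_pad_min
    accepted: list[MSFeature] = []
    rejected: list[MSFeature] = []
    for polarity in ("pos", "neg"):
        in_window = [
            f for f in features if f.polarity == polarity and lo <= f.rt_min <= hi
        ]
        if not in_window:
            continue
        base = max(f.intensity for f in in_window)
        for f in in_window:
            if f.intensity < rel_intensity_threshold * base:
                continue
            if abs(f.rt_min - cad_peak.apex_rt_min) <= rt_tol_min:
                accepted.append(f)
            else:
                rejected.append(f)
    return accepted, rejected


def assign_confidence(flags: EvidenceFlags) -> str:
    """First true flag in precedence order; formula-only evidence is partial."""
    if flags.reference_standard_match:
        return "reference"
    if flags.literature_db_match:
        return "matched"
    if flags.tentative_support:
        return "tentative"
    if flags.formula_only or flags.formula_assignable:
        return "partial"
    return "unknown"


def tally_confidence(
    records: Iterable[ConstituentRecord | str],
) -> dict[str, int]:
    """Counts per tier plus 'total'. Accepts records or bare tier strings."""
    counts = {tier: 0 for tier in TIERS}
    total = 0
    for rec in records:
        tier = rec if isinstance(rec, str) else rec.confidence
        tier = tier.strip().lower()
        if tier not in counts:
            raise ParameterError(f"unknown confidence tier {tier!r}")
        counts[tier] += 1
        total += 1
    counts["total"] = total
    return counts


def load_constituent_table(path=None) -> pd.DataFrame:
    """Load a constituent table CSV (default: the bundled reference profile
    of a commercial grape seed extract, GSE-1)."""
    if path is None:
        ref = resources.files("botanicad.data") / "gse1_constituents.csv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, comment="#")
    return pd.read_csv(path, comment="#")


def load_volatile_table(path=None) -> pd.DataFrame:
    """Load a volatile-constituent table CSV (default: the bundled GC profile
    of the same extract)."""
    if path is None:
        ref = resources.files("botanicad.data") / "gse1_volatiles.csv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, comment="#")
    return pd.read_csv(path, comment="#")


def records_from_table(df: pd.DataFrame) -> list[ConstituentRecord]:
    """Build ConstituentRecords from a constituent table CSV."""
    records = []
    for _, row in df.iterrows():
        amount = row.get("amount_ug_per_dose")
        records.append(
            ConstituentRecord(
                cad_peak_id=int(row["cad_peak"]),
                sub_label=str(row.get("sub", "") or ""),
                rt_min=float(row["rt_min"]) if pd.notna(row["rt_min"]) else 0.0,
                identification=str(row["identification"]),
                formula=(str(row["formula"]) if pd.notna(row.get("formula")) and
                         str(row.get("formula")) else None),
                amount_ug_per_dose=float(amount) if pd.notna(amount) else None,
                confidence=str(row["confidence"]).strip().lower(),
            )
        )
    return records
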