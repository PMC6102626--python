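"""Decision-tree safety assessment over the final constituent table.

The rule engine renders the tiered in-silico screening logic used for
botanical ingredients: (1) a constituent with known structure that is
commonly consumed in food, at a supplement exposure no higher than dietary
exposure, is comparable to diet; (2) otherwise published safety data with an
adequate margin of safety clears it; (3) otherwise an amount below the
threshold of toxicological concern clears it; (4) anything left needs
follow-up work. Food-exposure figures are user-supplied annotations (from
food-composition databases), not computed here, and the Cramer
classification itself is out of scope - the TTC value is configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .align import ConstituentRecord
from .errors import ParameterError
from .quant import DoseContext

OUTCOMES = ("diet_comparable", "mos_supported", "ttc_cleared", "needs_followup")


@dataclass(frozen=True)
class SafetyAnnotation:
    """External knowledge about one constituent."""

    constituent_id: str
    known_structure: bool = False
    found_in_food: bool = False
    dietary_exposure_ug_per_day: float | None = None
    has_safety_data_with_mos: bool = False

    def __post_init__(self) -> None:
        if (
            self.dietary_exposure_ug_per_day is not None
            and self.dietary_exposure_ug_per_day < 0
        ):
            raise ParameterError("dietary exposure must be >= 0")


@dataclass(frozen=True)
class SafetyVerdict:
    constituent_id: str
    outcome: str
    rationale: str

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ParameterError(f"outcome must be one of {OUTCOMES}")


def assess(
    record: ConstituentRecord,
    annotation: SafetyAnnotation | None,
    ctx: DoseContext,
) -> SafetyVerdict:
    """Apply the ordered decision rules to one constituent.

    A missing annotation is treated as all-unknown, falling through to the
    TTC comparison.
    """
    if record.amount_ug_per_dose is None:
        raise ParameterError(
            f"{record.identification}: an amount is required for assessment"
        )
    cid = annotation.constituent_id if annotation else record.identification
    amount = record.amount_ug_per_dose
    if annotation is not None:
        if (
            annotation.known_structure
            and annotation.found_in_food
            and annotation.dietary_exposure_ug_per_day is not None
            and amount <= annotation.dietary_exposure_ug_per_day
        ):
            return SafetyVerdict(
                cid, "diet_comparable",
                f"supplement exposure {amount:g} ug/day within dietary exposure "
                f"{annotation.dietary_exposure_ug_per_day:g} ug/day",
            )
        if annotation.has_safety_data_with_mos:
            return SafetyVerdict(
                cid, "mos_supported",
                "published safety data establish an adequate margin of safety",
            )
    if amount < ctx.ttc_ug:
        return SafetyVerdict(
            cid, "ttc_cleared",
            f"{amount:g} ug/day below the TTC of {ctx.ttc_ug:g} ug/day",
        )
    return SafetyVerdict(
        cid, "needs_followup",
        f"{amount:g} ug/day at or above the TTC with no clearing evidence",
    )


def assess_all(
    records: Sequence[ConstituentRecord],
    annotations: Mapping[str, SafetyAnnotation],
    ctx: DoseContext,
) -> list[SafetyVerdict]:
    return [assess(r, annotations.get(r.identification), ctx) for r in records]


def summarize(verdicts: Iterable[SafetyVerdict]) -> dict:
    """Counts per outcome plus the list of constituents needing follow-up."""
    counts = {outcome: 0 for outcome in OUTCOMES}
    followup: list[str] = []
    for v in verdicts:
        counts[v.outcome] += 1
        if v.outcome == "needs_followup":
            followup.append(v.constituent_id)
    counts["total"] = sum(counts[o] for o in OUTCOMES)
    return {"counts": counts, "needs_followup": followup}
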