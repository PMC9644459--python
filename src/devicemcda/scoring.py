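"""Score device evidence profiles against a weighted-criteria instrument.

Each criterion contributes ``weight_pct * score_fraction`` points, where the
fraction comes from the scoring option the device's evidence lands on.
Totals live on a 0-100 scale. A device that lands on any exclusion option
is removed from the tender: its per-criterion audit trail is kept, but no
total is reported, so an excluded device can never outrank anything by
arithmetic accident.

Evidence per criterion is either a named option (categorical criteria) or a
raw measurement that the engine buckets: technical fulfilment as a
percentage or a ``specs_met/specs_required`` pair, supplier fulfilment as a
percentage over the last three years, and refund/replacement behaviour as a
stagnant-report count over the last year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import CriteriaConfig, Criterion, ScoringOption

__all__ = [
    "SpecCount",
    "DeviceProfile",
    "CriterionScore",
    "Assessment",
    "ComparisonReport",
    "ScoringError",
    "fulfillment_percentage",
    "select_option",
    "score_device",
    "compare_devices",
]

#: Totals closer than this are reported as ties.
TIE_TOL = 1e-9


class ScoringError(ValueError):
    """Evidence that cannot be scored under the given instrument."""


@dataclass(frozen=True)
class SpecCount:
    """Raw technical evidence: specifications met out of those required."""

    specs_met: int
    specs_required: int


Evidence = str | int | float | SpecCount


@dataclass(frozen=True)
class DeviceProfile:
    """One device's evidence across every criterion of an instrument.

    ``evidence`` maps criterion_id to either an option_id string or a raw
    measurement. ``is_local_product`` gates options reserved for Egyptian-
    origin products. ``price`` is optional: the technical phase ignores it
    and the financial phase consumes it.
    """

    device_id: str
    supplier_id: str = ""
    evidence: dict[str, Evidence] = field(default_factory=dict)
    is_local_product: bool = False
    price: float | None = None

    def __post_init__(self) -> None:
        if self.price is not None and self.price < 0:
            raise ScoringError(f"device {self.device_id!r}: negative price")


@dataclass(frozen=True)
class CriterionScore:
    criterion_id: str
    option_id: str
    score_fraction: float
    points: float
    excluded_here: bool


@dataclass(frozen=True)
class Assessment:
    """Scored result for one device.

    ``total`` is None when the device is excluded — exclusion is not a zero
    score, it is removal from the tender.
    """

    device_id: str
    scores: tuple[CriterionScore, ...]
    total: float | None
    excluded: bool
    exclusion_reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class ComparisonReport:
    config_id: str
    assessments: tuple[Assessment, ...]  # non-excluded, total descending
    excluded: tuple[Assessment, ...]
    ties: tuple[frozenset[str], ...]
    errors: dict[str, str] = field(default_factory=dict)


def fulfillment_percentage(specs_met: int, specs_required: int) -> float:
    """Percentage of required technical specifications a device meets.

    E.g. 16 of 20 specifications gives 80.0.
    """
    if specs_required < 1:
        raise ScoringError(f"specs_required {specs_required} must be >= 1")
    if specs_met < 0:
        raise ScoringError(f"specs_met {specs_met} must be >= 0")
    if specs_met > specs_required:
        raise ScoringError(
            f"specs_met {specs_met} exceeds specs_required {specs_required}"
        )
    return 100.0 * specs_met / specs_required


def select_option(
    criterion: Criterion, evidence: Evidence, is_local_product: bool = False
) -> ScoringOption:
    """Resolve a device's evidence on one criterion to a scoring option.

    A string selects the named option directly (the only route for
    categorical criteria; also used for named quantitative-criterion options
    such as a supplier that never supplied before). Numbers are bucketed by
    the criterion's interval rules; a ``SpecCount`` is first converted to a
    fulfilment percentage. Options flagged ``local_only`` (the CE-only
    certificate route) reject non-local products.
    """
    if isinstance(evidence, str):
        try:
            opt = criterion.option(evidence)
        except KeyError as exc:
            raise ScoringError(str(exc)) from exc
        if opt.local_only and not is_local_product:
            raise ScoringError(
                f"option {opt.option_id!r} on {criterion.criterion_id!r} is "
                "restricted to local products"
            )
        return opt

    if criterion.measurement_kind == "categorical":
        raise ScoringError(
            f"criterion {criterion.criterion_id!r} is categorical; evidence "
            "must name an option"
        )
    if isinstance(evidence, SpecCount):
        if criterion.measurement_kind != "technical_fulfillment_pct":
            raise ScoringError(
                f"spec counts are only valid technical evidence, not for "
                f"{criterion.criterion_id!r}"
            )
        value = fulfillment_percentage(evidence.specs_met, evidence.specs_required)
    else:
        value = float(evidence)
    if criterion.measurement_kind.endswith("_pct") and not 0.0 <= value <= 100.0:
        raise ScoringError(
            f"{criterion.criterion_id!r}: percentage {value} outside [0,100]"
        )
    if criterion.measurement_kind == "stagnant_count" and value < 0:
        raise ScoringError(f"{criterion.criterion_id!r}: negative count {value}")
    for rule in criterion.bucket_rules:
        if rule.interval.contains(value):
            return criterion.option(rule.option_id)
    raise ScoringError(
        f"{criterion.criterion_id!r}: no bucket covers measurement {value}"
    )


def score_device(profile: DeviceProfile, config: CriteriaConfig) -> Assessment:
    """Score one device on every criterion and aggregate to a 0-100 total."""
    missing = [
        c.criterion_id for c in config.criteria if c.criterion_id not in profile.evidence
    ]
    if missing:
        raise ScoringError(
            f"device {profile.device_id!r}: missing evidence for {missing}"
        )
    scores: list[CriterionScore] = []
    reasons: list[str] = []
    for c in config.criteria:
        opt = select_option(c, profile.evidence[c.criterion_id], profile.is_local_product)
        scores.append(
            CriterionScore(
                criterion_id=c.criterion_id,
                option_id=opt.option_id,
                score_fraction=opt.score_fraction,
                points=opt.score_fraction * c.weight_pct,
                excluded_here=opt.is_exclusion,
            )
        )
        if opt.is_exclusion:
            reasons.append(f"{c.criterion_id}: {opt.label}")
    excluded = bool(reasons)
    total = None if excluded else sum(s.points for s in scores)
    return Assessment(
        device_id=profile.device_id,
        scores=tuple(scores),
        total=total,
        excluded=excluded,
        exclusion_reasons=tuple(reasons),
    )


def compare_devices(
    profiles: list[DeviceProfile] | tuple[DeviceProfile, ...],
    config: CriteriaConfig,
) -> ComparisonReport:
    """Score any number of devices and rank the survivors by total.

    Per-device scoring errors are collected into the report rather than
    aborting the whole comparison. Excluded devices are listed after the
    ranking with their reasons; equal totals are annotated as ties.
    """
    if not profiles:
        raise ScoringError("no device profiles supplied")
    ok: list[Assessment] = []
    excluded: list[Assessment] = []
    errors: dict[str, str] = {}
    for p in profiles:
        try:
            a = score_device(p, config)
        except ScoringError as exc:
            errors[p.device_id] = str(exc)
            continue
        (excluded if a.excluded else ok).append(a)
    ok.sort(key=lambda a: (-a.total, a.device_id))  # type: ignore[operator]
    tie_groups: list[frozenset[str]] = []
    i = 0
    while i < len(ok):
        j = i + 1
        while j < len(ok) and abs(ok[j].total - ok[i].total) <= TIE_TOL:
            j += 1
        if j - i > 1:
            tie_groups.append(frozenset(a.device_id for a in ok[i:j]))
        i = j
    return ComparisonReport(
        config_id=config.config_id,
        assessments=tuple(ok),
        excluded=tuple(excluded),
        ties=tuple(tie_groups),
        errors=errors,
    )
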