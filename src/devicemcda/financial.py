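"""Financial evaluation and sensitivity analysis.

The tender runs in two strictly separate phases: a technical phase that
produces the 0-100 MCDA totals, and a financial phase — run by a pricing
committee independent of the technical committee — that divides each
surviving device's price by its total. The device with the lowest price
per point offers the best value for money; the ranking is a
recommendation, and ties are reported back to the committee rather than
broken.

The sensitivity tools reproduce the pilot-phase exercise of perturbing one
criterion's weight (renormalising the rest proportionally) and watching
for rank reversals among the compared devices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import CriteriaConfig
from .scoring import Assessment, DeviceProfile, compare_devices

__all__ = [
    "PricedResult",
    "ValueRanking",
    "ReversalEvent",
    "SensitivityReport",
    "FinancialError",
    "rank_by_value",
    "reweight",
    "rank_reversal_scan",
]

TIE_TOL = 1e-9


class FinancialError(ValueError):
    pass


@dataclass(frozen=True)
class PricedResult:
    device_id: str
    total: float
    price: float
    price_per_point: float


@dataclass(frozen=True)
class ValueRanking:
    """Price-per-point recommendation, ascending (lowest = best value).

    Excluded devices never enter the financial phase; devices whose total
    is zero cannot be priced per point and are flagged unpriceable.
    """

    ranking: tuple[PricedResult, ...]
    excluded_device_ids: tuple[str, ...]
    unpriceable_device_ids: tuple[str, ...]
    ties: tuple[frozenset[str], ...]


@dataclass(frozen=True)
class ReversalEvent:
    criterion_id: str
    weight_pct: float
    new_leader: str


@dataclass(frozen=True)
class SensitivityReport:
    criterion_id: str
    grid: tuple[float, ...]
    baseline_leader: str
    baseline_ranking: tuple[str, ...]
    leaders: tuple[str, ...]  # leader at each grid point
    reversals: tuple[ReversalEvent, ...]


def rank_by_value(
    assessments: list[Assessment] | tuple[Assessment, ...],
    prices: dict[str, float],
) -> ValueRanking:
    """Rank non-excluded assessments by price per point, ascending."""
    results: list[PricedResult] = []
    excluded: list[str] = []
    unpriceable: list[str] = []
    for a in assessments:
        if a.excluded:
            excluded.append(a.device_id)
            continue
        if a.device_id not in prices:
            raise FinancialError(f"no price for device {a.device_id!r}")
        price = float(prices[a.device_id])
        if price < 0:
            raise FinancialError(f"negative price for device {a.device_id!r}")
        if a.total is None or a.total <= 0:
            unpriceable.append(a.device_id)
            continue
        results.append(PricedResult(a.device_id, a.total, price, price / a.total))
    results.sort(key=lambda r: (r.price_per_point, r.device_id))
    ties: list[frozenset[str]] = []
    i = 0
    while i < len(results):
        j = i + 1
        while (
            j < len(results)
            and abs(results[j].price_per_point - results[i].price_per_point) <= TIE_TOL
        ):
            j += 1
        if j - i > 1:
            ties.append(frozenset(r.device_id for r in results[i:j]))
        i = j
    return ValueRanking(
        ranking=tuple(results),
        excluded_device_ids=tuple(excluded),
        unpriceable_device_ids=tuple(unpriceable),
        ties=tuple(ties),
    )


def reweight(
    config: CriteriaConfig, criterion_id: str, new_weight_pct: float
) -> CriteriaConfig:
    """Set one criterion's weight and rescale the rest proportionally.

    The remaining weights are multiplied by ``(100 - new) / (100 - old)`` so
    the sum returns to 100; ranks are re-derived from the new weights (ties
    keep the previous rank order). Scoring options are untouched.
    """
    if not 0.0 < new_weight_pct < 100.0:
        raise FinancialError(
            f"new weight {new_weight_pct} must be strictly between 0 and 100"
        )
    target = config.criterion(criterion_id)  # KeyError if absent
    old = target.weight_pct
    rest = sum(c.weight_pct for c in config.criteria) - old
    if rest <= 0:
        raise FinancialError("cannot rescale: no weight mass on other criteria")
    scale = (100.0 - new_weight_pct) / rest
    new_weights = {
        c.criterion_id: new_weight_pct if c.criterion_id == criterion_id
        else c.weight_pct * scale
        for c in config.criteria
    }
    order = sorted(
        config.criteria, key=lambda c: (-new_weights[c.criterion_id], c.rank)
    )
    criteria = tuple(
        replace(c, rank=i + 1, weight_pct=new_weights[c.criterion_id])
        for i, c in enumerate(order)
    )
    return replace(config, criteria=criteria)


def rank_reversal_scan(
    profiles: list[DeviceProfile] | tuple[DeviceProfile, ...],
    config: CriteriaConfig,
    criterion_id: str,
    grid: list[float] | tuple[float, ...],
) -> SensitivityReport:
    """Sweep one criterion's weight over a grid and record leader changes.

    At each grid value the configuration is reweighted and every profile
    rescored; a reversal event is recorded whenever the top-ranked device
    differs from the baseline leader. The arithmetic is seedless, so the
    report is exactly reproducible from the grid.
    """
    baseline = compare_devices(profiles, config)
    if len(baseline.assessments) < 2:
        raise FinancialError(
            "rank-reversal scan needs at least two non-excluded devices"
        )
    base_leader = baseline.assessments[0].device_id
    leaders: list[str] = []
    events: list[ReversalEvent] = []
    for w in grid:
        perturbed = reweight(config, criterion_id, w)
        report = compare_devices(profiles, perturbed)
        if not report.assessments:
            raise FinancialError(f"no scoreable devices at weight {w}")
        leader = report.assessments[0].device_id
        leaders.append(leader)
        if leader != base_leader:
            events.append(ReversalEvent(criterion_id, w, leader))
    return SensitivityReport(
        criterion_id=criterion_id,
        grid=tuple(float(w) for w in grid),
        baseline_leader=base_leader,
        baseline_ranking=tuple(a.device_id for a in baseline.assessments),
        leaders=tuple(leaders),
        reversals=tuple(events),
    )
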