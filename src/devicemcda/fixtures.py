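"""Seedable synthetic panels, device profiles and prices with known truth.

Everything the other modules consume can be generated here, so the whole
engine is testable without any real tender data. Panels emulate the
workshop voting protocol: experts perturb a true importance ordering by
adjacent swaps and report swing votes equal to the true adjacent ratio
minus one plus Gaussian noise (truncated to the 0-1 voting scale, which
introduces a slight bias at extreme ratios; rejection sampling is
deliberately not used so every expert always votes).

Device profiles are drawn option-first: for each criterion an option is
sampled, then a raw measurement consistent with that option is synthesised
for quantitative criteria. Because the generator knows which option it
drew, the ground-truth total is a naive weight-times-fraction sum over the
drawn options — independent of the scoring engine's bucketing path, which
must map every synthesised measurement back onto the drawn option.

No attempt is made to model real Egyptian tender distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .elicitation import RankVote, SwingVote, VoteSet, swing_votes_from_weights
from .model import CriteriaConfig, Criterion, Interval
from .scoring import Assessment, CriterionScore, DeviceProfile, SpecCount

__all__ = [
    "PanelSpec",
    "ProfileSpec",
    "FixtureError",
    "gen_vote_set",
    "gen_profiles",
    "naive_total",
    "final_workshop_vote_fixture",
]


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class PanelSpec:
    """Synthetic expert panel around a known true weight vector.

    ``rank_noise`` is the per-expert probability of swapping each adjacent
    pair of the true ordering; ``swing_noise_sd`` the SD of additive
    Gaussian noise on each swing vote.
    """

    n_experts: int
    true_weights: dict[str, float]
    rank_noise: float = 0.0
    swing_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise FixtureError("n_experts must be >= 1")
        if not 0.0 <= self.rank_noise <= 1.0:
            raise FixtureError("rank_noise must be in [0,1]")
        if self.swing_noise_sd < 0:
            raise FixtureError("swing_noise_sd must be >= 0")


def gen_vote_set(spec: PanelSpec) -> VoteSet:
    """Draw a deterministic vote set for the panel spec."""
    rng = np.random.default_rng(spec.seed)
    ordering = tuple(
        sorted(spec.true_weights, key=lambda c: -spec.true_weights[c])
    )
    weights = [spec.true_weights[c] for c in ordering]
    true_votes = []
    for i, (hi, lo) in enumerate(zip(weights, weights[1:]), start=1):
        v = hi / lo - 1.0
        if not 0.0 <= v <= 1.0:
            raise FixtureError(
                f"true adjacent ratio at pair {i} is {hi / lo:.4f}, outside "
                "the voting scale [1,2]"
            )
        true_votes.append(v)

    rank_votes = []
    swing_votes = []
    for e in range(spec.n_experts):
        expert = f"expert{e + 1:02d}"
        order = list(ordering)
        for i in range(len(order) - 1):
            if rng.random() < spec.rank_noise:
                order[i], order[i + 1] = order[i + 1], order[i]
        rank_votes.append(RankVote(expert, tuple(order)))
        noise = rng.normal(0.0, spec.swing_noise_sd, size=len(true_votes))
        for i, (v, n) in enumerate(zip(true_votes, noise), start=1):
            swing_votes.append(
                SwingVote(expert, i, float(np.clip(v + n, 0.0, 1.0)))
            )
    return VoteSet(tuple(rank_votes), tuple(swing_votes))


@dataclass(frozen=True)
class ProfileSpec:
    """Distribution over synthetic device profiles.

    ``option_probs`` optionally fixes per-criterion option probabilities
    (criterion_id -> {option_id: p}); criteria without an entry use the
    default: exclusion options jointly sized so a device is excluded with
    probability ``exclusion_rate`` overall, non-exclusion options uniform
    on the remainder.
    """

    n_devices: int
    exclusion_rate: float = 0.0
    price_range: tuple[float, float] = (1000.0, 50000.0)
    option_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    with_prices: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_devices < 1:
            raise FixtureError("n_devices must be >= 1")
        if not 0.0 <= self.exclusion_rate < 1.0:
            raise FixtureError("exclusion_rate must be in [0,1)")
        if self.price_range[0] < 0 or self.price_range[1] < self.price_range[0]:
            raise FixtureError(f"bad price_range {self.price_range}")
        for cid, probs in self.option_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise FixtureError(f"option probabilities for {cid!r} do not sum to 1")


def _default_probs(c: Criterion, per_criterion_excl: float) -> dict[str, float]:
    excl = [o.option_id for o in c.options if o.is_exclusion]
    non = [o.option_id for o in c.options if not o.is_exclusion]
    probs: dict[str, float] = {}
    e = per_criterion_excl if excl else 0.0
    for oid in excl:
        probs[oid] = e / len(excl)
    for oid in non:
        probs[oid] = (1.0 - e) / len(non)
    return probs


def _sample_measurement(c: Criterion, option_id: str, rng: np.random.Generator):
    """A raw measurement the engine must bucket back onto ``option_id``."""
    rule = next((r for r in c.bucket_rules if r.option_id == option_id), None)
    if rule is None:
        return option_id  # named-only option, e.g. never supplied
    iv: Interval = rule.interval
    if c.measurement_kind == "stagnant_count":
        lo = int(math.ceil(iv.lo)) + (0 if iv.lo_closed else 1)
        hi = int(iv.hi) if not math.isinf(iv.hi) else lo + 4
        if not math.isinf(iv.hi) and not iv.hi_closed:
            hi -= 1
        return int(rng.integers(lo, hi + 1))
    eps = 1e-6
    lo = iv.lo + (0.0 if iv.lo_closed else eps)
    hi = iv.hi if not math.isinf(iv.hi) else iv.lo + 10.0
    hi -= 0.0 if iv.hi_closed or math.isinf(iv.hi) else eps
    value = float(rng.uniform(lo, hi))
    if c.measurement_kind == "technical_fulfillment_pct" and rng.random() < 0.5:
        # half the time report raw spec counts instead of a percentage
        required = int(rng.integers(10, 31))
        met = int(math.floor(value * required / 100.0))
        pct = 100.0 * met / required
        if iv.contains(pct):
            return SpecCount(met, required)
    return value


def naive_total(
    config: CriteriaConfig, chosen: dict[str, str]
) -> tuple[float | None, bool]:
    """Ground-truth aggregation: plain loop of weight times option fraction.

    ``chosen`` maps criterion_id to the drawn option_id. Returns
    ``(total, excluded)`` with total None when excluded.
    """
    total = 0.0
    excluded = False
    for c in config.criteria:
        opt = c.option(chosen[c.criterion_id])
        if opt.is_exclusion:
            excluded = True
        total += c.weight_pct * opt.score_fraction
    return (None, True) if excluded else (total, False)


def gen_profiles(
    spec: ProfileSpec, config: CriteriaConfig
) -> tuple[list[DeviceProfile], list[Assessment]]:
    """Draw device profiles plus ground-truth assessments.

    Deterministic per seed. The returned assessments are computed by
    :func:`naive_total` from the drawn options, not by the scoring engine.
    """
    for cid in spec.option_probs:
        config.criterion(cid)  # KeyError -> spec/config mismatch
    rng = np.random.default_rng(spec.seed)
    n_excl_criteria = sum(
        1 for c in config.criteria if any(o.is_exclusion for o in c.options)
    )
    # per-criterion exclusion mass chosen so the device-level exclusion
    # probability equals spec.exclusion_rate
    per_crit = (
        1.0 - (1.0 - spec.exclusion_rate) ** (1.0 / n_excl_criteria)
        if n_excl_criteria
        else 0.0
    )
    profiles: list[DeviceProfile] = []
    truths: list[Assessment] = []
    for d in range(spec.n_devices):
        device_id = f"device{d + 1:03d}"
        chosen: dict[str, str] = {}
        evidence: dict = {}
        local = False
        for c in config.criteria:
            probs = spec.option_probs.get(
                c.criterion_id, _default_probs(c, per_crit)
            )
            oids = list(probs)
            oid = str(rng.choice(oids, p=[probs[o] for o in oids]))
            chosen[c.criterion_id] = oid
            if c.option(oid).local_only:
                local = True
            if c.measurement_kind == "categorical":
                evidence[c.criterion_id] = oid
            else:
                evidence[c.criterion_id] = _sample_measurement(c, oid, rng)
        price = (
            float(rng.uniform(*spec.price_range)) if spec.with_prices else None
        )
        profiles.append(
            DeviceProfile(
                device_id=device_id,
                supplier_id=f"supplier{d % 7 + 1:02d}",
                evidence=evidence,
                is_local_product=local,
                price=price,
            )
        )
        total, excluded = naive_total(config, chosen)
        reasons = tuple(
            f"{c.criterion_id}: {c.option(chosen[c.criterion_id]).label}"
            for c in config.criteria
            if c.option(chosen[c.criterion_id]).is_exclusion
        )
        scores = tuple(
            CriterionScore(
                criterion_id=c.criterion_id,
                option_id=chosen[c.criterion_id],
                score_fraction=c.option(chosen[c.criterion_id]).score_fraction,
                points=c.option(chosen[c.criterion_id]).score_fraction * c.weight_pct,
                excluded_here=c.option(chosen[c.criterion_id]).is_exclusion,
            )
            for c in config.criteria
        )
        truths.append(
            Assessment(
                device_id=device_id,
                scores=scores,
                total=total,
                excluded=excluded,
                exclusion_reasons=reasons,
            )
        )
    return profiles, truths


def final_workshop_vote_fixture(config: CriteriaConfig) -> VoteSet:
    """The single-voice vote set implied by an instrument's printed weights.

    The rank vote is the instrument's ordering; the swing votes are the
    consecutive weight ratios minus one, i.e. exactly the votes a perfectly
    consistent panel would have cast to produce those weights.
    """
    ordering = config.criterion_ids
    weights = [config.criterion(cid).weight_pct for cid in ordering]
    return VoteSet(
        (RankVote("panel", ordering),),
        swing_votes_from_weights(weights, expert_id="panel"),
    )
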