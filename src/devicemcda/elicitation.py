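"""Expert-panel elicitation: rank aggregation and SMART swing weighting.

The panel protocol this module implements has three steps. Experts first
vote on modifications to the criteria list, adopted on a strict majority.
They then rank the criteria by importance; the consensus ordering is the
ascending mean of the voted rank positions. Finally, for each pair of
adjacently ranked criteria, each expert states on a 0-100% scale how much
more important the higher-ranked criterion is, where 0% means the two are
equally important and 100% means the higher-ranked one is twice as
important. The scale is interpolated linearly between those two anchors,
so a mean vote v maps to an importance ratio 1 + v.

Weights follow by chaining the ratios: the lowest-ranked criterion gets
relative value u_n = 1, each criterion above gets u_i = u_{i+1} * (1 + v_i),
and weights are the u values normalised to sum to 100. Mean (not median)
aggregation is used throughout for both rank positions and swing votes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import fmean

from .model import CriteriaConfig, ValidationReport, validate_config

__all__ = [
    "RankVote",
    "SwingVote",
    "VoteSet",
    "ConsensusRanking",
    "ElicitationError",
    "aggregate_rank_votes",
    "adopt_modification",
    "derive_swing_weights",
    "swing_votes_from_weights",
    "run_elicitation",
]


class ElicitationError(ValueError):
    """Invalid or incomplete panel votes."""


@dataclass(frozen=True)
class RankVote:
    """One expert's full ordering of the criteria, most important first."""

    expert_id: str
    ordering: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ordering)) != len(self.ordering):
            raise ElicitationError(
                f"expert {self.expert_id!r}: ordering repeats a criterion"
            )


@dataclass(frozen=True)
class SwingVote:
    """One expert's swing vote on adjacent pair ``pair_index``.

    ``pair_index`` is 1-based: pair i compares the criterion ranked i with
    the criterion ranked i+1. ``value`` is the 0-1 fraction of the voting
    scale (0 = equal importance, 1 = double importance).
    """

    expert_id: str
    pair_index: int
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ElicitationError(
                f"expert {self.expert_id!r} pair {self.pair_index}: swing vote "
                f"{self.value} outside [0,1]"
            )
        if self.pair_index < 1:
            raise ElicitationError(f"pair_index {self.pair_index} must be >= 1")


@dataclass(frozen=True)
class VoteSet:
    rank_votes: tuple[RankVote, ...]
    swing_votes: tuple[SwingVote, ...]

    @property
    def n_experts(self) -> int:
        ids = {v.expert_id for v in self.rank_votes}
        ids |= {v.expert_id for v in self.swing_votes}
        return len(ids)


@dataclass(frozen=True)
class ConsensusRanking:
    """Panel ordering with mean rank positions and any ties encountered.

    Ties are broken by the order criteria appear in the configuration; each
    tied group is reported so the panel can revisit it.
    """

    ordering: tuple[str, ...]
    mean_ranks: dict[str, float]
    ties: tuple[frozenset[str], ...]


def aggregate_rank_votes(
    votes: list[RankVote] | tuple[RankVote, ...],
    tie_break_order: list[str] | tuple[str, ...] | None = None,
) -> ConsensusRanking:
    """Average the voted rank positions into a consensus ordering.

    All votes must cover the same criterion set. Criteria are sorted by
    ascending mean position; exact ties are broken by ``tie_break_order``
    (defaults to the first vote's ordering) and flagged in the result.
    """
    if not votes:
        raise ElicitationError("no rank votes supplied")
    universe = frozenset(votes[0].ordering)
    for v in votes:
        if frozenset(v.ordering) != universe:
            raise ElicitationError(
                f"expert {v.expert_id!r} voted over a different criterion set"
            )
    base = tuple(tie_break_order) if tie_break_order else votes[0].ordering
    if frozenset(base) != universe:
        raise ElicitationError("tie_break_order does not match the voted criteria")
    base_pos = {cid: i for i, cid in enumerate(base)}

    mean_ranks = {
        cid: fmean(v.ordering.index(cid) + 1 for v in votes) for cid in universe
    }
    ordering = tuple(
        sorted(universe, key=lambda cid: (mean_ranks[cid], base_pos[cid]))
    )
    groups: dict[float, list[str]] = {}
    for cid, r in mean_ranks.items():
        groups.setdefault(r, []).append(cid)
    ties = tuple(
        frozenset(g) for r, g in sorted(groups.items()) if len(g) > 1
    )
    return ConsensusRanking(ordering, mean_ranks, ties)


def adopt_modification(yes_votes: int, total_participants: int) -> bool:
    """Strict-majority adoption rule: passes only if more than half agree."""
    if total_participants < 1:
        raise ElicitationError("total_participants must be >= 1")
    if not 0 <= yes_votes <= total_participants:
        raise ElicitationError(
            f"yes_votes {yes_votes} out of range 0..{total_participants}"
        )
    return yes_votes * 2 > total_participants


def derive_swing_weights(
    ordering: list[str] | tuple[str, ...],
    swing_votes: list[SwingVote] | tuple[SwingVote, ...],
) -> dict[str, float]:
    """Chain mean swing votes into normalised percentage weights.

    Every adjacent pair 1..n-1 needs at least one vote. Returns weights in
    the order of ``ordering``; they sum to 100 to floating precision and are
    monotone non-increasing in rank.
    """
    n = len(ordering)
    if n < 1:
        raise ElicitationError("empty ordering")
    by_pair: dict[int, list[float]] = {}
    for v in swing_votes:
        if v.pair_index > n - 1:
            raise ElicitationError(
                f"pair_index {v.pair_index} exceeds n_criteria-1 = {n - 1}"
            )
        by_pair.setdefault(v.pair_index, []).append(v.value)
    missing = [i for i in range(1, n) if i not in by_pair]
    if missing:
        raise ElicitationError(f"no swing votes for adjacent pair(s) {missing}")

    u = [0.0] * n
    u[n - 1] = 1.0
    for i in range(n - 2, -1, -1):
        u[i] = u[i + 1] * (1.0 + fmean(by_pair[i + 1]))
    total = sum(u)
    return {cid: 100.0 * ui / total for cid, ui in zip(ordering, u)}


def swing_votes_from_weights(
    weights: list[float] | tuple[float, ...], expert_id: str = "panel"
) -> tuple[SwingVote, ...]:
    """The adjacent-pair votes implied by a weight vector.

    For weights sorted descending, pair i's vote is w_i / w_{i+1} - 1 — the
    inverse of the chaining in :func:`derive_swing_weights`. Useful for
    round-trip fixtures; requires every adjacent ratio to be at most 2
    (the top of the voting scale).
    """
    votes = []
    for i, (hi, lo) in enumerate(zip(weights, weights[1:]), start=1):
        ratio = hi / lo
        if not 1.0 <= ratio <= 2.0:
            raise ElicitationError(
                f"adjacent ratio {ratio:.4f} at pair {i} is outside the "
                "voting scale [1,2]"
            )
        votes.append(SwingVote(expert_id, i, ratio - 1.0))
    return tuple(votes)


def run_elicitation(
    skeleton: CriteriaConfig, votes: VoteSet, config_id: str | None = None
) -> CriteriaConfig:
    """Full elicitation: rank votes -> ordering, swing votes -> weights.

    ``skeleton`` supplies the criteria (names, options, bucket rules); its
    ranks and weights are discarded and its criterion order serves as the
    tie-break. The result passes strict validation.
    """
    if not votes.rank_votes or not votes.swing_votes:
        raise ElicitationError("vote set must contain rank and swing votes")
    consensus = aggregate_rank_votes(
        list(votes.rank_votes), tie_break_order=skeleton.criterion_ids
    )
    weights = derive_swing_weights(consensus.ordering, list(votes.swing_votes))
    criteria = tuple(
        replace(
            skeleton.criterion(cid),
            rank=i + 1,
            weight_pct=weights[cid],
        )
        for i, cid in enumerate(consensus.ordering)
    )
    out = CriteriaConfig(
        config_id=config_id or f"{skeleton.config_id}-elicited",
        criteria=criteria,
        reference_countries=skeleton.reference_countries,
        provenance=f"elicited from {votes.n_experts} expert vote set(s)",
        current=True,
    )
    report: ValidationReport = validate_config(out, strict=True)
    if not report.ok:
        raise ElicitationError(
            "elicited config failed validation: "
            + "; ".join(f.message for f in report.errors())
        )
    return out
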