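"""File round-tripping and report rendering.

Formats are deliberately plain: instruments are single-document YAML,
everything tabular is UTF-8 comma-separated CSV with a header row and
decimal points. Device-profile cells hold either an option_id, a number,
or ``met/required`` spec counts (e.g. ``16/20``). Every CLI run drops a
JSON run manifest next to its output for auditability.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .elicitation import ElicitationError, RankVote, SwingVote, VoteSet
from .financial import ValueRanking
from .model import (
    ConfigError,
    CriteriaConfig,
    config_from_dict,
    config_to_dict,
)
from .scoring import ComparisonReport, DeviceProfile, ScoringError, SpecCount

__all__ = [
    "RunManifest",
    "read_config",
    "write_config",
    "read_profiles_csv",
    "write_profiles_csv",
    "read_votes_csv",
    "write_votes_csv",
    "read_prices_csv",
    "comparison_frame",
    "write_comparison_csv",
    "render_sheet",
    "write_manifest",
]


@dataclass(frozen=True)
class RunManifest:
    command: str
    inputs: tuple[str, ...]
    config_id: str
    tool_version: str
    timestamp: str
    seed: int | None = None


def write_manifest(
    out_path: str | Path,
    command: str,
    inputs: list[str] | tuple[str, ...],
    config_id: str,
    seed: int | None = None,
) -> Path:
    manifest = RunManifest(
        command=command,
        inputs=tuple(str(p) for p in inputs),
        config_id=config_id,
        tool_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        seed=seed,
    )
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n", encoding="utf-8")
    return path


# -- instrument configs -----------------------------------------------------

def read_config(path: str | Path) -> CriteriaConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a single YAML mapping")
    return config_from_dict(doc)


def write_config(config: CriteriaConfig, path: str | Path) -> None:
    doc = config_to_dict(config)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True, width=100)


# -- device profiles --------------------------------------------------------

_META_COLS = ("device_id", "supplier_id", "is_local_product", "price")


def _parse_cell(raw: str):
    raw = raw.strip()
    if "/" in raw:
        met_s, req_s = raw.split("/", 1)
        try:
            return SpecCount(int(met_s), int(req_s))
        except ValueError:
            pass
    try:
        f = float(raw)
    except ValueError:
        return raw  # option_id
    return int(f) if f.is_integer() and "." not in raw else f


def read_profiles_csv(path: str | Path) -> list[DeviceProfile]:
    """Read device profiles; one row per device, one column per criterion."""
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "device_id" not in reader.fieldnames:
            raise ScoringError(f"{path}: missing header with device_id column")
        crit_cols = [c for c in reader.fieldnames if c not in _META_COLS]
        profiles = []
        for lineno, row in enumerate(reader, start=2):
            try:
                price_raw = (row.get("price") or "").strip()
                profiles.append(
                    DeviceProfile(
                        device_id=row["device_id"].strip(),
                        supplier_id=(row.get("supplier_id") or "").strip(),
                        is_local_product=(row.get("is_local_product") or "")
                        .strip()
                        .lower()
                        in ("1", "true", "yes"),
                        price=float(price_raw) if price_raw else None,
                        evidence={
                            c: _parse_cell(row[c])
                            for c in crit_cols
                            if (row.get(c) or "").strip() != ""
                        },
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ScoringError(f"{path}:{lineno}: bad profile row ({exc})")
    if not profiles:
        raise ScoringError(f"{path}: no device profiles found")
    return profiles


def _cell(value) -> str:
    if isinstance(value, SpecCount):
        return f"{value.specs_met}/{value.specs_required}"
    return str(value)


def write_profiles_csv(
    profiles: list[DeviceProfile], config: CriteriaConfig, path: str | Path
) -> None:
    cols = list(_META_COLS) + list(config.criterion_ids)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for p in profiles:
            writer.writerow(
                [
                    p.device_id,
                    p.supplier_id,
                    str(p.is_local_product).lower(),
                    "" if p.price is None else p.price,
                ]
                + [_cell(p.evidence[c]) for c in config.criterion_ids]
            )


# -- votes ------------------------------------------------------------------

def read_votes_csv(path: str | Path, criterion_ids: tuple[str, ...]) -> VoteSet:
    """Read panel votes from (expert_id, vote_type, subject, value) rows.

    Rank rows give each criterion's voted position; swing rows give the
    adjacent pair index and the 0-1 vote. Each expert's rank votes must
    form a complete permutation of ``criterion_ids``.
    """
    rank_rows: dict[str, dict[str, int]] = {}
    swing_votes: list[SwingVote] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"expert_id", "vote_type", "subject", "value"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ElicitationError(
                f"{path}: header must contain {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            expert = row["expert_id"].strip()
            kind = row["vote_type"].strip().lower()
            try:
                if kind == "rank":
                    rank_rows.setdefault(expert, {})[row["subject"].strip()] = int(
                        float(row["value"])
                    )
                elif kind == "swing":
                    swing_votes.append(
                        SwingVote(expert, int(row["subject"]), float(row["value"]))
                    )
                else:
                    raise ValueError(f"unknown vote_type {kind!r}")
            except (ValueError, ElicitationError) as exc:
                raise ElicitationError(f"{path}:{lineno}: {exc}") from exc
    rank_votes = []
    for expert, positions in rank_rows.items():
        missing = set(criterion_ids) - set(positions)
        if missing:
            raise ElicitationError(
                f"{path}: expert {expert!r} missing rank votes for {sorted(missing)}"
            )
        extra = set(positions) - set(criterion_ids)
        if extra:
            raise ElicitationError(
                f"{path}: expert {expert!r} voted on unknown criteria {sorted(extra)}"
            )
        ordering = tuple(sorted(positions, key=lambda cid: positions[cid]))
        rank_votes.append(RankVote(expert, ordering))
    return VoteSet(tuple(rank_votes), tuple(swing_votes))


def write_votes_csv(votes: VoteSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["expert_id", "vote_type", "subject", "value"])
        for rv in votes.rank_votes:
            for pos, cid in enumerate(rv.ordering, start=1):
                writer.writerow([rv.expert_id, "rank", cid, pos])
        for sv in votes.swing_votes:
            writer.writerow([sv.expert_id, "swing", sv.pair_index, sv.value])


# -- prices -----------------------------------------------------------------

def read_prices_csv(path: str | Path) -> dict[str, float]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"device_id", "price"} <= set(
            reader.fieldnames
        ):
            raise ScoringError(f"{path}: header must contain device_id, price")
        return {
            row["device_id"].strip(): float(row["price"])
            for row in reader
        }


# -- reports ----------------------------------------------------------------

def comparison_frame(
    report: ComparisonReport, value_ranking: ValueRanking | None = None
) -> pd.DataFrame:
    """Tabulate a comparison: one row per device, ranked devices first."""
    rows = []
    for rank, a in enumerate(report.assessments, start=1):
        row = {"device_id": a.device_id, "rank": rank, "excluded": False}
        for s in a.scores:
            row[f"points_{s.criterion_id}"] = round(s.points, 6)
        row["total"] = round(a.total, 6)
        row["exclusion_reasons"] = ""
        rows.append(row)
    for a in report.excluded:
        row = {"device_id": a.device_id, "rank": None, "excluded": True}
        for s in a.scores:
            row[f"points_{s.criterion_id}"] = round(s.points, 6)
        row["total"] = None
        row["exclusion_reasons"] = "; ".join(a.exclusion_reasons)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if value_ranking is not None:
        ppp = {r.device_id: r for r in value_ranking.ranking}
        vrank = {r.device_id: i + 1 for i, r in enumerate(value_ranking.ranking)}
        frame["price"] = frame["device_id"].map(
            lambda d: ppp[d].price if d in ppp else None
        )
        frame["price_per_point"] = frame["device_id"].map(
            lambda d: round(ppp[d].price_per_point, 6) if d in ppp else None
        )
        frame["value_rank"] = frame["device_id"].map(vrank)
    return frame


def write_comparison_csv(
    report: ComparisonReport,
    path: str | Path,
    value_ranking: ValueRanking | None = None,
) -> None:
    comparison_frame(report, value_ranking).to_csv(path, index=False)


def render_sheet(config: CriteriaConfig) -> str:
    """Printable scoring sheet: per criterion, each option with its
    weight-adjusted points and a blank column for the assessor."""
    lines = [
        f"# Scoring sheet — {config.config_id}",
        "",
        "Total score is the sum of the entered points (maximum 100).",
        "An EXCLUSION outcome removes the device from the tender.",
        "",
    ]
    for c in config.criteria:
        lines.append(f"## {c.rank}. {c.name} — weight {c.weight_pct:g}%")
        if c.rationale:
            lines.append(f"*{c.rationale}*")
        lines.append("")
        lines.append("| Scoring option | Points | Entry |")
        lines.append("| --- | --- | --- |")
        for o in c.options:
            pts = "EXCLUSION" if o.is_exclusion else f"{o.score_fraction * c.weight_pct:.2f}"
            lines.append(f"| {o.label} | {pts} |  |")
        lines.append("")
    if config.reference_countries:
        lines.append(
            "Reference countries: " + ", ".join(config.reference_countries)
        )
        lines.append("")
    return "\n".join(lines)
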