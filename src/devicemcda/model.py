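"""Instrument data model for multicriteria device-tender scoring.

An instrument (:class:`CriteriaConfig`) is an ordered, weighted list of
criteria. Each criterion carries a scoring function: a set of discrete
options, each worth a fraction of the criterion's weight, possibly flagged
as an exclusion rule (a device that lands on an exclusion option is removed
from the tender regardless of its other scores). Quantitative criteria
additionally carry bucket rules that map a raw measurement (a fulfilment
percentage, a stagnant-report count) onto one of the options.

The bundled default instrument is the final eight-criterion Egyptian tool
for implantable-device procurement; the interim nine-criterion draft from
the first expert workshop ships as a non-current fixture.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "MEASUREMENT_KINDS",
    "Interval",
    "ScoringOption",
    "BucketRule",
    "Criterion",
    "CriteriaConfig",
    "Finding",
    "ValidationReport",
    "ConfigError",
    "validate_config",
    "load_default_tool",
    "load_first_workshop_tool",
    "config_from_dict",
    "config_to_dict",
]

#: Measurement kinds a criterion may declare. ``categorical`` criteria take a
#: named option directly; the quantitative kinds bucket a raw number.
MEASUREMENT_KINDS = frozenset(
    {
        "categorical",
        "technical_fulfillment_pct",
        "supplier_fulfillment_pct",
        "stagnant_count",
    }
)


class ConfigError(ValueError):
    """Raised for structurally unusable configuration input."""


_INTERVAL_RE = re.compile(
    r"^\s*([\[\(])\s*([^,\s]+)\s*,\s*([^,\s\]\)]+)\s*([\]\)])\s*$"
)


@dataclass(frozen=True)
class Interval:
    """A numeric interval in standard bracket notation, e.g. ``[70,80)``.

    ``inf`` is accepted as the upper endpoint for unbounded count buckets.
    """

    lo: float
    hi: float
    lo_closed: bool
    hi_closed: bool

    @classmethod
    def parse(cls, text: str) -> "Interval":
        m = _INTERVAL_RE.match(text)
        if not m:
            raise ConfigError(f"unparseable interval {text!r}")
        lo_b, lo_s, hi_s, hi_b = m.groups()
        lo = float(lo_s)
        hi = math.inf if hi_s in ("inf", "+inf") else float(hi_s)
        iv = cls(lo, hi, lo_b == "[", hi_b == "]")
        if iv.hi < iv.lo or (iv.hi == iv.lo and not (iv.lo_closed and iv.hi_closed)):
            raise ConfigError(f"empty interval {text!r}")
        if math.isinf(iv.hi) and iv.hi_closed:
            raise ConfigError(f"interval {text!r} cannot close at infinity")
        return iv

    def contains(self, x: float) -> bool:
        above = x > self.lo or (self.lo_closed and x == self.lo)
        below = x < self.hi or (self.hi_closed and x == self.hi)
        return above and below

    def __str__(self) -> str:
        lo_b = "[" if self.lo_closed else "("
        hi_b = "]" if self.hi_closed else ")"
        hi = "inf" if math.isinf(self.hi) else _fmt_num(self.hi)
        return f"{lo_b}{_fmt_num(self.lo)},{hi}{hi_b}"


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


@dataclass(frozen=True)
class ScoringOption:
    """One row of a criterion's scoring function.

    ``score_fraction`` is the fraction of the criterion's weight awarded
    (Table rows printed as percentages, divided by 100). Exclusion options
    carry no score: landing on one removes the device from the tender.
    ``local_only`` marks options reserved for locally manufactured products
    (the CE-certificate-only route).
    """

    option_id: str
    label: str
    score_fraction: float = 0.0
    is_exclusion: bool = False
    local_only: bool = False

    def __post_init__(self) -> None:
        if self.is_exclusion and self.score_fraction != 0.0:
            object.__setattr__(self, "score_fraction", 0.0)


@dataclass(frozen=True)
class BucketRule:
    """Maps a measurement interval onto a scoring option."""

    interval: Interval
    option_id: str


@dataclass(frozen=True)
class Criterion:
    criterion_id: str
    name: str
    rank: int
    weight_pct: float
    measurement_kind: str
    options: tuple[ScoringOption, ...]
    bucket_rules: tuple[BucketRule, ...] = ()
    rationale: str = ""

    def option(self, option_id: str) -> ScoringOption:
        for opt in self.options:
            if opt.option_id == option_id:
                return opt
        raise KeyError(
            f"criterion {self.criterion_id!r} has no option {option_id!r}"
        )

    @property
    def non_exclusion_options(self) -> tuple[ScoringOption, ...]:
        return tuple(o for o in self.options if not o.is_exclusion)

    @property
    def top_option(self) -> ScoringOption:
        """The highest-scoring non-exclusion option."""
        return max(self.non_exclusion_options, key=lambda o: o.score_fraction)


@dataclass(frozen=True)
class CriteriaConfig:
    """A complete instrument: criteria ordered by rank plus shared metadata."""

    config_id: str
    criteria: tuple[Criterion, ...]
    reference_countries: tuple[str, ...] = ()
    provenance: str = ""
    current: bool = True

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.criteria, key=lambda c: c.rank))
        object.__setattr__(self, "criteria", ordered)

    def criterion(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.criterion_id == criterion_id:
                return c
        raise KeyError(f"no criterion {criterion_id!r} in config {self.config_id!r}")

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(c.criterion_id for c in self.criteria)

    @property
    def weights(self) -> dict[str, float]:
        return {c.criterion_id: c.weight_pct for c in self.criteria}


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" or "warning"
    location: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    findings: tuple[Finding, ...]

    @property
    def ok(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def errors(self) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.severity == "error")


_KIND_DOMAIN = {
    "technical_fulfillment_pct": (0.0, 100.0),
    "supplier_fulfillment_pct": (0.0, 100.0),
    "stagnant_count": (0.0, math.inf),
}


def validate_config(config: CriteriaConfig, strict: bool = True) -> ValidationReport:
    """Check an instrument for structural defects.

    Problems are collected into a report, never raised. In strict mode the
    weights must sum to 100 within 1e-6; lenient mode tolerates +/-0.5 to
    accommodate instruments published with rounded weights.
    """
    findings: list[Finding] = []

    def err(loc: str, msg: str) -> None:
        findings.append(Finding("error", loc, msg))

    total = sum(c.weight_pct for c in config.criteria)
    tol = 1e-6 if strict else 0.5
    if abs(total - 100.0) > tol:
        err("config", f"weight sum {round(total, 6)} != 100")

    ranks = [c.rank for c in config.criteria]
    if sorted(ranks) != list(range(1, len(ranks) + 1)):
        err("config", f"ranks {sorted(ranks)} are not 1..{len(ranks)} without gaps")

    seen_ids: set[str] = set()
    for c in config.criteria:
        loc = f"criterion {c.criterion_id}"
        if c.criterion_id in seen_ids:
            err(loc, "duplicate criterion_id")
        seen_ids.add(c.criterion_id)
        if c.weight_pct <= 0:
            err(loc, f"weight_pct {c.weight_pct} must be > 0")
        if c.measurement_kind not in MEASUREMENT_KINDS:
            err(loc, f"unknown measurement kind {c.measurement_kind!r}")
        if not c.non_exclusion_options:
            err(loc, "criterion has no non-exclusion option")
        opt_ids = [o.option_id for o in c.options]
        if len(opt_ids) != len(set(opt_ids)):
            err(loc, "duplicate option_id")
        for o in c.options:
            if not 0.0 <= o.score_fraction <= 1.0:
                err(loc, f"option {o.option_id!r} score_fraction "
                         f"{o.score_fraction} outside [0,1]")
        findings.extend(_check_buckets(c))

    return ValidationReport(tuple(findings))


def _check_buckets(c: Criterion) -> list[Finding]:
    loc = f"criterion {c.criterion_id}"
    out: list[Finding] = []
    if c.measurement_kind == "categorical":
        if c.bucket_rules:
            out.append(Finding("warning", loc, "bucket rules on a categorical criterion are ignored"))
        return out
    if not c.bucket_rules:
        out.append(Finding("error", loc, "quantitative criterion has no bucket rules"))
        return out
    opt_ids = {o.option_id for o in c.options}
    for rule in c.bucket_rules:
        if rule.option_id not in opt_ids:
            out.append(Finding("error", loc, f"bucket maps to unknown option {rule.option_id!r}"))
    lo_dom, hi_dom = _KIND_DOMAIN[c.measurement_kind]
    rules = sorted(c.bucket_rules, key=lambda r: (r.interval.lo, not r.interval.lo_closed))
    if c.measurement_kind == "stagnant_count":
        # integer domain: [0,1] and [2,2] are adjacent, not gapped
        spans = []
        for r in rules:
            iv = r.interval
            lo_i = int(math.ceil(iv.lo))
            if lo_i == iv.lo and not iv.lo_closed:
                lo_i += 1
            if math.isinf(iv.hi):
                hi_i: float = math.inf
            else:
                hi_i = int(math.floor(iv.hi))
                if hi_i == iv.hi and not iv.hi_closed:
                    hi_i -= 1
            spans.append((lo_i, hi_i, iv))
        if spans[0][0] > 0:
            out.append(Finding("error", loc, f"buckets leave a gap below {spans[0][2]}"))
        for (alo, ahi, aiv), (blo, bhi, biv) in zip(spans, spans[1:]):
            if blo <= ahi:
                out.append(Finding("error", loc, f"buckets {aiv} and {biv} overlap"))
            elif blo > ahi + 1:
                out.append(Finding("error", loc, f"gap between buckets {aiv} and {biv}"))
        if not math.isinf(spans[-1][1]):
            out.append(Finding("error", loc, f"buckets leave a gap above {spans[-1][2]}"))
        return out
    first = rules[0].interval
    if first.lo != lo_dom or not first.lo_closed:
        out.append(Finding("error", loc, f"buckets leave a gap below {first}"))
    for prev, nxt in zip(rules, rules[1:]):
        a, b = prev.interval, nxt.interval
        if b.lo < a.hi or (b.lo == a.hi and b.lo_closed and a.hi_closed):
            out.append(Finding("error", loc, f"buckets {a} and {b} overlap"))
        elif b.lo > a.hi or (b.lo == a.hi and not b.lo_closed and not a.hi_closed):
            out.append(Finding("error", loc, f"gap between buckets {a} and {b}"))
    last = rules[-1].interval
    if last.hi < hi_dom or (last.hi == hi_dom and not last.hi_closed):
        out.append(Finding("error", loc, f"buckets leave a gap above {last}"))
    return out


# ---------------------------------------------------------------------------
# serialisation

def config_from_dict(doc: dict) -> CriteriaConfig:
    """Build a config from a parsed YAML/JSON document."""
    try:
        criteria = tuple(_criterion_from_dict(d) for d in doc["criteria"])
        return CriteriaConfig(
            config_id=str(doc["config_id"]),
            criteria=criteria,
            reference_countries=tuple(doc.get("reference_countries", ())),
            provenance=str(doc.get("provenance", "")).strip(),
            current=bool(doc.get("current", True)),
        )
    except KeyError as exc:
        raise ConfigError(f"config document missing key {exc}") from exc


def _criterion_from_dict(d: dict) -> Criterion:
    options = tuple(
        ScoringOption(
            option_id=str(o["id"]),
            label=str(o["label"]).strip(),
            score_fraction=float(o.get("score", 0.0)),
            is_exclusion=bool(o.get("exclusion", False)),
            local_only=bool(o.get("local_only", False)),
        )
        for o in d["options"]
    )
    buckets = tuple(
        BucketRule(Interval.parse(b["interval"]), str(b["option"]))
        for b in d.get("buckets", ())
    )
    return Criterion(
        criterion_id=str(d["id"]),
        name=str(d["name"]).strip(),
        rank=int(d["rank"]),
        weight_pct=float(d["weight_pct"]),
        measurement_kind=str(d["measurement"]),
        options=options,
        bucket_rules=buckets,
        rationale=str(d.get("rationale", "")).strip(),
    )


def config_to_dict(config: CriteriaConfig) -> dict:
    """Inverse of :func:`config_from_dict`; round-trips exactly."""
    return {
        "config_id": config.config_id,
        "provenance": config.provenance,
        "current": config.current,
        "reference_countries": list(config.reference_countries),
        "criteria": [
            {
                "id": c.criterion_id,
                "name": c.name,
                "rationale": c.rationale,
                "rank": c.rank,
                "weight_pct": c.weight_pct,
                "measurement": c.measurement_kind,
                "options": [
                    {
                        "id": o.option_id,
                        "label": o.label,
                        **({"exclusion": True} if o.is_exclusion else {"score": o.score_fraction}),
                        **({"local_only": True} if o.local_only else {}),
                    }
                    for o in c.options
                ],
                **(
                    {
                        "buckets": [
                            {"interval": str(b.interval), "option": b.option_id}
                            for b in c.bucket_rules
                        ]
                    }
                    if c.bucket_rules
                    else {}
                ),
            }
            for c in config.criteria
        ],
    }


def _load_bundled(name: str) -> CriteriaConfig:
    text = resources.files("devicemcda.data").joinpath(name).read_text(encoding="utf-8")
    return config_from_dict(yaml.safe_load(text))


def load_default_tool() -> CriteriaConfig:
    """The bundled final eight-criterion Egyptian instrument.

    Weights are the adopted panel values (29.4, 19.5, 14.9, 11.7, 9.0, 6.9,
    4.6, 4.0); they sum to exactly 100 and are treated as canonical, so no
    renormalisation is applied.
    """
    return _load_bundled("egypt_final_2022.yaml")


def load_first_workshop_tool() -> CriteriaConfig:
    """The interim nine-criterion draft instrument (non-current fixture).

    Its printed weights total 99.8 because of rounding; validate with
    ``strict=False``.
    """
    return _load_bundled("egypt_interim_2021.yaml")
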