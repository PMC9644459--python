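# devicemcda

A multicriteria decision analysis (MCDA) engine for scoring implantable
medical devices in public procurement tenders, built around the
eight-criterion instrument adopted for the Egyptian public sector.

When several equivalent implantable devices (pacemakers, stents, insulin
pumps, …) compete in a tender, the purchasing authority needs an objective,
auditable way to compare them. The instrument implemented here evaluates
each device on eight weighted criteria — technical characteristics (29.4%),
country of origin (19.5%), use in reference countries (14.9%), supply
reliability (11.7%), previous use in tenders (9.0%), instant replacement
within product variety (6.9%), pharmacovigilance (4.6%), and refund or
replacement (4.0%) — and aggregates a weighted sum

    total = Σᵢ wᵢ · sᵢ        (wᵢ = criterion weight in %, sᵢ ∈ [0, 1])

to a score out of 100. Two outcomes are *exclusion rules*: a device meeting
fewer than 70% of its required technical specifications, or whose supplier
has no pharmacovigilance system, is removed from the tender regardless of
its other scores. Price is deliberately absent from the technical score: in
a separate financial phase each surviving device's price is divided by its
total, and the lowest **price per point** marks the best value for money.

The package is intended for procurement analysts and health-technology
assessment researchers. Beyond the bundled instrument it provides:

- **Criteria model** — validated, serialisable instrument configurations
  (YAML), including the interim nine-criterion draft from the first expert
  workshop as a historical fixture.
- **Elicitation** — rank-vote averaging, strict-majority adoption, and
  SMART swing weighting: experts rate each adjacent pair of ranked criteria
  on a 0–100% scale (0% = equally important, 100% = twice as important);
  ratios `1 + v` are chained and normalised into weights.
- **Scoring engine** — bucketing of raw measurements (specs met/required,
  supplier fulfilment %, stagnant-report counts), exclusion handling, and
  multi-device comparison reports.
- **Financial & sensitivity** — price-per-point value ranking, proportional
  reweighting, and rank-reversal scans over a weight grid.
- **Synthetic fixtures** — seedable expert panels and device profiles with
  independently computed ground truth.

## Worked example

```python
from devicemcda import load_default_tool, DeviceProfile, SpecCount, score_device

tool = load_default_tool()
device = DeviceProfile(
    "pacemaker-A",
    evidence={
        "technical": SpecCount(16, 20),          # 80% -> 60% of 29.4
        "country_of_origin": "ref_both",
        "reference_use": "ce_plus_freesale",
        "supply_reliability": 85.0,              # 70-90% bucket
        "previous_use": "upa_listed",
        "instant_replacement": "provided",
        "pharmacovigilance": "moderate",
        "refund_replacement": 2,                 # stagnant twice last year
    },
)
a = score_device(device, tool)
for s in a.scores:
    print(f"{s.criterion_id:<20} {s.option_id:<16} {s.points:.2f}")
print("total", a.total)
```

prints

```
technical            f80              17.64
country_of_origin    ref_both         19.50
reference_use        ce_plus_freesale 11.18
supply_reliability   f70_90           9.36
previous_use         upa_listed       9.00
instant_replacement  provided         6.90
pharmacovigilance    moderate         3.22
refund_replacement   stagnant2        2.80
total 79.595
```

A device meeting 16 of 20 required specifications fulfils 80% of them and
earns 60% of the technical weight (17.64 of 29.4 points); the remaining
rows follow the instrument's scoring table, and the weighted sum gives a
final score of 79.6 out of 100. Had the technical fulfilment been below
70%, `a.excluded` would be true and no total reported.

The same flows are available from the shell:

```
devicemcda sheet --out sheet.md                 # printable scoring sheet
devicemcda compare profiles.csv --prices prices.csv --out ranked.csv
devicemcda elicit votes.csv --out elicited.yaml # panel votes -> weights
```

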