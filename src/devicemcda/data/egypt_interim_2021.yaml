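# Interim nine-criterion tool voted at the first (2021) workshop. Superseded by
# egypt-final-2022; shipped as a fixture only. The published record gives only
# the interim ranks and weights; scoring options are carried over from the
# final instrument where criteria overlap, and the later-removed "training"
# criterion is given a minimal two-option scoring function.
config_id: egypt-interim-2021
provenance: >-
  Interim nine-criterion draft instrument voted at the January/February 2021
  workshop; printed weights total 99.8 due to rounding. Non-current fixture.
current: false
reference_countries:
  - Australia
  - Austria
  - Belgium
  - Canada
  - Denmark
  - Germany
  - Finland
  - Iceland
  - France
  - Ireland
  - Luxemburg
  - The Netherlands
  - New Zealand
  - Norway
  - Sweden
  - Switzerland
  - USA
  - UK
  - Japan
  - Italy
  - Spain
  - Portugal
criteria:
  - id: technical
    name: Technical characteristics of the medical device
    rationale: To assure fulfilling the technical specifications
    rank: 1
    weight_pct: 33.0
    measurement: technical_fulfillment_pct
    options:
      - id: full
        label: Fulfills 100% of the technical specifications required
        score: 1.0
      - id: f90
        label: Fulfills 90-<100% of the technical specifications required
        score: 0.8
      - id: f80
        label: Fulfills 80-<90% of the technical specifications required
        score: 0.6
      - id: f70
        label: Fulfills 70-<80% of the technical specifications required
        score: 0.1
      - id: below70
        label: Fulfills <70% of the technical specifications required
        exclusion: true
    buckets:
      - interval: "[100,100]"
        option: full
      - interval: "[90,100)"
        option: f90
      - interval: "[80,90)"
        option: f80
      - interval: "[70,80)"
        option: f70
      - interval: "[0,70)"
        option: below70
  - id: reference_use
    name: Use in reference countries
    rationale: To assure previous use in countries with good standards of quality
    rank: 2
    weight_pct: 17.8
    measurement: categorical
    options:
      - id: cfg_fda
        label: CFG certificate from FDA
        score: 1.0
      - id: canadian_bundle
        label: >-
          Canadian free sale certificate + ((medical device active license +
          MDSAP certificate) or medical device establishment license)
        score: 0.8
      - id: ce_plus_freesale
        label: European CE certificate + free sale certificate from a reference country
        score: 0.75
      - id: ce_only
        label: European CE certificate only (for local products only)
        score: 0.5
        local_only: true
  - id: supply_reliability
    name: Supply reliability
    rationale: To assure the reliability of the supplier concerning quantities and delay
    rank: 3
    weight_pct: 11.3
    measurement: supplier_fulfillment_pct
    options:
      - id: above90
        label: Supplier fulfilled more than 90% of the committed requirements in the last 3 years
        score: 1.0
      - id: f70_90
        label: Supplier fulfilled 70-90% of the committed requirements in the last 3 years
        score: 0.8
      - id: f50_70
        label: Supplier fulfilled 50-70% of the committed requirements in the last 3 years
        score: 0.6
      - id: never_supplied
        label: Did not supply previously
        score: 0.5
      - id: below50
        label: Supplier fulfilled <50% of the committed requirements in the last 3 years
        score: 0.1
    buckets:
      - interval: "(90,100]"
        option: above90
      - interval: "[70,90]"
        option: f70_90
      - interval: "[50,70)"
        option: f50_70
      - interval: "[0,50)"
        option: below50
  - id: country_of_origin
    name: Country of origin
    rationale: To ensure manufacturing quality via the origin country's standards
    rank: 4
    weight_pct: 9.0
    measurement: categorical
    options:
      - id: ref_both
        label: Reference countries for both legal and actual manufacturer or local product
        score: 1.0
      - id: ref_one
        label: Reference country of the legal manufacturer or actual manufacturer
        score: 0.75
      - id: nonref
        label: Non reference countries for both
        score: 0.4
  - id: previous_use
    name: Previous use in tenders
    rationale: To reward products already tried and trusted in procurement
    rank: 5
    weight_pct: 7.4
    measurement: categorical
    options:
      - id: upa_listed
        label: Listed in the UPA platform
        score: 1.0
      - id: supplied_recent
        label: Supplied to governmental or non-governmental organizations in the previous 2 years
        score: 0.7
      - id: not_supplied
        label: Was not supplied previously
        score: 0.45
  - id: pharmacovigilance
    name: Pharmacovigilance system
    rationale: >-
      EDA will provide evidence for the efficiency of the pharmacovigilance
      system from 1 year as a maximum
    rank: 6
    weight_pct: 7.3
    measurement: categorical
    options:
      - id: efficient
        label: Supplier has an efficient pharmacovigilance system
        score: 1.0
      - id: moderate
        label: Supplier has a moderate quality pharmacovigilance system
        score: 0.7
      - id: low
        label: Supplier has a low-quality pharmacovigilance system
        score: 0.2
      - id: none
        label: No pharmacovigilance system
        exclusion: true
  - id: instant_replacement
    name: Instant replacement within product variety
    rationale: To assure supplier flexibility
    rank: 7
    weight_pct: 5.1
    measurement: categorical
    options:
      - id: provided
        label: Supplier provides instant replacement within product variety (during surgery or on shelf stock)
        score: 1.0
      - id: not_provided
        label: Supplier does not provide product replacement for different sizes/types
        score: 0.15
  - id: training
    name: Training
    rationale: To assure the supplier trains clinical staff on device use
    rank: 8
    weight_pct: 4.7
    measurement: categorical
    options:
      - id: provided
        label: Supplier provides sufficient training for the device
        score: 1.0
      - id: not_provided
        label: Supplier does not provide training
        score: 0.0
  - id: refund_replacement
    name: Provision of refund or replacement
    rationale: To assure replacing unwanted or expired products
    rank: 9
    weight_pct: 4.2
    measurement: stagnant_count
    options:
      - id: stagnant1
        label: The product was present in the stagnant report 1 time or less in the last year
        score: 1.0
      - id: stagnant2
        label: The product was present in the stagnant report 2 times subsequently in the last year
        score: 0.7
      - id: stagnant3
        label: The product was present in the stagnant report 3 times subsequently in the last year
        score: 0.5
      - id: stagnant4
        label: The product was present in the stagnant report 4 times in the last year
        score: 0.2
    buckets:
      - interval: "[0,1]"
        option: stagnant1
      - interval: "[2,2]"
        option: stagnant2
      - interval: "[3,3]"
        option: stagnant3
      - interval: "[4,inf)"
        option: stagnant4
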