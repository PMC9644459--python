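config_id: egypt-final-2022
provenance: >-
  Final eight-criterion instrument for implantable-device tenders in the
  Egyptian public sector, adopted by expert vote at the March 2022 workshop.
current: true
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
    weight_pct: 29.4
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
  - id: country_of_origin
    name: Country of origin
    rationale: To ensure manufacturing quality via the origin country's standards
    rank: 2
    weight_pct: 19.5
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
  - id: reference_use
    name: Use in reference countries
    rationale: To assure previous use in countries with good standards of quality
    rank: 3
    weight_pct: 14.9
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
    rank: 4
    weight_pct: 11.7
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
  - id: previous_use
    name: Previous use in tenders
    rationale: To reward products already tried and trusted in procurement
    rank: 5
    weight_pct: 9.0
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
  - id: instant_replacement
    name: Instant replacement within product variety
    rationale: To assure supplier flexibility
    rank: 6
    weight_pct: 6.9
    measurement: categorical
    options:
      - id: provided
        label: Supplier provides instant replacement within product variety (during surgery or on shelf stock)
        score: 1.0
      - id: not_provided
        label: Supplier does not provide product replacement for different sizes/types
        score: 0.15
  - id: pharmacovigilance
    name: Pharmacovigilance system
    rationale: >-
      EDA will provide evidence for the efficiency of the pharmacovigilance
      system from 1 year as a maximum
    rank: 7
    weight_pct: 4.6
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
  - id: refund_replacement
    name: Provision of refund or replacement
    rationale: To assure replacing unwanted or expired products
    rank: 8
    weight_pct: 4.0
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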