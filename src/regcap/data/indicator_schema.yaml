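# Two-level indicator system for provincial drug-regulatory capacity,
# with the published frozen weight system: dimension-level weights and
# within-dimension indicator weights.
dimensions:
  - id: resource_acquisition
    name: Resource acquisition capability
    weight: 0.153
  - id: functional_performance
    name: Functional performance capacity
    weight: 0.218
  - id: performance_level
    name: Performance development level
    weight: 0.289
  - id: learning_development
    name: Learning and development ability
    weight: 0.210
  - id: internet_application
    name: Internet application
    weight: 0.130
indicators:
  - id: I_1
    name: Per capita GDP
    unit: Ten thousand yuan
    dimension: resource_acquisition
    nature: positive
    weight: 0.281
  - id: I_2
    name: Per capita fiscal revenue
    unit: Ten thousand yuan
    dimension: resource_acquisition
    nature: positive
    weight: 0.379
  - id: I_3
    name: Regional informatization level
    unit: ""
    dimension: resource_acquisition
    nature: positive
    weight: 0.340
  - id: I_4
    name: Number of administrative acceptances
    unit: piece
    dimension: functional_performance
    nature: positive
    weight: 0.562
  - id: I_5
    name: Approved re-registration applications of domestic drugs
    unit: piece
    dimension: functional_performance
    nature: positive
    weight: 0.401
  - id: I_6
    name: Relative change in registered licensed pharmacists
    unit: ""
    dimension: functional_performance
    nature: positive
    weight: 0.038
  - id: I_7
    name: Qualified rate of drug sampling
    unit: "%"
    dimension: performance_level
    nature: positive
    weight: 0.152
  - id: I_8
    name: Production department qualified rate
    unit: "%"
    dimension: performance_level
    nature: positive
    weight: 0.588
  - id: I_9
    name: Operating department qualified rate
    unit: "%"
    dimension: performance_level
    nature: positive
    weight: 0.261
  - id: I_10
    name: Scientific research input
    unit: Ten thousand yuan
    dimension: learning_development
    nature: positive
    weight: 0.721
  - id: I_11
    name: Training expense
    unit: Ten thousand yuan
    dimension: learning_development
    nature: positive
    weight: 0.279
  - id: I_12
    name: Total site visits
    unit: number of times
    dimension: internet_application
    nature: positive
    weight: 0.330
  - id: I_13
    name: Released information items
    unit: number of times
    dimension: internet_application
    nature: positive
    weight: 0.580
  - id: I_14
    name: Share of government services handled fully online
    unit: "%"
    dimension: internet_application
    nature: positive
    weight: 0.091
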