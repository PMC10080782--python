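# 24-feature clinical schema for the under-2 head-trauma cohort.
# Level sets follow the study's baseline-characteristics table; the first
# level of each categorical feature is the reference level for encoding.
# na_linked_to marks structured "Not applicable" levels: the child feature
# is "Not applicable" exactly when the parent is "No"/"Not applicable".
features:
  - name: age_months
    kind: continuous
  - name: injury_mechanism
    kind: categorical
    levels:
      - Fall from an elevation
      - Motor vehicle collision
      - Pedestrian struck by moving vehicle
      - Bike rider struck by automobile
      - Bike collision or fall from bike
      - Other wheeled transport crash
      - Fall from standing/walking/running
      - Walked or ran into stationary object
      - Fall down stairs
      - Sports
      - Assault
      - Object struck head - accidental
      - Other
  - name: injury_severity
    kind: categorical
    levels: [Low, Moderate, High]
  - name: loss_of_consciousness
    kind: binary
    levels: ["No", "Yes"]
  - name: post_traumatic_seizure
    kind: binary
    levels: ["No", "Yes"]
  - name: seizure_duration
    kind: categorical
    levels: [Not applicable, "<1 min", "1-<5 min", "5-15 min", ">15 min"]
    na_linked_to: post_traumatic_seizure
  - name: acting_normally
    kind: binary
    levels: ["Yes", "No"]
  - name: vomiting
    kind: binary
    levels: ["No", "Yes"]
  - name: vomiting_episodes
    kind: categorical
    levels: [Not applicable, "1", "2", ">2"]
    na_linked_to: vomiting
  - name: altered_mental_status
    kind: binary
    levels: ["No", "Yes"]
  - name: fontanelle_bulging
    kind: binary
    levels: ["No", "Yes"]
  - name: scalp_hematoma
    kind: binary
    levels: ["No", "Yes"]
  - name: hematoma_location
    kind: categorical
    levels: [Not applicable, Frontal, Occipital, Parietal/Temporal]
    na_linked_to: scalp_hematoma
  - name: hematoma_size
    kind: categorical
    levels: [Not applicable, Small, Medium, Large]
    na_linked_to: hematoma_location
  - name: trauma_above_clavicles
    kind: binary
    levels: ["No", "Yes"]
  - name: trauma_face
    kind: categorical
    levels: [Not applicable, "No", "Yes"]
    na_linked_to: trauma_above_clavicles
  - name: trauma_neck
    kind: categorical
    levels: [Not applicable, "No", "Yes"]
    na_linked_to: trauma_above_clavicles
  - name: trauma_scalp_frontal
    kind: categorical
    levels: [Not applicable, "No", "Yes"]
    na_linked_to: trauma_above_clavicles
  - name: trauma_scalp_occipital
    kind: categorical
    levels: [Not applicable, "No", "Yes"]
    na_linked_to: trauma_above_clavicles
  - name: trauma_scalp_parietal
    kind: categorical
    levels: [Not applicable, "No", "Yes"]
    na_linked_to: trauma_above_clavicles
  - name: trauma_scalp_temporal
    kind: categorical
    levels: [Not applicable, "No", "Yes"]
    na_linked_to: trauma_above_clavicles
  - name: gender
    kind: binary
    levels: [Boy, Girl]
  - name: ethnicity
    kind: binary
    levels: [Non-Hispanic, Hispanic]
  - name: race
    kind: categorical
    levels: [White, Black, Asian, Other]
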