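# Default 45-variable cohort schema: 33 blood/urine analytes followed by 12
# qualitative clinical variables.
#
# Healthy intervals are standard adult reference intervals; `extreme` bounds
# are plausible physiological limits that delimit the unhealthy flanks used by
# the deflection-range weights and the worst-case normalization. Both are
# method parameters and can be overridden by supplying a different schema file.
#
# Qualitative categories are listed in code order (code = 1-based position in
# the list); the first category of `associated_pathology` (code 1, "none") is
# the benign one.
variables:
  - {name: albumin,               kind: numeric, unit: g/dL,      healthy: [3.5, 5.0],    extreme: [1.0, 7.0]}
  - {name: bilirubin_direct,      kind: numeric, unit: mg/dL,     healthy: [0.1, 0.3],    extreme: [0.01, 15.0]}
  - {name: bilirubin_total,       kind: numeric, unit: mg/dL,     healthy: [0.3, 1.2],    extreme: [0.05, 30.0]}
  - {name: creatinine,            kind: numeric, unit: mg/dL,     healthy: [0.6, 1.2],    extreme: [0.1, 15.0]}
  - {name: alkaline_phosphatase,  kind: numeric, unit: U/L,       healthy: [44.0, 147.0], extreme: [5.0, 1500.0]}
  - {name: gamma_gt,              kind: numeric, unit: U/L,       healthy: [9.0, 48.0],   extreme: [1.0, 2000.0]}
  - {name: glycemia,              kind: numeric, unit: mg/dL,     healthy: [70.0, 110.0], extreme: [20.0, 800.0]}
  - {name: got_ast,               kind: numeric, unit: U/L,       healthy: [8.0, 40.0],   extreme: [2.0, 3000.0]}
  - {name: gpt_alt,               kind: numeric, unit: U/L,       healthy: [7.0, 56.0],   extreme: [2.0, 3000.0]}
  - {name: potassium,             kind: numeric, unit: mmol/L,    healthy: [3.5, 5.0],    extreme: [1.5, 9.0]}
  - {name: total_protein,         kind: numeric, unit: g/dL,      healthy: [6.0, 8.3],    extreme: [3.0, 12.0]}
  - {name: sodium,                kind: numeric, unit: mmol/L,    healthy: [135.0, 145.0], extreme: [110.0, 175.0]}
  - {name: quick_time,            kind: numeric, unit: s,         healthy: [11.0, 13.5],  extreme: [8.0, 60.0]}
  - {name: prothrombin_index,     kind: numeric, unit: '%',       healthy: [80.0, 120.0], extreme: [10.0, 160.0]}
  - {name: inr,                   kind: numeric, unit: ratio,     healthy: [0.8, 1.2],    extreme: [0.4, 10.0]}
  - {name: urea,                  kind: numeric, unit: mg/dL,     healthy: [15.0, 45.0],  extreme: [3.0, 400.0]}
  - {name: iron,                  kind: numeric, unit: ug/dL,     healthy: [60.0, 170.0], extreme: [5.0, 500.0]}
  - {name: leukocytes,            kind: numeric, unit: 10^3/uL,   healthy: [4.0, 11.0],   extreme: [0.5, 100.0]}
  - {name: basophils,             kind: numeric, unit: 10^3/uL,   healthy: [0.0, 0.1],    extreme: [0.0, 2.0]}
  - {name: neutrophils_count,     kind: numeric, unit: 10^3/uL,   healthy: [1.5, 8.0],    extreme: [0.1, 50.0]}
  - {name: neutrophils_pct,       kind: numeric, unit: '%',       healthy: [40.0, 70.0],  extreme: [5.0, 100.0]}
  - {name: eosinophils_pct,       kind: numeric, unit: '%',       healthy: [0.0, 6.0],    extreme: [0.0, 50.0]}
  - {name: lymphocytes_pct,       kind: numeric, unit: '%',       healthy: [20.0, 40.0],  extreme: [1.0, 95.0]}
  - {name: monocytes_pct,         kind: numeric, unit: '%',       healthy: [2.0, 10.0],   extreme: [0.2, 40.0]}
  - {name: mcv,                   kind: numeric, unit: fL,        healthy: [80.0, 100.0], extreme: [50.0, 140.0]}
  - {name: hemoglobin,            kind: numeric, unit: g/dL,      healthy: [12.0, 17.5],  extreme: [3.0, 22.0]}
  - {name: erythrocytes,          kind: numeric, unit: 10^6/uL,   healthy: [4.2, 5.9],    extreme: [1.5, 8.5]}
  - {name: mch,                   kind: numeric, unit: pg,        healthy: [27.0, 33.0],  extreme: [15.0, 45.0]}
  - {name: mchc,                  kind: numeric, unit: g/dL,      healthy: [32.0, 36.0],  extreme: [22.0, 40.0]}
  - {name: rdw_cv,                kind: numeric, unit: '%',       healthy: [11.5, 14.5],  extreme: [8.0, 35.0]}
  - {name: rdw_sd,                kind: numeric, unit: fL,        healthy: [39.0, 46.0],  extreme: [25.0, 90.0]}
  - {name: hematocrit,            kind: numeric, unit: '%',       healthy: [36.0, 50.0],  extreme: [10.0, 65.0]}
  - {name: platelets,             kind: numeric, unit: 10^3/uL,   healthy: [150.0, 450.0], extreme: [10.0, 1500.0]}
  - name: environment
    kind: qualitative
    categories: [rural, urban]
    benign: [rural]
  - name: tumor_position
    kind: qualitative
    categories: [none, rectum, sigmoid, descending_colon, transverse_colon, ascending_colon, cecum]
    benign: [none]
  - name: t_stage
    kind: qualitative
    categories: [T0, T1, T2, T3, T4]
    benign: [T0]
  - name: n_stage
    kind: qualitative
    categories: [N0, N1, N2]
    benign: [N0]
  - name: m_stage
    kind: qualitative
    categories: [M0, M1]
    benign: [M0]
  - name: dukes
    kind: qualitative
    categories: [none, A, B, C, D]
    benign: [none]
  - name: associated_pathology
    kind: qualitative
    categories: [none, cardiovascular, metabolic, hepatic, renal, pulmonary, digestive, inflammatory, endocrine, other]
    benign: [none]
  - name: technical_approach
    kind: qualitative
    categories: [none, open_surgery, laparoscopic]
    benign: [none]
  - name: complications
    kind: qualitative
    categories: [none, minor, major]
    benign: [none]
  - name: incidents
    kind: qualitative
    categories: [none, present]
    benign: [none]
  - name: ultrasound_dimensions
    kind: qualitative
    categories: [none, small, medium, large]
    benign: [none]
  - name: ultrasound_localization
    kind: qualitative
    categories: [none, primary_site, liver, lymph_nodes, peritoneum]
    benign: [none]
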