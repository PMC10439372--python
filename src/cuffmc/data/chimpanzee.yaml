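# Chimpanzee glenohumeral model parameters.
#
# Same schema and conventions as human.yaml. Chimpanzee whole-muscle
# infraspinatus and subscapularis PCSA were partitioned into elements using
# the human element shares (infraspinatus upper/lower = 0.4537/0.5463 of
# 24.42 cm^2; subscapularis upper/middle/lower = 0.2429/0.3193/0.4378 of
# 46.07 cm^2); the listed values are the resulting published figures.
# Standard deviations are identical to the human model for every
# probabilistic input. The stability baseline is the shared human reference
# profile; the 13.13 % offset encodes the deeper chimpanzee glenoid.
species_id: chimpanzee
body_mass_kg: 45.0
stature_m: 1.32
segment_lengths_m:
  arm: 0.300
  forearm: 0.290
  hand: 0.210
  scapula: 0.135
segment_mass_fractions:   # chimpanzee forelimbs are relatively heavier
  arm: 0.040
  forearm: 0.023
  hand: 0.009
segment_com_fractions:
  arm: 0.450
  forearm: 0.430
  hand: 0.500
humeral_head_radius_m: 0.022
glenoid_inclination_mean_cm: 104.78
glenoid_inclination_sd_cm: 0.3
# Scapular repositioning applied when human suspension kinematics are
# transferred to the chimpanzee (radiograph-informed; magnitude assumed).
scapular_reposition_m: [0.0, -0.003, -0.003]
stability:
  offset_pct: 13.13
  sd_pct: 4.0
  offset_mode: multiplicative
  baseline_ratios:
    superior: 0.32
    anterosuperior: 0.35
    anterior: 0.45
    anteroinferior: 0.70
    inferior: 0.85
    posteroinferior: 0.78
    posterior: 0.62
    posterosuperior: 0.38
muscle_elements:
  - name: deltoid_middle
    absolute_pcsa_cm2: 28.95
    attachment_bone: humerus
    attachment_mean: [0.0315, 0.0415, 0.346]
    fixed_end: scapula:origin_deltoid_middle
  - name: deltoid_posterior
    absolute_pcsa_cm2: 11.06
    coupling_parent: deltoid_middle
    coupling_offsets: [0.0, 0.0, 0.03]
    fixed_end: scapula:origin_deltoid_posterior
  - name: deltoid_anterior
    absolute_pcsa_cm2: 12.10
    coupling_parent: deltoid_middle
    coupling_offsets: [0.0, 0.0, -0.03]
    fixed_end: scapula:origin_deltoid_anterior
  - name: infraspinatus_upper
    absolute_pcsa_cm2: 11.08
    attachment_bone: scapula
    attachment_mean: [-0.200, 0.300, 0.587]
    fixed_end: humerus:insertion_infraspinatus_upper
  - name: infraspinatus_lower
    absolute_pcsa_cm2: 13.34
    coupling_parent: infraspinatus_upper
    coupling_offsets: [0.0, -0.08, 0.07]
    fixed_end: humerus:insertion_infraspinatus_lower
  - name: subscapularis_upper
    absolute_pcsa_cm2: 11.19
    attachment_bone: scapula
    attachment_mean: [-0.0615, 0.162, 0.643]
    fixed_end: humerus:insertion_subscapularis_upper
  - name: subscapularis_middle
    absolute_pcsa_cm2: 14.71
    coupling_parent: subscapularis_upper
    coupling_offsets: [0.0, -0.06, 0.08]
    fixed_end: humerus:insertion_subscapularis_middle
  - name: subscapularis_lower
    absolute_pcsa_cm2: 20.17
    coupling_parent: subscapularis_upper
    coupling_offsets: [0.0, -0.12, 0.16]
    fixed_end: humerus:insertion_subscapularis_lower
  - name: supraspinatus
    absolute_pcsa_cm2: 19.92
    attachment_bone: scapula
    attachment_mean: [-0.051, 0.125, 0.460]
    fixed_end: humerus:insertion_supraspinatus
  - name: teres_minor
    absolute_pcsa_cm2: 5.48
    attachment_bone: scapula
    attachment_mean: [-0.090, 0.110, 0.720]   # fixed (not probabilistically varied)
    fixed_end: humerus:insertion_teres_minor
attachment_distributions:
  - element_group: infraspinatus_origin
    mean: [-0.200, 0.300, 0.587]
    sd: [0.010, 0.035, 0.035]
  - element_group: subscapularis_origin
    mean: [-0.0615, 0.162, 0.643]
    sd: [0.010, 0.035, 0.035]
  - element_group: supraspinatus_origin
    mean: [-0.051, 0.125, 0.460]
    sd: [0.010, 0.035, 0.035]
  - element_group: deltoid_insertion
    mean: [0.0315, 0.0415, 0.346]
    sd: [0.035, 0.010, 0.035]
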