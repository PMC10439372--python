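# Human glenohumeral model parameters.
#
# Attachment coordinates are fractions of longitudinal bone length in axis
# order (anterior_posterior, medial_lateral, superior_inferior). Human PCSA
# values are the published, already age-doubled figures for a healthy adult.
# Coupled elements carry fractional per-axis offsets from their parent
# element (child = parent * (1 + offset)), so each muscle moves as a unit
# when its parent attachment is perturbed.
species_id: human
body_mass_kg: 72.0
stature_m: 1.8
segment_lengths_m:
  arm: 0.335        # glenohumeral joint centre to elbow
  forearm: 0.263
  hand: 0.194
  scapula: 0.155    # longitudinal (superior-inferior) scapular length
segment_mass_fractions:   # of body mass (standard adult anthropometry)
  arm: 0.028
  forearm: 0.016
  hand: 0.006
segment_com_fractions:    # centre of mass, fraction of length from proximal
  arm: 0.436
  forearm: 0.430
  hand: 0.506
humeral_head_radius_m: 0.025
glenoid_inclination_mean_cm: 115.12   # global mediolateral coordinate of the superior glenoid landmark
glenoid_inclination_sd_cm: 0.3
scapular_reposition_m: [0.0, 0.0, 0.0]
stability:
  offset_pct: 0.0
  sd_pct: 4.0
  offset_mode: multiplicative
  # Assumed anisotropic baseline (weakest superiorly/anterosuperiorly,
  # strongest inferiorly); the deterministic ancestor model's printed values
  # are unavailable, so this profile is a documented assumption.
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
    absolute_pcsa_cm2: 7.42
    attachment_bone: humerus
    attachment_mean: [-0.004, 0.064, 0.369]   # deltoid tuberosity insertion
    fixed_end: scapula:origin_deltoid_middle
  - name: deltoid_posterior
    absolute_pcsa_cm2: 4.29
    coupling_parent: deltoid_middle
    coupling_offsets: [0.0, 0.0, 0.03]
    fixed_end: scapula:origin_deltoid_posterior
  - name: deltoid_anterior
    absolute_pcsa_cm2: 8.84
    coupling_parent: deltoid_middle
    coupling_offsets: [0.0, 0.0, -0.03]
    fixed_end: scapula:origin_deltoid_anterior
  - name: infraspinatus_upper
    absolute_pcsa_cm2: 6.37
    attachment_bone: scapula
    attachment_mean: [-0.106, 0.240, 0.607]
    fixed_end: humerus:insertion_infraspinatus_upper
  - name: infraspinatus_lower
    absolute_pcsa_cm2: 7.67
    coupling_parent: infraspinatus_upper
    coupling_offsets: [0.0, -0.08, 0.07]
    fixed_end: humerus:insertion_infraspinatus_lower
  - name: subscapularis_upper
    absolute_pcsa_cm2: 2.83
    attachment_bone: scapula
    attachment_mean: [-0.030, 0.307, 0.523]
    fixed_end: humerus:insertion_subscapularis_upper
  - name: subscapularis_middle
    absolute_pcsa_cm2: 3.72
    coupling_parent: subscapularis_upper
    coupling_offsets: [0.0, -0.06, 0.08]
    fixed_end: humerus:insertion_subscapularis_middle
  - name: subscapularis_lower
    absolute_pcsa_cm2: 5.10
    coupling_parent: subscapularis_upper
    coupling_offsets: [0.0, -0.12, 0.16]
    fixed_end: humerus:insertion_subscapularis_lower
  - name: supraspinatus
    absolute_pcsa_cm2: 3.15
    attachment_bone: scapula
    attachment_mean: [-0.050, 0.315, 0.360]
    fixed_end: humerus:insertion_supraspinatus
  - name: teres_minor
    absolute_pcsa_cm2: 2.81
    attachment_bone: scapula
    attachment_mean: [-0.080, 0.120, 0.700]   # fixed (not probabilistically varied)
    fixed_end: humerus:insertion_teres_minor
attachment_distributions:
  - element_group: infraspinatus_origin
    mean: [-0.106, 0.240, 0.607]
    sd: [0.010, 0.035, 0.035]
  - element_group: subscapularis_origin
    mean: [-0.030, 0.307, 0.523]
    sd: [0.010, 0.035, 0.035]
  - element_group: supraspinatus_origin
    mean: [-0.050, 0.315, 0.360]
    sd: [0.010, 0.035, 0.035]
  - element_group: deltoid_insertion
    mean: [-0.004, 0.064, 0.369]
    sd: [0.035, 0.010, 0.035]
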