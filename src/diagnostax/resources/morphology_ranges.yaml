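# Per-species morphology parameter table used by the specimen simulator.
# Continuous/integer characters are printed min-max ranges (no distribution
# was reported; uniform sampling is an assumption recorded in generated
# metadata).  Categorical characters are fixed to the species' reported
# states.  Depths are the reported bathymetric ranges in metres.
T. shetlandica:
  body_length_mm: [5.0, 16.0]
  complete: true
  lamellae: [22, 26]
  abdominal_chaetigers: [25, 34]
  ventral_filament_um: [175.0, 225.0]
  depth_m: [25, 375]
  branchiae_type: 3
  fifth_lobe: false
  thoracic_type: 4
  abdominal_type: "2"
  mg_pattern: 1
  mg_j_segments: []
  white_venter: []
  ciliated_papilla: false
  glandular_tc3: absent
  ciliary_tufts: false
  notochaetae_tc1: similar
  geniculate: [6]
T. lavesquei:
  body_length_mm: [5.0, 35.0]
  complete: true
  lamellae: [17, 42]
  abdominal_chaetigers: [30, 31]
  ventral_filament_um: [125.0, 250.0]
  depth_m: [115, 534]
  branchiae_type: 2
  fifth_lobe: true
  thoracic_type: 3
  abdominal_type: "2"
  mg_pattern: 9
  mg_j_segments: [3, 4, 5]
  white_venter: []
  ciliated_papilla: false
  glandular_tc3: J_shaped
  ciliary_tufts: false
  notochaetae_tc1: similar
  geniculate: [6]
T. atlantis:
  body_length_mm: [10.0, 16.0]
  complete: true
  lamellae: [10, 11]
  abdominal_chaetigers: [23, 28]
  ventral_filament_um: [175.0, 175.0]
  depth_m: [219, 2750]
  branchiae_type: 3
  fifth_lobe: false
  thoracic_type: 3
  abdominal_type: "2"
  mg_pattern: 9
  mg_j_segments: [3, 4, 5]
  white_venter: []
  ciliated_papilla: false
  glandular_tc3: absent
  ciliary_tufts: false
  notochaetae_tc1: similar
  geniculate: [6]
T. irinae:
  body_length_mm: [10.0, 17.0]
  complete: false
  lamellae: [7, 7]
  abdominal_chaetigers: [18, 20]
  ventral_filament_um: [75.0, 75.0]
  depth_m: [4038, 4380]
  branchiae_type: 4
  fifth_lobe: true
  thoracic_type: 3
  abdominal_type: "2"
  mg_pattern: 1
  mg_j_segments: []
  white_venter: []
  ciliated_papilla: false
  glandular_tc3: absent
  ciliary_tufts: false
  notochaetae_tc1: similar
  geniculate: [6]
T. williamsae:
  body_length_mm: [9.0, 34.0]
  complete: true
  lamellae: [16, 18]
  abdominal_chaetigers: [38, 44]
  ventral_filament_um: [50.0, 50.0]
  depth_m: [178, 612]
  branchiae_type: 2
  fifth_lobe: true
  thoracic_type: 1
  abdominal_type: "1A"
  mg_pattern: 2
  mg_j_segments: []
  white_venter: [1, 2, 3, 4]
  ciliated_papilla: true
  glandular_tc3: absent
  ciliary_tufts: true
  notochaetae_tc1: similar
  geniculate: [6]
T. gracilis:
  body_length_mm: [5.0, 29.0]
  complete: true
  lamellae: [23, 32]
  abdominal_chaetigers: [34, 41]
  ventral_filament_um: [125.0, 175.0]
  depth_m: [237, 1268]
  branchiae_type: 2
  fifth_lobe: true
  thoracic_type: 1
  abdominal_type: "1A"
  mg_pattern: 2
  mg_j_segments: []
  white_venter: [4]
  ciliated_papilla: true
  glandular_tc3: absent
  ciliary_tufts: true
  notochaetae_tc1: similar
  geniculate: [6]
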