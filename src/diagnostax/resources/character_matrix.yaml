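# Taxon x character matrix for the six focal NE Atlantic species.
# States follow the discriminating-character table of the source dataset;
# the white ventral colouration character is included because the uncini /
# branchiae / staining characters alone leave T. williamsae and T. gracilis
# separated only by distribution trends.
characters:
  - name: branchiae_type
    domain: [1, 2, 3, 4]
  - name: thoracic_type
    domain: [1, 3, 4]
  - name: abdominal_type
    domain: ["1A", "2"]
  - name: mg_pattern
    domain: [1, 2, 9, other]
  - name: ciliated_papilla
    domain: [true, false]
  - name: white_venter
    domain: [none, TC4, TC1-4, other]
  - name: papillae_on_lamellae
    domain: [true, false]
taxa:
  T. shetlandica:
    branchiae_type: 3
    thoracic_type: 4
    abdominal_type: "2"
    mg_pattern: 1
    ciliated_papilla: false
    white_venter: none
    papillae_on_lamellae: false
  T. lavesquei:
    branchiae_type: 2
    thoracic_type: 3
    abdominal_type: "2"
    mg_pattern: 9
    ciliated_papilla: false
    white_venter: none
    papillae_on_lamellae: false
  T. atlantis:
    branchiae_type: 3
    thoracic_type: 3
    abdominal_type: "2"
    mg_pattern: 9
    ciliated_papilla: false
    white_venter: none
    papillae_on_lamellae: false
  T. irinae:
    branchiae_type: 4
    thoracic_type: 3
    abdominal_type: "2"
    mg_pattern: 1
    ciliated_papilla: false
    white_venter: none
    papillae_on_lamellae: false
  T. williamsae:
    branchiae_type: 2
    thoracic_type: 1
    abdominal_type: "1A"
    mg_pattern: 2
    ciliated_papilla: true
    white_venter: TC1-4
    papillae_on_lamellae: false
  T. gracilis:
    branchiae_type: 2
    thoracic_type: 1
    abdominal_type: "1A"
    mg_pattern: 2
    ciliated_papilla: true
    white_venter: TC4
    papillae_on_lamellae: false
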