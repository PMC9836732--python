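# Dichotomous key to the NE Atlantic species of the genus, encoded
# couplet-for-couplet.  Each couplet has exactly two leads; a lead carries
# a predicate list over derived specimen characters and either a goto
# (next couplet) or a terminal taxon list.  Couplet 18 discriminates by
# bathymetry only (no morphological difference is known); couplets 12 and
# 18 end in multi-taxon terminals.
couplets:
  1:
    - predicates:
        - {char: white_venter, op: in, value: [TC4, TC1-4, other]}
      goto: 2
    - predicates:
        - {char: white_venter, op: eq, value: none}
      goto: 4
  2:
    - predicates:
        - {char: size_class, op: in, value: [medium, large]}
        - {char: fifth_lobe, op: eq, value: true}
        - {char: notochaetae_tc1, op: eq, value: similar}
        - {char: thoracic_type, op: eq, value: 1}
      goto: 3
    - predicates:
        - {char: size_class, op: eq, value: small}
        - {char: fifth_lobe, op: eq, value: false}
        - {char: notochaetae_tc1, op: in, value: [shorter, absent]}
        - {char: thoracic_type, op: eq, value: 3}
      taxa: [T. ceneresi]
  3:
    - predicates:
        - {char: white_venter, op: eq, value: TC1-4}
      taxa: [T. williamsae]
    - predicates:
        - {char: white_venter, op: eq, value: TC4}
      taxa: [T. gracilis]
  4:
    - predicates:
        - {char: branchiae_type, op: eq, value: 4}
      taxa: [T. irinae]
    - predicates:
        - {char: branchiae_type, op: ne, value: 4}
      goto: 5
  5:
    - predicates:
        - {char: branchiae_type, op: in, value: [2, 3]}
        - {char: size_class, op: in, value: [small, medium]}
      goto: 6
    - predicates:
        - {char: branchiae_type, op: eq, value: 1}
        - {char: size_class, op: eq, value: large}
      goto: 9
  6:
    - predicates:
        - {char: thoracic_type, op: eq, value: 4}
      taxa: [T. shetlandica]
    - predicates:
        - {char: thoracic_type, op: eq, value: 3}
      goto: 7
  7:
    - predicates:
        - {char: branchiae_type, op: eq, value: 2}
        - {char: size_class, op: eq, value: medium}
      taxa: [T. lavesquei]
    - predicates:
        - {char: branchiae_type, op: eq, value: 3}
        - {char: size_class, op: eq, value: small}
      goto: 8
  8:
    - predicates:
        - {char: glandular_tc3, op: in, value: [round, oval, J_shaped]}
        - {char: notochaetae_tc1, op: eq, value: longer}
      taxa: [T. parapari]
    - predicates:
        - {char: glandular_tc3, op: eq, value: absent}
        - {char: notochaetae_tc1, op: eq, value: similar}
      taxa: [T. atlantis]
  9:
    - predicates:
        - {char: geniculate, op: eq, value: TC5-6}
      taxa: [T. bigeniculatus]
    - predicates:
        - {char: geniculate, op: eq, value: TC6}
      goto: 10
  10:
    - predicates:
        - {char: papillae_on_lamellae, op: eq, value: false}
      goto: 11
    - predicates:
        - {char: papillae_on_lamellae, op: eq, value: true}
      goto: 13
  11:
    - predicates:
        - {char: branchiae_type, op: eq, value: 2}
      taxa: [T. gralli]
    - predicates:
        - {char: branchiae_type, op: eq, value: 1}
      goto: 12
  12:
    - predicates:
        - {char: abdominal_cr, op: le, value: 0.8}
      taxa: [T. stroemii]
    - predicates:
        - {char: abdominal_cr, op: gt, value: 0.8}
      taxa: [T. kongsrudi, T. bakkeni]
  13:
    - predicates:
        - {char: glandular_tc3, op: in, value: [round, oval]}
      goto: 14
    - predicates:
        - {char: glandular_tc3, op: in, value: [J_shaped, absent]}
      goto: 15
  14:
    - predicates:
        - {char: glandular_tc3_mg_stain, op: eq, value: white}
      taxa: [T. lilasae]
    - predicates:
        - {char: glandular_tc3_mg_stain, op: eq, value: blue}
      taxa: [T. bonifi]
  15:
    - predicates:
        - {char: ciliary_tufts, op: eq, value: true}
      taxa: [T. gentili]
    - predicates:
        - {char: ciliary_tufts, op: eq, value: false}
      goto: 16
  16:
    - predicates:
        - {char: upper_lip_elongated, op: eq, value: true}
      taxa: [T. resomari]
    - predicates:
        - {char: upper_lip_elongated, op: eq, value: false}
      goto: 17
  17:
    - predicates:
        - {char: thoracic_type, op: eq, value: 1}
      taxa: [T. ronningae]
    - predicates:
        - {char: thoracic_type, op: eq, value: 3}
      goto: 18
  18:
    - predicates:
        - {char: depth_m, op: ge, value: 200}
      taxa: [T. norvegica]
    - predicates:
        - {char: depth_m, op: lt, value: 200}
      taxa: [T. europaea, T. scotica]
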