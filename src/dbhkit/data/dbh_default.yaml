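sequence: MERGAARKSLPGPSMREAAFMYSTAVAIFLVILVAALQGSAPAESPFPFHIPLDPEGSLELSWNVSYTQEAIHFQLLVRRLKAGVLFGMSDRGELENADLVVLWTDGDTAYFADAWSDQKGQIHLDPQQDYQLLQVQRTPEGLTLLFKRPFGTCDPNDYLIEDGTVHLVYGILEEPFRSLEAINGSGLQMGLQRVQLLKPNIPEPELPSDACTMEVQAPNIQIPSQETTYWCYIKELPKGFSRHHIIKYEPIVTKGNEALVHHMEVFQCAPEMDSVPHFSGPCDSKMKPDRLNYCRHVLAAWALGAKAFYYPEEAGLAFGGPGSSRYLRLEVHYHNPLVIEGRNDSSGIRLYYTAKLRRFNAGIMELGLVYTPVMAIPPRETAFILTGYCTDKCTQLALPPSGIHIFASQLHTHLTGRKVVTVLVRDGREWEIVNQDNHYSPHFQEIRMLKKVVSVHPGDVLITSCTYNTEDRELATVGGFGILEQMCVNYVHYYPQTQLELCKSAVDAGFLQKYFHLINRFNNEDVCTCPQASVSQQFTSVPWNSFNRDVLKALYSFAPISMHCNKSSAVRFQGEWNLQPLPKVISTLEEPTPQCPTSQGRSPAGPTVVSIGGGKG
disulfides:
- pos_i: 154
  pos_j: 596
  scope: intrachain
  soft: false
- pos_i: 232
  pos_j: 283
  scope: intrachain
  soft: false
- pos_i: 269
  pos_j: 295
  scope: intrachain
  soft: false
- pos_i: 390
  pos_j: 503
  scope: intrachain
  soft: true
- pos_i: 394
  pos_j: 565
  scope: intrachain
  soft: false
- pos_i: 466
  pos_j: 488
  scope: intrachain
  soft: false
- pos_i: 528
  pos_j: 528
  scope: interchain
  soft: false
- pos_i: 530
  pos_j: 530
  scope: interchain
  soft: false
metal_sites:
- label: CuA
  element: CU
  ligands:
  - pos: 262
    atom: ND1
    distance: 1.99
  - pos: 263
    atom: ND1
    distance: 1.99
  - pos: 333
    atom: ND1
    distance: 1.99
  water_ligands:
    count: 1
    distance: 1.94
  notes: ''
- label: CuB
  element: CU
  ligands:
  - pos: 412
    atom: NE2
    distance: 1.99
  - pos: 414
    atom: NE2
    distance: 1.99
  water_ligands:
    count: 1
    distance: 1.94
  notes: third ligand X unidentified (His or O-donor or solvent); Met487 SD is the
    reduced-state ligand and is not placed
ss_prediction: ''
strand_pairs:
- range_a:
  - 50
  - 53
  range_b:
  - 193
  - 197
  target_ca_ca: 5.0
domain_ranges:
  DOMON:
  - 57
  - 173
  Cu_monooxygenase_N:
  - 196
  - 344
  Cu_monooxygenase_C:
  - 359
  - 526
params:
  salt_bridge_cutoff: 7.0
  electrostatic_cutoff: 4.0
  snp_radius: 6.0
  metal_ligand_cutoff: 3.0
  extended_shell: 6.5
  ss_bond_target: 2.05
  ss_bond_tolerance: 0.3
  hbond_max_donor_acceptor: 3.5
  hbond_min_angle: 120.0
  min_cu_cu: 7.0
  probe_radius: 1.4
  hydrophobic_cc_cutoff: 4.0
  clash_threshold: 2.4
  surface_rel_exposure: 0.25
  active_site_metal_dist: 8.0
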