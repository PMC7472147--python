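# Hallmark-motif panel registry, in the degenerate notation documented in
# viroseek.annotate (x: any residue, u: uncharged residue, -: any or none,
# A/B: alternation at one position, uppercase X: any residue).
panels:
  parvovirus_NS1:
    walker_a: GxxxxGKT/S
    walker_b: uuuuD/ED/E
    rcr_1: xuHuHuuux
    rcr_2: uxxYux-Kxx
  parvovirus_VP1:
    pla2_hd: HD
    pla2_d: D
    ca_binding: YLGPG
  polyomavirus_LT:
    dnaj: HPDKGG
    rb_binding: LXCXE
    walker_a_lt: G/AxxxxGKT/S
    zn_cxxc: CXXC
    zn_clvc: CLVC
    zn_cfsc: CFSC
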