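# Bundled cleavage-specificity table (rule-set version is stamped by the
# package as peptikit-rules-1.0). These are editorial reconstructions of
# standard Keil / PeptideCutter-style conventions, stated over Schechter-
# Berger positions; every entry can be overridden by a user config of the
# same shape. The stem-bromelain rule is the lowest-confidence entry: no
# authoritative protein-substrate specificity is published for it, so a
# broad basic/small-residue convention is used.
enzymes:
  pepsin_ph_gt2:
    ec: 3.4.23.1
    p1_allow: FLWYE
    p1prime_block: P
  bromelain_stem:
    ec: 3.4.22.32
    p1_allow: KRAYG
    p1prime_block: P
  papain:
    ec: 3.4.22.2
    p1_allow: KR
    p2_allow: F
    p1prime_block: P
  trypsin:
    ec: 3.4.21.4
    p1_allow: KR
    p1prime_block: P
  chymotrypsin_a:
    ec: 3.4.21.1
    p1_allow: FYW
    p1prime_block: P
  lys_c:
    ec: 3.4.21.50
    p1_allow: K
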