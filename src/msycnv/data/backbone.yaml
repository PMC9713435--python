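# Condensed horse MSY haplotype backbone used as the default genotyping tree.
#
# Only five markers carry their field names (rAX gates the Crown haplogroup;
# rA, rW and fYR split the Crown into the T, A and H haplogroups; rAY defines
# DW4).  The remaining markers are systematically named placeholders
# ("p-<edge>") standing in for the full 30-marker panel; supply a complete
# marker map via your own config for real genotype data.  Nodes "DW4-u" and
# "Tb1-u" are placeholder leaves representing not-yet-resolved haplotypes
# below DW4 and Tb-1, so samples stopping at those haplogroups are reported
# as internal (unresolved) placements.
name: condensed-horse-msy-backbone
root: Root
gate_marker: rAX
nodes:
  Crown: Root
  DW1: Root
  DW4: Root
  P: Root
  DW2: DW1
  DW3: DW1
  I: DW2
  N: DW2
  O: DW3
  M: DW3
  Y: DW3
  DW4-u: DW4
  Pa: P
  Pb: P
  T: Crown
  A: Crown
  H: Crown
  Ta: T
  Tu: T
  Tb: T
  Tb-1: Tb
  Tb-d: Tb
  Tb-o: Tb
  Tb1-u: Tb-1
  Ad: A
  Am: A
  Ao: A
  Hs: H
markers:
  - {name: rAX, edge: Crown, kind: SNV, ancestral: T, derived: C}
  - {name: rA, edge: T, kind: SNV, ancestral: A, derived: G}
  - {name: rW, edge: A, kind: SNV, ancestral: C, derived: T}
  - {name: fYR, edge: H, kind: SNV, ancestral: G, derived: A}
  - {name: rAY, edge: DW4, kind: SNV, ancestral: A, derived: C}
  - {name: p-DW1, edge: DW1, kind: SNV, ancestral: G, derived: A}
  - {name: p-DW2, edge: DW2, kind: SNV, ancestral: T, derived: C}
  - {name: p-DW3, edge: DW3, kind: SNV, ancestral: C, derived: A}
  - {name: p-I, edge: I, kind: SNV, ancestral: A, derived: G}
  - {name: p-N, edge: N, kind: SNV, ancestral: G, derived: T}
  - {name: p-O, edge: O, kind: SNV, ancestral: C, derived: T}
  - {name: p-M, edge: M, kind: SNV, ancestral: A, derived: C}
  - {name: p-Y, edge: Y, kind: SNV, ancestral: T, derived: G}
  - {name: p-DW4u, edge: DW4-u, kind: SNV, ancestral: G, derived: C}
  - {name: p-P, edge: P, kind: SNV, ancestral: A, derived: T}
  - {name: p-P2, edge: P, kind: indel, ancestral: del, derived: ins}
  - {name: p-Pa, edge: Pa, kind: SNV, ancestral: C, derived: G}
  - {name: p-Pb, edge: Pb, kind: SNV, ancestral: T, derived: A}
  - {name: p-Ta, edge: Ta, kind: SNV, ancestral: G, derived: A}
  - {name: p-Tu, edge: Tu, kind: SNV, ancestral: C, derived: T}
  - {name: p-Tb, edge: Tb, kind: SNV, ancestral: A, derived: G}
  - {name: p-Tb1, edge: Tb-1, kind: SNV, ancestral: T, derived: C}
  - {name: p-Tbd, edge: Tb-d, kind: SNV, ancestral: G, derived: T}
  - {name: p-Tbd2, edge: Tb-d, kind: SNV, ancestral: C, derived: A}
  - {name: p-Tbo, edge: Tb-o, kind: SNV, ancestral: A, derived: T}
  - {name: p-Tb1u, edge: Tb1-u, kind: SNV, ancestral: C, derived: G}
  - {name: p-Ad, edge: Ad, kind: SNV, ancestral: T, derived: G}
  - {name: p-Am, edge: Am, kind: SNV, ancestral: G, derived: C}
  - {name: p-Ao, edge: Ao, kind: SNV, ancestral: A, derived: G}
  - {name: p-Hs, edge: Hs, kind: SNV, ancestral: C, derived: T}
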