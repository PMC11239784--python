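# Synthetic GH13 subfamily benchmark: four labelled classes whose 52-position
# CSR blocks carry per-position consensus residues at the conservation
# probabilities reported for the real subfamilies, on a uniform random
# background.  Multi-position features carry per-position probabilities equal
# to the k-th root of the printed joint fraction, so the joint conservation of
# the feature matches the reported value:
#   L-[DN] (19-20)   joint 262/304 = 0.8618  -> per-position 0.92835
#   preCSRV Asp      290/304 = 0.95395
#   [WY]-[GA] (28-29) joint 40/41 = 0.97561  -> per-position 0.98773
#   Asp33, Glu40     39/41 = 0.95122
#   Cys24 (shared)   0.81
#   GQ (51-52)       joint 0.855             -> per-position 0.92466
# Family-typical features (NH 14-15, GXR 21-23, NHD 41-42) at 0.95; remaining
# CSR positions default to 0.85; catalytic triad D25/E34/D43 at 1.0.
# Within an allowed set the first residue is the consensus (weight 4), the
# rest share weight 1 each.

length: 210
placement:
  # per-region 0-based ungapped start index; logo positions are contiguous
  # within each region, and regions appear in N->C order VI,I,V,II,III,IV,VII
  CSR-VI: 30
  CSR-I: 55
  CSR-V: 80
  CSR-II: 100
  CSR-III: 125
  CSR-IV: 150
  CSR-VII: 175
default_conservation: 0.85
catalytic_conservation: 1.0
indel_rate: 0.0
n_per_class:
  GH13_48: 300
  GH13_49: 40
  GH13_38: 3
  intermediary: 2

classes:
  GH13_48:
    consensus: "GFRVDAAKHDVVINHEWFLDGTRCDAVEVFMAGEVWLWLGNHDFVDNHDNGQ"
    positions:
      14: {set: "N", c: 0.95}
      15: {set: "H", c: 0.95}
      19: {set: "L", c: 0.92835}
      20: {set: "DN", c: 0.92835}
      21: {set: "G", c: 0.95}
      23: {set: "R", c: 0.95}
      24: {set: "C", c: 0.81}
      41: {set: "N", c: 0.95}
      42: {set: "H", c: 0.95}
      51: {set: "G", c: 0.92466}
      52: {set: "Q", c: 0.92466}
    auxiliary:
      preCSRV: {set: "D", c: 0.95395}
  GH13_49:
    consensus: "GYHLDLAENDAVLNHTPMVGGSRCDLTWGYQIDEAFMGVENHDLSTDPRIGQ"
    positions:
      14: {set: "N", c: 0.95}
      15: {set: "H", c: 0.95}
      21: {set: "G", c: 0.95}
      23: {set: "R", c: 0.95}
      24: {set: "C", c: 0.81}
      28: {set: "WY", c: 0.98773}
      29: {set: "GA", c: 0.98773}
      33: {set: "D", c: 0.95122}
      40: {set: "E", c: 0.95122}
      41: {set: "N", c: 0.95}
      42: {set: "H", c: 0.95}
      51: {set: "G", c: 0.92466}
      52: {set: "Q", c: 0.92466}
  GH13_38:
    consensus: "GWNMDIVPHDYIGNHKAQPSGVRADFNKTWNLVEGYIAFENHDMKHEATVGQ"
    positions:
      14: {set: "N", c: 0.95}
      15: {set: "H", c: 0.95}
      21: {set: "G", c: 0.95}
      23: {set: "R", c: 0.95}
      40: {set: "ED", c: 0.95}
      41: {set: "N", c: 0.95}
      42: {set: "H", c: 0.95}
      51: {set: "G", c: 0.92466}
      52: {set: "Q", c: 0.92466}
  intermediary:
    consensus: "GLKADQWTHDMVTNHRGEIAGNRVDYHASLHTAEKDVVYANHDQEWGVKSGQ"
    positions:
      14: {set: "N", c: 0.95}
      15: {set: "H", c: 0.95}
      21: {set: "G", c: 0.95}
      23: {set: "R", c: 0.95}
      41: {set: "N", c: 0.95}
      42: {set: "H", c: 0.95}

fingerprints:
  GH13_48:
    - name: csr5_LDN
      description: "L-[DN] at the end of CSR-V"
      positions: {19: "L", 20: "DN"}
    - name: pre_csr5_asp
      description: "binding-site Asp immediately before CSR-V"
      positions: {preCSRV: "D"}
  GH13_49:
    - name: csr2_WYGA
      description: "[WY]-[GA] at the end of CSR-II"
      positions: {28: "WY", 29: "GA"}
    - name: csr3_asp33
      description: "Asp directly preceding the general acid/base in CSR-III"
      positions: {33: "D"}
    - name: csr4_glu40
      description: "well-preserved Glu in CSR-IV"
      positions: {40: "E"}
  shared:
    - name: csr2_cys24
      description: "Cys directly preceding the catalytic nucleophile"
      positions: {24: "C"}
    - name: csr7_GQ
      description: "GQ at the end of CSR-VII"
      positions: {51: "G", 52: "Q"}
    - name: csr1_NH
      description: "NH at the end of CSR-I"
      positions: {14: "N", 15: "H"}
    - name: csr2_GxR
      description: "GXR at the beginning of CSR-II"
      positions: {21: "G", 23: "R"}
    - name: csr4_NHD
      description: "NHD at the end of CSR-IV"
      positions: {41: "N", 42: "H", 43: "D"}
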