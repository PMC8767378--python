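# Measurement catalog, version 1.
#
# kind: distance | angle | ratio
#   distance: operands are two landmark codes; value = pixel distance x scale
#   angle:    operands are three landmark codes, vertex in the middle; degrees
#   ratio:    operands are two *measurement* codes (distances), dimensionless
# view: the single view the operands are read from
# units: mm | cm | degrees | dimensionless
# optional: depends on a supplementary landmark; absent entries are not errors
version: 1
measurements:
  # --- surface distances (nose region, reported in cm) ---
  - {code: n-prn,  kind: distance, operands: [n, prn],      view: lateral, units: cm}
  - {code: n-sn,   kind: distance, operands: [n, sn],       view: lateral, units: cm}
  - {code: n-r,    kind: distance, operands: [n, r],        view: lateral, units: cm}
  - {code: sn-prn, kind: distance, operands: [sn, prn],     view: lateral, units: cm}
  - {code: n-gn,   kind: distance, operands: [n, gn],       view: lateral, units: cm}
  - {code: al-al,  kind: distance, operands: [al_R, al_L],  view: frontal, units: cm}
  - {code: ac-ac,  kind: distance, operands: [ac_R, ac_L],  view: frontal, units: cm}
  - {code: en-en,  kind: distance, operands: [en_R, en_L],  view: frontal, units: cm}
  - {code: mf-mf,  kind: distance, operands: [mf_R, mf_L],  view: frontal, units: cm}
  - {code: mal-mal, kind: distance, operands: [mal_R, mal_L], view: frontal, units: cm}
  - {code: g-sn,   kind: distance, operands: [g, sn],       view: frontal, units: cm}

  # --- skin-surface angles (lateral profile) ---
  - {code: g-n-prn,  kind: angle, operands: [g, n, prn],   view: lateral, units: degrees}
  - {code: pg-n-prn, kind: angle, operands: [pg, n, prn],  view: lateral, units: degrees}
  - {code: g-sn-pg,  kind: angle, operands: [g, sn, pg],   view: lateral, units: degrees}
  - {code: n-prn-sn, kind: angle, operands: [n, prn, sn],  view: lateral, units: degrees}
  - {code: n-prn-cm, kind: angle, operands: [n, prn, cm],  view: lateral, units: degrees, optional: true}
  - {code: cm-sn-ls, kind: angle, operands: [cm, sn, ls],  view: lateral, units: degrees, optional: true}
  - {code: li-sn-pg, kind: angle, operands: [li, sn, pg],  view: lateral, units: degrees, optional: true}
  # middle / lower facial height angles
  - {code: g-n-sn,   kind: angle, operands: [g, n, sn],    view: lateral, units: degrees}
  - {code: n-sn-gn,  kind: angle, operands: [n, sn, gn],   view: lateral, units: degrees}
  # dorsal-hump angle; kyphion is present only in some subjects
  - {code: n-k-r,    kind: angle, operands: [n, k, r],     view: lateral, units: degrees, optional: true}

  # --- frontal ratios ---
  - {code: height-width-ratio, kind: ratio, operands: [g-sn, mf-mf], view: frontal, units: dimensionless}
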