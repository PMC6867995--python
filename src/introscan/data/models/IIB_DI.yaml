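# Canonical IIB DI-domain model.
#
# Same element grammar as the IIA model, but with the IIB-distinctive
# stem set and geometry: subdomain c carries two hairpins (c1 with EBS2
# plus the extra c2 stem-loop), subdomain d is compound with EBS1 in a
# nested d1 hairpin, the principal stems (i, a, b, c, d) require at
# least 5 bp, sub-stems at least 4 bp, and loops/joiners are tighter.
# The richer, better-determined stem set makes this model markedly more
# specific than the relaxed IIA model.
name: IIB_DI
intron_class: IIB
elements:
  - {type: strand, id: ss5, min: 5, max: 5, role: SPLICE5,
     pattern: [GUGCG, UUGCG, GGGCG]}
  - {type: strand, id: j0, min: 0, max: 4}
  - {type: helix5, id: i, min: 5, max: 12}
  - {type: strand, id: j1, min: 0, max: 4}
  - {type: helix5, id: a, min: 5, max: 12}
  - {type: strand, id: La, min: 3, max: 10, role: EPSILON}
  - {type: helix3, id: a}
  - {type: strand, id: j2, min: 0, max: 4}
  - {type: helix5, id: b, min: 5, max: 12}
  - {type: strand, id: Lb, min: 3, max: 10, role: KAPPA}
  - {type: helix3, id: b}
  - {type: strand, id: j3, min: 0, max: 4}
  - {type: helix5, id: c, min: 5, max: 12}
  - {type: strand, id: jc1, min: 0, max: 3}
  - {type: helix5, id: c1, min: 4, max: 10}
  - {type: strand, id: Lc1, min: 4, max: 10, role: EBS2}
  - {type: helix3, id: c1}
  - {type: strand, id: jc2, min: 0, max: 3}
  - {type: helix5, id: c2, min: 4, max: 10}
  - {type: strand, id: Lc2, min: 3, max: 10}
  - {type: helix3, id: c2}
  - {type: strand, id: jc3, min: 0, max: 3}
  - {type: helix3, id: c}
  - {type: strand, id: j4, min: 0, max: 4}
  - {type: helix5, id: d, min: 5, max: 12}
  - {type: strand, id: jd1, min: 0, max: 3}
  - {type: helix5, id: d1, min: 4, max: 10}
  - {type: strand, id: Ld1, min: 5, max: 8, role: EBS1}
  - {type: helix3, id: d1}
  - {type: strand, id: jd2, min: 0, max: 3}
  - {type: helix3, id: d}
  - {type: strand, id: j5, min: 0, max: 4}
  - {type: helix3, id: i}
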