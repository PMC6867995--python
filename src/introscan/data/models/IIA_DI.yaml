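# Canonical IIA DI-domain model.
#
# Topology: the DI closing stem (i) encloses four stem-loop subdomains
# a-d. Functional loops carry role tags: epsilon in subdomain a, kappa in
# subdomain b, EBS2 in the c1 hairpin of subdomain c, EBS1 in the
# terminal loop of subdomain d. The model starts at the 5' splice-site
# consensus (GUGCG / UUGCG / GGGCG). Stems allow 3-12 bp, terminal loops
# 3-20 nt (role loops sized to their function), joiners 0-6 nt; only
# Watson-Crick and G.U pairs are allowed.
name: IIA_DI
intron_class: IIA
elements:
  - {type: strand, id: ss5, min: 5, max: 5, role: SPLICE5,
     pattern: [GUGCG, UUGCG, GGGCG]}
  - {type: strand, id: j0, min: 0, max: 6}
  - {type: helix5, id: i, min: 3, max: 12}
  - {type: strand, id: j1, min: 0, max: 6}
  - {type: helix5, id: a, min: 3, max: 12}
  - {type: strand, id: La, min: 3, max: 12, role: EPSILON}
  - {type: helix3, id: a}
  - {type: strand, id: j2, min: 0, max: 6}
  - {type: helix5, id: b, min: 3, max: 12}
  - {type: strand, id: Lb, min: 3, max: 12, role: KAPPA}
  - {type: helix3, id: b}
  - {type: strand, id: j3, min: 0, max: 6}
  - {type: helix5, id: c, min: 3, max: 12}
  - {type: strand, id: jc1, min: 0, max: 4}
  - {type: helix5, id: c1, min: 3, max: 10}
  - {type: strand, id: Lc1, min: 4, max: 12, role: EBS2}
  - {type: helix3, id: c1}
  - {type: strand, id: jc2, min: 0, max: 4}
  - {type: helix3, id: c}
  - {type: strand, id: j4, min: 0, max: 6}
  - {type: helix5, id: d, min: 3, max: 12}
  - {type: strand, id: Ld, min: 5, max: 8, role: EBS1}
  - {type: helix3, id: d}
  - {type: strand, id: j5, min: 0, max: 6}
  - {type: helix3, id: i}
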