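# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `introscan`. Everything stated here is computed by the
package itself (the test suite and `scripts/acceptance.py`); nothing is
imported from external analyses.

## The descriptor language

A descriptor encodes a secondary-structure model as an ordered 5'→3'
list of elements: helix half-sides (each helix contributes a `helix5`
and a matching `helix3` entry) and single strands. Helices carry a
base-pair length range and an allowed-pair set — by default Watson–Crick
plus the G·U wobble, i.e. non-canonical pairs are prohibited. Strands
carry a nucleotide length range, an optional IUPAC pattern (or list of
alternative patterns) anchored at the element's 5' end, and an optional
role tag naming its biological function (5' splice site, EBS1/EBS2
loops, κ and ε contact loops, α/β pseudoknot partners). Nesting is
implied by side order, exactly as brackets imply nesting in dot-bracket
strings; a helix flagged `pseudoknot: true` is exempt from the nesting
check, its sides are matched as unconstrained strands, and its pairing
is assessed downstream as a tertiary complementarity filter. This keeps
the matcher's search topology a tree and the search polynomial.

## The shipped DI-domain models

The two canonical DI models start at the splice-site consensus
(GUGCG/UUGCG/GGGCG — note a single IUPAC string cannot express this
3-member set, which is why patterns admit alternatives) and arrange the
DI closing stem (i) around stem-loop subdomains a–d: the ε loop in
subdomain a, the κ loop in subdomain b, EBS2 in the c1 hairpin of
subdomain c, EBS1 in the terminal loop of subdomain d.

* **IIA_DI** is deliberately relaxed: principal stems 3–12 bp, terminal
  loops 3–20 nt (role loops sized to their function, e.g. EBS1 5–8 nt),
  joiners 0–6 nt. Six stems in total.
* **IIB_DI** carries the IIB-distinctive stem set and tighter geometry:
  subdomain c holds two hairpins (c1 with EBS2 plus the extra c2 stem),
  subdomain d is compound with EBS1 in a nested d1 hairpin, principal
  stems require ≥5 bp and sub-stems ≥4 bp. Eight stems in total.

The asymmetry is intentional and is the models' defining empirical
property: with identical downstream filters, the IIA model's
false-positive rate on null sequence is on the order of 10⁻⁶ per nt
while the IIB model's is below measurability at desk scale — matching
the relaxed-versus-specific character of the two intron classes. During
development we verified that topology alone (extra stems at 3-bp minima)
does *not* create this separation — short stems with flexible loops are
almost always satisfiable somewhere — so the IIB model's stem-length
minima are part of its definition. Every range is user-overridable in
the descriptor file.

The models are compact relative to full-length DI domains (maximum spans
~230–300 nt); they describe the conserved core stems, not every
species-specific insertion.

## The matcher

Matching is a small constraint-satisfaction problem: assign a length to
every element so that spans tile the window, helix sides base-pair under
the allowed set, and patterns match. Placements are anchored at
occurrences of the splice-site pattern (or at every position, for
descriptors without one). Three devices keep it fast:

* interval propagation — suffix minimum/maximum span sums prune
  infeasible partial assignments;
* a memoized existence table over (element, interval) states;
* vectorized complementarity masks that screen candidate helix closing
  positions in bulk.

A locus can admit enormously many satisfying assignments (10⁵–10⁶ at a
planted intron), so the representative fold is *not* chosen by
enumeration: the minimum-energy satisfying fold is computed exactly by
dynamic programming over the descriptor tree. The energy decomposes per
helix subtree — internal stacking plus the penalty of the loop the
innermost pair closes — and the coaxial-stack case (single child, no
gaps) depends only on residues at interval boundaries, so the minimum is
exact. Energy ties break toward longer helices, then smaller element
lengths, greedily 5'→3' during reconstruction. Full enumeration
(`policy="all"`, with a documented per-anchor cap of 2000) is retained
for oracle tests. The pipeline scans with one candidate per anchor,
applies the gates, and then reduces overlapping candidates (≥50% of the
shorter interval) to the accepted one of lowest energy — gating before
locus reduction, so a spurious lower-energy overlap cannot evict a
gate-passing candidate.

Scanning is forward-strand only; the CLI `--both-strands` flag scans the
reverse complement explicitly. `N` never pairs and matches only `N`
pattern positions.

## Energy model and the stability filter

The shipped energy model is a reduced nearest-neighbor scheme: a
36-entry stacking table over the six pair classes (Watson–Crick values
at standard magnitudes, flat representative wobble values) and
Jacobson–Stockmayer logarithmic loop penalties (hairpin 5.4 + 1.08·ln(n/3),
bulge 3.8 + 1.08·ln n, interior 1.7 + 1.08·ln(n/2), multiloop
3.4 + 0.4·branches + 0.1·unpaired, all kcal/mol at 37 °C). Absolute
energies are not comparable to a full Turner-parameter evaluator and are
not meant to be: the filter is defined on the Z-score, which is robust
to the energy scale. Any evaluator with the same signature can be
plugged in through the `EnergyModel` slot without touching filter logic.

The null for Z is the candidate window's own dinucleotide-preserving
shuffle ensemble (exact counts, fixed terminal residues), generated by
the Euler-path method with random-arborescence sampling — uniform over
valid shuffles. The same dot-bracket is re-evaluated on each shuffle; a
pair broken by the shuffle simply contributes no stacking term (loop
penalties still apply), which keeps the null defined for every shuffle
without re-matching. Default 100 shuffles per candidate (standard error
on Z ≈ 0.1). A window that is its own only valid shuffle has zero null
variance; that is reported as a degenerate null and the candidate fails
the filter conservatively. The threshold −1.48 is treated as a given
constant of the method; the inequality is strict.

Two different null constructions are used for two different jobs, both
deliberately: *fresh* first-order-Markov sequences matching a reference
dinucleotide table for the false-positive-rate experiments (each
nucleotide scanned is new), versus *exact-count shuffles of the window
itself* for the Z statistic (the conventional energy-significance null).

## Tertiary filters

The shared primitive is best ungapped antiparallel complementarity
between two spans over all sliding registers, scored by the longest
contiguous run of allowed pairs. Defaults (all config-overridable, and
explicitly assumptions — the detection thresholds are not specified by
the method's source beyond naming the interactions):

| interaction | span A | span B | min contiguous pairs |
|---|---|---|---|
| EBS1–IBS1 | EBS1 loop | 7 nt of exon 5' of the intron | 5 |
| EBS2–IBS2 | EBS2 loop | next 7 nt upstream | 4 |
| κ | κ loop | 20 nt window 3' of the matched DI region | 3 |
| ε | ε loop | intron positions 3–4 | 2 |
| α–α', β–β' | role-tagged spans | primed partners | 4 (annotated only) |

The κ partner window is a stated approximation: κ' lies near DV, which a
DI-only model cannot place precisely, so a fixed window immediately
downstream of the match stands in for it. The gate is conjunctive over
EBS1–IBS1, EBS2–IBS2, κ and ε; a contact whose partner window falls off
the sequence end is *not-evaluable*, which is distinct from not-found
and does not fail the gate. α/β pseudoknots are reported but never
required (degenerate introns lacking β–β' are a documented biological
class).

## RT motifs

YADD (and its single-substitution variant YADV, reported separately and
flagged) is sought in the three forward reading frames under the
standard genetic code; stop codons do not terminate the scan, because
DIV ORFs of degenerate introns may be interrupted (a longest-ORF mode
exists by flag). RT motif conservation is the best ungapped
sliding-window percent identity of each reference block against the
frame translations, conserved iff > 70% strictly. Whether the original
analysis allowed gaps or used a substitution matrix is not specified;
ungapped identity is the simplest faithful reading and is the documented
default. Reference blocks are user-supplied (peptide FASTA, labels
sharing a block id before the first `|` are alternatives for one block);
the test suite uses synthetic stand-ins rather than inventing published
sequences.

## Structure comparison

Dot-bracket structures map losslessly to ordered rooted trees (pair →
internal node, unpaired base → leaf, virtual root). Distance is
Zhang–Shasha tree edit distance, default unit insert/delete/relabel
costs, verified against an exhaustive edit-recursion oracle on small
structures. A `vienna` cost scheme (unpaired indel 1, pair indel 2,
relabel 1) reproduces the classic full-structure comparison program's
defaults and is cross-checked against that binary in the tests. UPGMA
follows the textbook size-weighted average-linkage agglomeration with a
deterministic tie-break (equal-distance merges take the
lexicographically smallest cluster labels); output is an ultrametric
tree serialized as Newick.

## Synthetic data: what it emulates and what it does not

The generator produces (a) Markov null sequence from a shipped
AT-rich organellar-like dinucleotide table (Euler-balanced; replaceable
by a composition estimated from user genomes), and (b) planted intron
instances: element lengths sampled from the descriptor ranges, helices
filled as perfect Watson–Crick complements with G+C fraction 0.6,
patterns instantiated, and designed tertiary partners written into the
flanks (IBS1/IBS2 upstream, κ' downstream at offset 2, ε complement
tiled across its loop). EBS loops are designed at full window length so
the planted complement survives small boundary shifts of the
representative fold.

Planted positives are *idealized*: perfect helices, perfect designed
contacts, uniform background. Passing recall tests therefore
demonstrates that the machinery recovers structures that satisfy the
model — not that the model captures every real intron. Real organellar
introns diverge from the shipped core models (acquired/lost stems fall
outside the descriptor by construction), carry long DIV insertions, and
sit in genomes with local composition structure the first-order Markov
null does not reproduce.

## Problem sizes and numerical choices

Default study sizes, chosen as desk-scale settings of the method:
recall on 200 planted IIA positives in 1.2-kb backgrounds; false
positive rates on 2×10⁶ nt of null per model (exact Garwood 95% Poisson
intervals make the precision of small-count estimates explicit — at
measured IIA rates, 2×10⁶ nt yields only a few hits, so rates are
order-of-magnitude estimates); Z calibration on 150 chance windows of
40 nt with 40 shuffles each. The IIB model's published-scale rate
(~10⁻⁷–10⁻⁸ per nt) is below desk-scale measurability; the package
reports its count (typically zero at 2×10⁶ nt) with the upper Poisson
bound, and the specificity ordering rate(IIB) < rate(IIA) is the
assertion tested. Reproducibility: every stochastic component takes a
seed or a NumPy `Generator`; the pipeline derives per-candidate shuffle
streams from (config seed, locus), so verdicts do not depend on scan
order.

## Known limitations

* Descriptors are hand-specified; there is no model training, and no
  general MFE folding — only descriptor-constrained placement.
* DII–DVI are not modeled by the shipped files (the language can express
  them; the shipped models cover DI, where class topology lives).
* The energy model omits terminal-mismatch, dangling-end and
  special-hairpin terms; absolute energies are reduced-model values.
* κ/ε geometry is an explicit approximation (above).
* The homolog-cluster overlay uses whole-window edit-distance identity
  (via edlib), not flank-extension analysis of the surrounding genome.
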