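"""Long-range interaction filters.

Group II intron function requires a set of tertiary contacts beyond the
secondary structure: the exon-binding loops EBS1/EBS2 in DI must be
complementary to the intron-binding sites IBS1/IBS2 in the 5' exon, the
kappa and epsilon contacts stabilize the catalytic core, and alpha-alpha'
and beta-beta' pseudoknots knit DI together.  The shared detection
primitive is ungapped antiparallel complementarity: two spans interact
when, at the best sliding register, at least ``min_pairs`` *contiguous*
Watson-Crick/G·U pairs form.

A candidate passes the tertiary gate when EBS1-IBS1, EBS2-IBS2, kappa
and epsilon are all found; alpha/beta pseudoknots are annotated and
reported but not required.  An interaction whose partner window falls
off the sequence (e.g. no upstream exon) is *not-evaluable*, which is
distinct from not-found and does not fail the gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .descriptor import Descriptor, WATSON_CRICK_WOBBLE
from .scanner import NucleotideSequence, StructureMatch

__all__ = [
    "TertiaryAnnotation",
    "InteractionConfig",
    "ConfigurationError",
    "check_complementarity",
    "annotate_interactions",
    "splice_site_ok",
    "tertiary_gate",
    "SPLICE5_CONSENSUS",
]

#: The three admissible 5' splice-site starts.
SPLICE5_CONSENSUS = ("GUGCG", "UUGCG", "GGGCG")


class ConfigurationError(ValueError):
    """A required interaction has no role-tagged anchor in the descriptor."""


@dataclass(frozen=True)
class TertiaryAnnotation:
    """One detected (or absent, or not-evaluable) long-range interaction."""

    interaction: str
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    n_pairs: int
    found: bool
    evaluable: bool = True
    register_a: Optional[tuple[int, int]] = None
    register_b: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class InteractionConfig:
    """Detection thresholds and window geometry (all user-overridable).

    The published method names the interactions but not their detection
    thresholds; these defaults follow canonical group II intron geometry:
    IBS1 is the 7 nt of exon immediately 5' of the intron, IBS2 the 7 nt
    before that, epsilon' sits at intron positions 3-4, and the kappa
    partner is sought in a window just 3' of the matched DI region.
    """

    ebs1_min: int = 5
    ibs1_window: int = 7
    ebs2_min: int = 4
    ibs2_window: int = 7
    alpha_min: int = 4
    beta_min: int = 4
    kappa_min: int = 3
    kappa_window: int = 20
    epsilon_min: int = 2
    required: tuple[str, ...] = ("EBS1_IBS1", "EBS2_IBS2", "KAPPA", "EPSILON")


def check_complementarity(
    seq,
    span_a: tuple[int, int],
    span_b: tuple[int, int],
    min_pairs: int,
    allowed_pairs: frozenset[str] = WATSON_CRICK_WOBBLE,
    interaction: str = "",
) -> TertiaryAnnotation:
    """Best ungapped antiparallel pairing between two disjoint spans.

    Slides all registers of span_a against span_b (a running 5'→3', b
    3'→5'); ``n_pairs`` is the longest contiguous run of allowed pairs
    over all registers, and ``found`` requires n_pairs >= min_pairs.
    """
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq
    (sa, ea), (sb, eb) = span_a, span_b
    if sa < 0 or sb < 0 or ea > len(s) or eb > len(s):
        raise ValueError("span outside sequence")
    if sa < eb and sb < ea:
        raise ValueError("spans must be disjoint")
    a, b = s[sa:ea], s[sb:eb]
    best = 0
    best_reg = None
    for ia in range(len(a)):
        for ib in range(len(b) - 1, -1, -1):
            # run starting with a[ia] paired to b[ib], extending a forward
            # and b backward; count only maximal starts
            if ia > 0 and ib < len(b) - 1 and (a[ia - 1] + b[ib + 1]) in allowed_pairs:
                continue
            t = 0
            while ia + t < len(a) and ib - t >= 0 and (a[ia + t] + b[ib - t]) in allowed_pairs:
                t += 1
            if t > best:
                best = t
                best_reg = (
                    (sa + ia, sa + ia + t),
                    (sb + ib - t + 1, sb + ib + 1),
                )
    return TertiaryAnnotation(
        interaction=interaction,
        span_a=span_a,
        span_b=span_b,
        n_pairs=best,
        found=best >= min_pairs,
        register_a=best_reg[0] if best_reg else None,
        register_b=best_reg[1] if best_reg else None,
    )


def _not_evaluable(interaction: str, span_a, span_b) -> TertiaryAnnotation:
    return TertiaryAnnotation(
        interaction=interaction,
        span_a=span_a,
        span_b=span_b,
        n_pairs=0,
        found=False,
        evaluable=False,
    )


def annotate_interactions(
    m: StructureMatch,
    seq: NucleotideSequence,
    d: Descriptor,
    config: Optional[InteractionConfig] = None,
) -> list[TertiaryAnnotation]:
    """Evaluate every configured interaction for one structure match.

    EBS loops are paired against the exon windows immediately 5' of the
    intron start (IBS1 abutting the splice site, IBS2 upstream of IBS1);
    epsilon pairs its loop against intron positions 3-4; kappa pairs its
    loop against a short window 3' of the matched region, where DV would
    sit; alpha/beta pair role-tagged spans against their primed partners
    when both tags exist in the descriptor.
    """
    cfg = config or InteractionConfig()
    n = len(seq)
    out: list[TertiaryAnnotation] = []

    def role_span(role: str) -> Optional[tuple[int, int]]:
        el = d.element_by_role(role)
        if el is None:
            return None
        return m.element_spans.get(el.id)

    def require(role: str, interaction: str) -> tuple[int, int]:
        span = role_span(role)
        if span is None:
            raise ConfigurationError(
                f"interaction {interaction} requires a {role}-tagged element "
                f"in descriptor {d.name}"
            )
        return span

    for interaction in cfg.required:
        if interaction == "EBS1_IBS1":
            span_a = require("EBS1", interaction)
            lo = m.start - cfg.ibs1_window
            if lo < 0:
                out.append(_not_evaluable(interaction, span_a, (0, m.start)))
                continue
            out.append(
                check_complementarity(
                    seq, span_a, (lo, m.start), cfg.ebs1_min, interaction=interaction
                )
            )
        elif interaction == "EBS2_IBS2":
            span_a = require("EBS2", interaction)
            hi = m.start - cfg.ibs1_window
            lo = hi - cfg.ibs2_window
            if lo < 0:
                out.append(_not_evaluable(interaction, span_a, (max(hi, 0), max(hi, 0))))
                continue
            out.append(
                check_complementarity(
                    seq, span_a, (lo, hi), cfg.ebs2_min, interaction=interaction
                )
            )
        elif interaction == "KAPPA":
            span_a = require("KAPPA", interaction)
            hi = min(m.end + cfg.kappa_window, n)
            if hi - m.end < cfg.kappa_min:
                out.append(_not_evaluable(interaction, span_a, (m.end, hi)))
                continue
            out.append(
                check_complementarity(
                    seq, span_a, (m.end, hi), cfg.kappa_min, interaction=interaction
                )
            )
        elif interaction == "EPSILON":
            span_a = require("EPSILON", interaction)
            span_b = (m.start + 2, m.start + 4)
            out.append(
                check_complementarity(
                    seq, span_a, span_b, cfg.epsilon_min, interaction=interaction
                )
            )
        else:
            raise ConfigurationError(f"unknown required interaction {interaction!r}")

    for name, min_pairs in (("ALPHA", cfg.alpha_min), ("BETA", cfg.beta_min)):
        span_a = role_span(name)
        span_b = role_span(name + "_P")
        if span_a is not None and span_b is not None:
            out.append(
                check_complementarity(
                    seq, span_a, span_b, min_pairs, interaction=name
                )
            )
    return out


def splice_site_ok(m: StructureMatch, seq: NucleotideSequence) -> bool:
    """True iff the match starts with one of the three 5' splice sites."""
    return seq.residues[m.start : m.start + 5] in SPLICE5_CONSENSUS


def tertiary_gate(
    annotations: list[TertiaryAnnotation],
    config: Optional[InteractionConfig] = None,
) -> bool:
    """Conjunctive gate over the required interactions.

    Not-evaluable annotations (missing flank) do not fail the gate;
    alpha/beta annotations are informational only.
    """
    cfg = config or InteractionConfig()
    by_name = {a.interaction: a for a in annotations}
    for name in cfg.required:
        ann = by_name.get(name)
        if ann is None:
            return False
        if ann.evaluable and not ann.found:
            return False
    return True
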