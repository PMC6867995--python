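"""End-to-end candidate calling.

Stage order: descriptor scan → 5' splice-site gate → stability gate
(Z < −1.48 against dinucleotide-shuffle nulls) → tertiary-interaction
gate → RT motif annotation.  Gates are conjunctive, so the accepted set
is order-independent; the cheap sequence gate simply runs before the
Monte-Carlo one.  Every candidate carries its verdict and, when
rejected, the first failing stage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import energetics, motifs, tertiary
from .descriptor import Descriptor
from .energetics import DegenerateNullError, ZScoreResult, Z_THRESHOLD
from .scanner import NucleotideSequence, StructureMatch, scan, validate_match
from .tertiary import InteractionConfig, TertiaryAnnotation

__all__ = [
    "PipelineConfig",
    "IntronCall",
    "run_pipeline",
    "dedupe",
    "classify_and_group",
    "revalidate_call",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds, windows and gate switches for a pipeline run."""

    z_threshold: float = Z_THRESHOLD
    n_shuffles: int = 100
    enable_splice: bool = True
    enable_stability: bool = True
    enable_tertiary: bool = True
    tertiary: InteractionConfig = field(default_factory=InteractionConfig)
    rt_references: tuple[tuple[str, str], ...] = ()
    rt_threshold: float = motifs.RT_IDENTITY_THRESHOLD
    homology_identity: float = 90.0
    overlap_frac: float = 0.5
    energy_model: Optional[energetics.EnergyModel] = None
    seed: int = 0


@dataclass
class IntronCall:
    """Aggregate record for one candidate intron."""

    match: StructureMatch
    z: Optional[ZScoreResult]
    tertiary: list[TertiaryAnnotation]
    motif_hits: list[motifs.MotifHit]
    rt_scores: list[motifs.RTMotifScore]
    intron_class: str
    orf_less: bool
    verdict: str  # "accepted" or "rejected:<stage>"
    group_hint: Optional[str] = None
    homolog_cluster: Optional[int] = None
    copy_count: int = 1

    @property
    def accepted(self) -> bool:
        return self.verdict == "accepted"


def _match_seed(config_seed: int, m: StructureMatch) -> int:
    # stable per-candidate stream: same sequence+locus ⇒ same shuffles
    h = zlib.crc32(f"{m.seq_id}:{m.start}:{m.end}".encode())
    return (config_seed * 2654435761 + h) % (2**31 - 1)


def run_pipeline(
    sequences: Iterable[NucleotideSequence],
    models: Sequence[Descriptor],
    config: Optional[PipelineConfig] = None,
) -> list[IntronCall]:
    """Scan sequences with each model and push candidates through the gates."""
    cfg = config or PipelineConfig()
    if not models:
        raise ValueError("at least one descriptor model is required")
    calls: list[IntronCall] = []
    for seq in sequences:
        for d in models:
            judged = [
                _judge(m, seq, d, cfg)
                for m in scan(
                    seq, d, policy="best_per_anchor",
                    energy_model=cfg.energy_model,
                )
            ]
            calls.extend(_reduce_call_loci(judged, cfg.overlap_frac))
    return calls


def _reduce_call_loci(calls: list[IntronCall], overlap_frac: float) -> list[IntronCall]:
    """One call per locus: overlapping candidates reduce to the accepted one
    with the lowest energy, or — if none passed the gates — the
    lowest-energy rejected candidate (kept for reporting)."""
    kept: list[IntronCall] = []
    ordered = sorted(
        calls, key=lambda c: (not c.accepted, c.match.energy, c.match.start)
    )
    for c in ordered:
        m = c.match
        clash = False
        for other in kept:
            o = other.match
            ov = min(m.end, o.end) - max(m.start, o.start)
            if ov > 0 and ov >= overlap_frac * min(
                m.end - m.start, o.end - o.start
            ):
                clash = True
                break
        if not clash:
            kept.append(c)
    return sorted(kept, key=lambda c: c.match.start)


def _judge(
    m: StructureMatch,
    seq: NucleotideSequence,
    d: Descriptor,
    cfg: PipelineConfig,
) -> IntronCall:
    z: Optional[ZScoreResult] = None
    anns: list[TertiaryAnnotation] = []
    verdict = "accepted"

    if cfg.enable_splice and not tertiary.splice_site_ok(m, seq):
        verdict = "rejected:splice_site"

    if verdict == "accepted" and cfg.enable_stability:
        try:
            z = energetics.z_score(
                m.window(seq),
                m.dot_bracket,
                model=cfg.energy_model,
                n_shuffles=cfg.n_shuffles,
                rng_seed=_match_seed(cfg.seed, m),
            )
            if not (z.z < cfg.z_threshold):
                verdict = "rejected:stability"
        except DegenerateNullError:
            verdict = "rejected:stability"  # conservative: no null, no pass

    if verdict == "accepted" and cfg.enable_tertiary:
        anns = tertiary.annotate_interactions(m, seq, d, cfg.tertiary)
        if not tertiary.tertiary_gate(anns, cfg.tertiary):
            verdict = "rejected:tertiary"
    elif verdict != "accepted" and cfg.enable_tertiary:
        # annotate anyway for reporting; the verdict already stands
        try:
            anns = tertiary.annotate_interactions(m, seq, d, cfg.tertiary)
        except tertiary.ConfigurationError:
            anns = []

    hits: list[motifs.MotifHit] = []
    scores: list[motifs.RTMotifScore] = []
    if verdict == "accepted":
        hits = motifs.find_yadd(m.window(seq))
        if cfg.rt_references:
            scores = motifs.score_rt_motifs(
                m.window(seq), cfg.rt_references, cfg.rt_threshold
            )
    orf_less = not any(not h.is_variant for h in hits) and not any(
        s.conserved for s in scores
    )
    return IntronCall(
        match=m,
        z=z,
        tertiary=anns,
        motif_hits=hits,
        rt_scores=scores,
        intron_class=d.intron_class,
        orf_less=orf_less,
        verdict=verdict,
    )


def dedupe(calls: list[IntronCall], sequences: Optional[dict[str, NucleotideSequence]] = None) -> list[IntronCall]:
    """Collapse calls whose matched subsequences are identical strings.

    The representative (first by sequence id, then coordinate) carries
    the copy count.  Needs the scanned sequences to read the matched
    residues; calls whose sequence is unavailable pass through unchanged.
    """
    groups: dict[str, list[IntronCall]] = {}
    passthrough: list[IntronCall] = []
    for call in calls:
        if sequences is None or call.match.seq_id not in sequences:
            if hasattr(call, "_matched_cache"):
                key = call._matched_cache
            else:
                passthrough.append(call)
                continue
        else:
            key = call.match.window(sequences[call.match.seq_id])
        groups.setdefault(key, []).append(call)
    out: list[IntronCall] = []
    for key, members in groups.items():
        members.sort(key=lambda c: (c.match.seq_id, c.match.start))
        rep = members[0]
        rep.copy_count = len(members)
        out.append(rep)
    out.extend(passthrough)
    out.sort(key=lambda c: (c.match.seq_id, c.match.start))
    return out


def _identity(a: str, b: str) -> float:
    """Ungapped-anchor percent identity via banded edit distance."""
    if a == b:
        return 100.0
    try:
        import edlib

        res = edlib.align(a, b, task="distance")
        dist = res["editDistance"]
    except ImportError:  # pragma: no cover - edlib is normally present
        from difflib import SequenceMatcher

        ratio = SequenceMatcher(None, a, b).ratio()
        return 100.0 * ratio
    return 100.0 * (1.0 - dist / max(len(a), len(b)))


def classify_and_group(
    calls: list[IntronCall],
    sequences: Optional[dict[str, NucleotideSequence]] = None,
    identity_threshold: float = 90.0,
) -> dict:
    """Assign group hints and homolog clusters to accepted calls.

    YADD_RT: a YADD hit plus at least one conserved RT block (the
    functional-RT group); NO_YADD otherwise.  Calls whose matched
    sequences exceed the identity threshold against one another share a
    homolog cluster id (single-linkage).
    """
    accepted = [c for c in calls if c.accepted]
    for c in accepted:
        has_yadd = any(h.motif == "YADD" for h in c.motif_hits)
        has_rt = any(s.conserved for s in c.rt_scores)
        c.group_hint = "YADD_RT" if (has_yadd and has_rt) else "NO_YADD"

    if sequences is not None and accepted:
        seqs = [c.match.window(sequences[c.match.seq_id]) for c in accepted]
        parent = list(range(len(accepted)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(accepted)):
            for j in range(i + 1, len(accepted)):
                if _identity(seqs[i], seqs[j]) >= identity_threshold:
                    parent[find(i)] = find(j)
        roots: dict[int, int] = {}
        for i, c in enumerate(accepted):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots)
            c.homolog_cluster = roots[r]
            # multi-member clusters are flagged as the homolog group overlay
        sizes: dict[int, int] = {}
        for c in accepted:
            sizes[c.homolog_cluster] = sizes.get(c.homolog_cluster, 0) + 1
        for c in accepted:
            if sizes[c.homolog_cluster] > 1 and c.group_hint == "NO_YADD":
                c.group_hint = "HOMOLOG_CLUSTER"

    groups: dict[str, list[IntronCall]] = {}
    for c in accepted:
        groups.setdefault(c.group_hint, []).append(c)
    return {
        "calls": accepted,
        "groups": groups,
        "counts": {k: len(v) for k, v in groups.items()},
    }


def revalidate_call(
    call: IntronCall,
    seq: NucleotideSequence,
    d: Descriptor,
    cfg: Optional[PipelineConfig] = None,
) -> list[str]:
    """Independent audit of an accepted call, outside pipeline bookkeeping."""
    cfg = cfg or PipelineConfig()
    diags = validate_match(call.match, seq, d)
    if cfg.enable_splice and not tertiary.splice_site_ok(call.match, seq):
        diags.append("splice site not in consensus")
    if cfg.enable_stability:
        if call.z is None:
            diags.append("missing Z-score on accepted call")
        elif not (call.z.z < cfg.z_threshold):
            diags.append(f"z={call.z.z} does not pass the stability criterion")
    if cfg.enable_tertiary:
        anns = tertiary.annotate_interactions(call.match, seq, d, cfg.tertiary)
        if not tertiary.tertiary_gate(anns, cfg.tertiary):
            diags.append("tertiary gate fails on re-annotation")
    return diags
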