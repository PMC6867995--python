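"""Reverse-transcriptase motif analysis.

Functional group II introns encode a reverse transcriptase in their DIV
ORF; its active site carries the YADD tetrapeptide (YADV is one
nucleotide substitution away).  This module locates YADD/YADV in the
three forward reading frames of a candidate intron and scores ungapped
RT motif blocks against user-supplied reference motifs: a block counts
as conserved when its best sliding-window percent identity against any
reference *exceeds* 70% (strict).

Stop codons do not terminate the scan — DIV ORFs of degenerate introns
may be interrupted — unless longest-ORF mode is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "MotifHit",
    "RTMotifScore",
    "find_yadd",
    "score_rt_motifs",
    "motif_position_report",
    "translate_frames",
]

RT_IDENTITY_THRESHOLD = 70.0


@dataclass(frozen=True)
class MotifHit:
    """One YADD/YADV occurrence in a forward reading frame."""

    motif: str  # "YADD" or "YADV"
    frame: int  # 0, 1, 2
    nt_offset: int  # nt from intron start to the first nt of the motif codon
    aa_context: str
    is_variant: bool = False


@dataclass(frozen=True)
class RTMotifScore:
    """Best identity of one RT motif block against the references."""

    motif_id: str
    best_identity: float
    best_reference: str
    conserved: bool


def translate_frames(intron_seq: str) -> list[str]:
    """Standard-code translation of the three forward frames."""
    seq = intron_seq.upper().replace("T", "U")
    out = []
    for frame in range(3):
        sub = seq[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate()) if sub else "")
    return out


def find_yadd(intron_seq: str) -> list[MotifHit]:
    """All YADD (and flagged YADV) occurrences in the forward frames."""
    hits: list[MotifHit] = []
    for frame, aa in enumerate(translate_frames(intron_seq)):
        for motif in ("YADD", "YADV"):
            start = 0
            while True:
                pos = aa.find(motif, start)
                if pos < 0:
                    break
                hits.append(
                    MotifHit(
                        motif=motif,
                        frame=frame,
                        nt_offset=frame + 3 * pos,
                        aa_context=aa[max(0, pos - 5) : pos + len(motif) + 5],
                        is_variant=(motif == "YADV"),
                    )
                )
                start = pos + 1
    hits.sort(key=lambda h: (h.nt_offset, h.motif))
    return hits


def _block_id(label: str) -> str:
    return label.split("|", 1)[0]


def score_rt_motifs(
    intron_seq: str,
    references: Sequence[tuple[str, str]],
    threshold: float = RT_IDENTITY_THRESHOLD,
    longest_orf_only: bool = False,
) -> list[RTMotifScore]:
    """Score each reference RT block by its best sliding-window identity.

    ``references`` holds (label, peptide) pairs; labels sharing a block
    id before the first ``|`` (e.g. ``RT3|E_faecium``) are alternatives
    for the same block and the block takes the best over all of them.
    Identity is ungapped: matches / block length x 100 over every window
    of the block's length in every forward-frame translation.
    """
    if not references:
        raise ValueError("references must be non-empty")
    frames = translate_frames(intron_seq)
    if longest_orf_only:
        frames = [max(aa.split("*"), key=len, default="") for aa in frames]
    if all(not aa for aa in frames):
        return []
    best: dict[str, tuple[float, str]] = {}
    order: list[str] = []
    for label, peptide in references:
        block = _block_id(label)
        if block not in best:
            best[block] = (0.0, label)
            order.append(block)
        L = len(peptide)
        if L == 0:
            raise ValueError(f"reference {label!r} is empty")
        for aa in frames:
            for i in range(len(aa) - L + 1):
                window = aa[i : i + L]
                ident = 100.0 * sum(x == y for x, y in zip(window, peptide)) / L
                if ident > best[block][0]:
                    best[block] = (ident, label)
    return [
        RTMotifScore(
            motif_id=block,
            best_identity=best[block][0],
            best_reference=best[block][1],
            conserved=best[block][0] > threshold,
        )
        for block in order
    ]


def motif_position_report(calls: Iterable) -> "pandas.DataFrame":  # noqa: F821
    """Per-intron table of YADD/YADV offsets and conserved RT blocks.

    One row per call: intron identity, YADD/YADV nt offsets (the distance
    from intron start to the motif codon), and the conserved block ids —
    the tabular form of a motif-position figure.
    """
    import pandas as pd

    rows = []
    for call in calls:
        yadd = [h.nt_offset for h in call.motif_hits if h.motif == "YADD"]
        yadv = [h.nt_offset for h in call.motif_hits if h.motif == "YADV"]
        conserved = [s.motif_id for s in call.rt_scores if s.conserved]
        rows.append(
            {
                "seq_id": call.match.seq_id,
                "start": call.match.start,
                "end": call.match.end,
                "intron_class": call.intron_class,
                "yadd_offsets": ",".join(map(str, yadd)),
                "yadv_offsets": ",".join(map(str, yadv)),
                "conserved_blocks": ",".join(conserved),
                "orf_less": call.orf_less,
            }
        )
    return pd.DataFrame(rows)
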