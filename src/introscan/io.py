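"""File formats: FASTA in, TSV/GFF3/dot-bracket/Newick out."""

from __future__ import annotations

from typing import Iterable, TextIO, Union

from Bio import SeqIO

from .pipeline import IntronCall
from .scanner import NucleotideSequence, StructureMatch


def read_fasta(path_or_handle: Union[str, TextIO]) -> list[NucleotideSequence]:
    """Read nucleotide FASTA; T is mapped to U, case is normalized."""
    return [
        NucleotideSequence.from_string(rec.id, str(rec.seq))
        for rec in SeqIO.parse(path_or_handle, "fasta")
    ]


def read_peptide_fasta(path_or_handle: Union[str, TextIO]) -> list[tuple[str, str]]:
    """Read labeled peptide blocks (RT reference motifs)."""
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path_or_handle, "fasta")
    ]


def write_matches_tsv(calls: Iterable[IntronCall], handle: TextIO) -> None:
    cols = [
        "seq_id", "start", "end", "strand", "model", "class", "energy",
        "z", "verdict", "group", "copies", "tertiary_found", "yadd", "dot_bracket",
    ]
    handle.write("\t".join(cols) + "\n")
    for c in calls:
        m = c.match
        found = ",".join(
            a.interaction for a in c.tertiary if a.found
        )
        yadd = ",".join(f"{h.motif}@{h.nt_offset}" for h in c.motif_hits)
        row = [
            m.seq_id, str(m.start), str(m.end), m.strand, m.descriptor_name,
            c.intron_class, f"{m.energy:.2f}",
            f"{c.z.z:.3f}" if c.z else "NA",
            c.verdict, c.group_hint or "NA", str(c.copy_count),
            found or "NA", yadd or "NA", m.dot_bracket,
        ]
        handle.write("\t".join(row) + "\n")


def write_gff3(calls: Iterable[IntronCall], handle: TextIO, source: str = "introscan") -> None:
    """GFF3 intron features (1-based closed coordinates)."""
    handle.write("##gff-version 3\n")
    for i, c in enumerate(calls):
        m = c.match
        attrs = [
            f"ID=intron{i + 1}",
            f"model={m.descriptor_name}",
            f"intron_class={c.intron_class}",
            f"verdict={c.verdict}",
        ]
        if c.z is not None:
            attrs.append(f"zscore={c.z.z:.3f}")
        found = [a.interaction for a in c.tertiary if a.found]
        if found:
            attrs.append("tertiary=" + ",".join(found))
        if c.group_hint:
            attrs.append(f"group={c.group_hint}")
        cols = [
            m.seq_id, source, "group_II_intron",
            str(m.start + 1), str(m.end), f"{m.energy:.2f}",
            m.strand, ".", ";".join(attrs),
        ]
        handle.write("\t".join(cols) + "\n")


def write_dot_bracket(
    match: StructureMatch, seq: NucleotideSequence, handle: TextIO
) -> None:
    """Vienna-style record: header, sequence, structure."""
    handle.write(f">{match.seq_id}/{match.start + 1}-{match.end}\n")
    handle.write(match.window(seq) + "\n")
    handle.write(match.dot_bracket + "\n")


def read_dot_bracket(handle: TextIO) -> list[tuple[str, str]]:
    """Read labeled structures from a Vienna-style dot-bracket file."""
    out: list[tuple[str, str]] = []
    label = None
    lines = [ln.strip() for ln in handle if ln.strip()]
    i = 0
    while i < len(lines):
        if lines[i].startswith(">"):
            label = lines[i][1:].split()[0]
            i += 1
            # optional sequence line before the structure line
            if i < len(lines) and set(lines[i]) <= set("ACGUNTacgunt"):
                i += 1
            if i < len(lines):
                out.append((label, lines[i]))
                i += 1
        else:
            out.append((f"s{len(out) + 1}", lines[i]))
            i += 1
    return out
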