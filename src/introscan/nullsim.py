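"""Null models and synthetic positives.

Two distinct null constructions are used, mirroring their two distinct
jobs:

* the *negative dataset* for false-positive-rate estimation consists of
  fresh random sequences drawn from the first-order Markov chain whose
  transition frequencies match a reference dinucleotide composition
  (5,000-nt chunks by default);
* the *stability null* for energy Z-scores uses exact-count
  dinucleotide-preserving shuffles of the candidate window itself
  (Euler-path shuffle in the style of Altschul & Erickson), which keeps
  all 16 dinucleotide counts and both terminal residues identical.

The module also plants descriptor-conforming introns into background
sequence (:func:`implant`), recording ground truth, so that scanner
recall and filter behavior can be measured on positives whose
coordinates are known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import numpy as np
from scipy.stats import chi2

from .descriptor import (
    Descriptor,
    HelixSide,
    IUPAC,
    StrandElement,
)
from .scanner import NucleotideSequence

__all__ = [
    "DinucleotideComposition",
    "FPRateEstimate",
    "ImplantDesign",
    "ImplantTruth",
    "random_sequences",
    "dinucleotide_shuffle",
    "implant",
    "estimate_fp_rate",
    "default_composition",
]

_NTS = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


@dataclass(frozen=True)
class DinucleotideComposition:
    """The 16 ordered dinucleotide counts of a sequence (or a target)."""

    counts: dict[str, float]
    first: Optional[str] = None
    last: Optional[str] = None

    @staticmethod
    def from_sequence(seq: str) -> "DinucleotideComposition":
        seq = seq.upper().replace("T", "U")
        counts = {a + b: 0.0 for a in _NTS for b in _NTS}
        for i in range(len(seq) - 1):
            di = seq[i : i + 2]
            if di in counts:
                counts[di] += 1
        return DinucleotideComposition(counts, seq[:1] or None, seq[-1:] or None)

    def is_realizable(self) -> bool:
        """Eulerian-path condition: some sequence has these exact counts."""
        out_deg = {a: 0.0 for a in _NTS}
        in_deg = {a: 0.0 for a in _NTS}
        for di, c in self.counts.items():
            if c < 0:
                return False
            out_deg[di[0]] += c
            in_deg[di[1]] += c
        used = [a for a in _NTS if out_deg[a] + in_deg[a] > 0]
        if not used:
            return False
        # weak connectivity on used vertices
        adj = {a: set() for a in used}
        for di, c in self.counts.items():
            if c > 0:
                adj[di[0]].add(di[1])
                adj[di[1]].add(di[0])
        seen = {used[0]}
        stack = [used[0]]
        while stack:
            for b in adj[stack.pop()]:
                if b not in seen:
                    seen.add(b)
                    stack.append(b)
        if set(used) - seen:
            return False
        starts = sum(1 for a in used if out_deg[a] - in_deg[a] == 1)
        ends = sum(1 for a in used if in_deg[a] - out_deg[a] == 1)
        balanced = all(abs(out_deg[a] - in_deg[a]) <= 1 for a in used)
        return balanced and starts <= 1 and ends <= 1


@dataclass(frozen=True)
class FPRateEstimate:
    """Surviving calls per nucleotide of null sequence scanned."""

    hits: int
    nt_scanned: int
    rate: float
    ci_low: float
    ci_high: float
    filter_stack: str

    def __post_init__(self):
        assert self.ci_low <= self.rate <= self.ci_high + 1e-300


def default_composition() -> DinucleotideComposition:
    """AT-rich organellar-like dinucleotide composition (shipped table)."""
    text = resources.files("introscan").joinpath(
        "data/organellar_dinucleotides.tsv"
    ).read_text()
    counts = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        di, c = line.split()
        counts[di.upper().replace("T", "U")] = float(c)
    for a in _NTS:
        for b in _NTS:
            counts.setdefault(a + b, 0.0)
    return DinucleotideComposition(counts)


def random_sequences(
    composition: DinucleotideComposition,
    length: int = 5000,
    n: int = 1,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[NucleotideSequence]:
    """Sample first-order Markov sequences matching a dinucleotide table."""
    if length < 2:
        raise ValueError("length must be >= 2")
    if not composition.is_realizable():
        raise ValueError("composition is not realizable by any sequence")
    rng = rng if rng is not None else np.random.default_rng(seed)
    trans = np.zeros((4, 4))
    for i, a in enumerate(_NTS):
        for j, b in enumerate(_NTS):
            trans[i, j] = composition.counts.get(a + b, 0.0)
    row = trans.sum(axis=1)
    start_p = row / row.sum()
    cum = np.zeros((4, 4))
    for i in range(4):
        if row[i] > 0:
            cum[i] = np.cumsum(trans[i] / row[i])
        else:  # absorbing symbol: stay (can only occur at the terminal residue)
            cum[i] = np.cumsum(np.eye(4)[i])
    out = []
    for k in range(n):
        u = rng.random(length)
        cur = int(np.searchsorted(np.cumsum(start_p), u[0], side="right"))
        chars = [cur]
        for t in range(1, length):
            cur = int(np.searchsorted(cum[cur], u[t], side="right"))
            cur = min(cur, 3)
            chars.append(cur)
        residues = "".join(_NTS[c] for c in chars)
        out.append(NucleotideSequence(f"null_{k}", residues))
    return out


def dinucleotide_shuffle(
    seq: str,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Exact dinucleotide-preserving shuffle (Euler-path method).

    The result has identical dinucleotide counts and the same first and
    last residue as the input.  Sampling follows the random-arborescence
    scheme: each non-terminal vertex is assigned a random final outgoing
    edge, the assignment is accepted when those final edges all lead to
    the terminal vertex, and the remaining edge multiset is permuted
    uniformly at random.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 nt to shuffle")
    rng = rng if rng is not None else np.random.default_rng(seed)
    adj: dict[str, list[str]] = {}
    for i in range(len(seq) - 1):
        adj.setdefault(seq[i], []).append(seq[i + 1])
    last = seq[-1]
    verts = [v for v in adj if v != last]
    if not verts:  # homopolymer or 2-mer
        return seq

    def leads_home(last_edge: dict[str, str]) -> bool:
        for v in verts:
            cur, hops = v, 0
            while cur != last and cur in last_edge and hops <= len(last_edge):
                cur = last_edge[cur]
                hops += 1
            if cur != last:
                return False
        return True

    while True:
        last_edge = {v: adj[v][rng.integers(len(adj[v]))] for v in verts}
        if leads_home(last_edge):
            break
    order: dict[str, list[str]] = {}
    for v, targets in adj.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        order[v] = rest + ([last_edge[v]] if v in last_edge else [])
    ptr = {v: 0 for v in order}
    out = [seq[0]]
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = order[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# synthetic positives

@dataclass(frozen=True)
class ImplantDesign:
    """Sampling options for planted intron instances."""

    helix_gc: float = 0.6  # G+C fraction of helix strands (stability)
    ibs1_window: int = 7
    ibs2_window: int = 7
    kappa_offset: int = 2  # nt between intron 3' end and the planted kappa partner
    splice_site: Optional[str] = None  # force one of GUGCG/UUGCG/GGGCG


@dataclass(frozen=True)
class ImplantTruth:
    """Ground truth for one planted intron."""

    seq_id: str
    start: int
    end: int
    element_spans: dict[str, tuple[int, int]]
    dot_bracket: str
    splice_site: str


def _sample_letter(rng, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return _NTS[int(rng.choice(4, p=p))]


def _instantiate_pattern(rng, alt: str, length: int, gc: float) -> str:
    out = [rng.choice(sorted(IUPAC[c])) for c in alt]
    while len(out) < length:
        out.append(_sample_letter(rng, 0.5))
    return "".join(out)


def implant(
    background: NucleotideSequence,
    d: Descriptor,
    position: int,
    design: Optional[ImplantDesign] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[NucleotideSequence, ImplantTruth]:
    """Plant a descriptor-conforming intron instance into background sequence.

    Helices are filled with perfect Watson–Crick complements, strand
    patterns are instantiated, and role-tagged elements get designed
    partners: the upstream flank receives IBS1/IBS2 complementary to the
    EBS loops, a κ' partner is written just downstream of the intron, and
    the ε loop is made complementary to intron positions 3–4.
    """
    design = design or ImplantDesign()
    rng = rng if rng is not None else np.random.default_rng(seed)

    lengths: dict[str, int] = {}
    role_cap = {
        "EBS1": design.ibs1_window,
        "EBS2": design.ibs2_window,
    }
    for el in d.elements:
        if isinstance(el, HelixSide):
            if el.id not in lengths:
                lengths[el.id] = int(
                    rng.integers(el.helix.min_len, el.helix.max_len + 1)
                )
        else:
            hi = el.max_len
            lo = el.min_len
            if el.role in role_cap:
                # design EBS loops at full window length: the planted
                # complement then survives small boundary shifts of the
                # representative fold
                lo = hi = min(el.max_len, max(el.min_len, role_cap[el.role]))
            if el.pattern:
                lo = max(lo, min(len(a) for a in el.pattern))
            lengths[el.id] = int(rng.integers(lo, max(lo, hi) + 1))

    contents: dict[str, str] = {}
    splice_site = None
    for el in d.elements:
        if isinstance(el, HelixSide):
            key = f"{el.id}.{el.side}p"
            if el.side == "5":
                contents[key] = "".join(
                    _sample_letter(rng, design.helix_gc) for _ in range(lengths[el.id])
                )
            else:
                contents[key] = revcomp(contents[f"{el.id}.5p"])
        else:
            L = lengths[el.id]
            if el.pattern:
                alts = [a for a in el.pattern if len(a) <= L] or list(el.pattern)
                if el.role == "SPLICE5" and design.splice_site:
                    alt = design.splice_site
                else:
                    alt = alts[int(rng.integers(len(alts)))]
                contents[el.id] = _instantiate_pattern(rng, alt, L, 0.5)
                if el.role == "SPLICE5":
                    splice_site = contents[el.id][:5]
            else:
                contents[el.id] = "".join(
                    _sample_letter(rng, 0.5) for _ in range(L)
                )

    # assemble in element order, recording spans relative to the intron start
    order_keys = []
    for el in d.elements:
        order_keys.append(
            f"{el.id}.{el.side}p" if isinstance(el, HelixSide) else el.id
        )
    # tertiary-role designed complementarities inside the intron
    intron = "".join(contents[k] for k in order_keys)
    offsets = {}
    pos = 0
    for k in order_keys:
        offsets[k] = (pos, pos + len(contents[k]))
        pos += len(contents[k])
    span_len = pos

    chars = list(intron)

    def _overwrite(key: str, payload: str, centered: bool = False):
        a, b = offsets[key]
        payload = payload[: b - a]
        if centered:  # robust to small boundary shifts of the matched fold
            a += (b - a - len(payload)) // 2
        chars[a : a + len(payload)] = list(payload)

    for el in d.elements:
        if isinstance(el, StrandElement) and el.role == "EPSILON":
            # tile the loop with the 2-nt complement of intron positions 3-4
            # so every register of the matched loop contains it
            a, b = offsets[el.id]
            unit = revcomp(intron[2:4])
            _overwrite(el.id, (unit * ((b - a) // 2 + 1))[: b - a])
        if isinstance(el, StrandElement) and el.role in ("ALPHA_P", "BETA_P", "EPSILON_P"):
            partner = d.element_by_role(el.role[:-2])
            if partner is not None:
                _overwrite(el.id, revcomp(contents[partner.id]))
    intron = "".join(chars)

    # place into the background with designed flanks
    w1, w2 = design.ibs1_window, design.ibs2_window
    upstream_need = w1 + w2
    ebs1 = d.element_by_role("EBS1")
    ebs2 = d.element_by_role("EBS2")
    kap = d.element_by_role("KAPPA")
    kappa_payload = revcomp(contents[kap.id]) if kap is not None else ""
    downstream_need = design.kappa_offset + len(kappa_payload)
    if position < (upstream_need if (ebs1 or ebs2) else 0):
        raise ValueError(f"position {position} too close to the 5' end")
    if position + span_len + downstream_need > len(background):
        raise ValueError(f"position {position} too close to the 3' end")

    bg = list(background.residues)
    bg[position : position + span_len] = list(intron)
    if ebs1 is not None:
        ibs1 = revcomp(intron[slice(*offsets[ebs1.id])])[:w1]
        bg[position - len(ibs1) : position] = list(ibs1)
    if ebs2 is not None:
        ibs2 = revcomp(intron[slice(*offsets[ebs2.id])])[:w2]
        bg[position - w1 - len(ibs2) : position - w1] = list(ibs2)
    if kap is not None:
        a = position + span_len + design.kappa_offset
        bg[a : a + len(kappa_payload)] = list(kappa_payload)

    residues = "".join(bg)
    spans = {k: (a + position, b + position) for k, (a, b) in offsets.items()}
    db = ["."] * span_len
    for el in d.elements:
        if isinstance(el, HelixSide) and el.side == "5" and not el.helix.pseudoknot:
            a5, b5 = offsets[f"{el.id}.5p"]
            a3, b3 = offsets[f"{el.id}.3p"]
            for x in range(a5, b5):
                db[x] = "("
            for x in range(a3, b3):
                db[x] = ")"
    truth = ImplantTruth(
        seq_id=background.id,
        start=position,
        end=position + span_len,
        element_spans=spans,
        dot_bracket="".join(db),
        splice_site=splice_site or intron[:5],
    )
    return NucleotideSequence(background.id, residues), truth


# ---------------------------------------------------------------------------
# false-positive rate

def garwood_ci(hits: int, nt: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact Poisson (Garwood) confidence interval for a rate."""
    alpha = 1 - conf
    lo = 0.0 if hits == 0 else 0.5 * chi2.ppf(alpha / 2, 2 * hits) / nt
    hi = 0.5 * chi2.ppf(1 - alpha / 2, 2 * hits + 2) / nt
    return lo, hi


def estimate_fp_rate(
    d: Descriptor,
    total_nt: int,
    seed: Optional[int] = None,
    composition: Optional[DinucleotideComposition] = None,
    with_splice: bool = True,
    with_tertiary: bool = True,
    with_stability: bool = False,
    chunk_len: int = 5000,
    config=None,
) -> FPRateEstimate:
    """Estimate surviving calls per nt of Markov null sequence.

    Null chunks (5,000 nt by default) are generated to ``total_nt`` and
    pushed through the configured filter stack exactly as the pipeline
    applies it.  The stability gate is off by default here: the published
    specificity analysis conditions on the splice-site consensus and the
    tertiary motifs.
    """
    from .pipeline import PipelineConfig, run_pipeline  # deferred: avoids cycle

    composition = composition or default_composition()
    rng = np.random.default_rng(seed)
    cfg = config or PipelineConfig()
    cfg = replace(
        cfg,
        enable_splice=with_splice,
        enable_stability=with_stability,
        enable_tertiary=with_tertiary,
        seed=int(rng.integers(2**31 - 1)),
    )
    hits = 0
    scanned = 0
    k = 0
    while scanned < total_nt:
        length = min(chunk_len, max(2, total_nt - scanned))
        seq = random_sequences(composition, length=length, n=1, rng=rng)[0]
        seq = NucleotideSequence(f"null_{k}", seq.residues)
        calls = run_pipeline([seq], [d], cfg)
        hits += sum(1 for c in calls if c.verdict == "accepted")
        scanned += length
        k += 1
    lo, hi = garwood_ci(hits, scanned)
    stack = "+".join(
        name
        for flag, name in [
            (True, "scan"),
            (with_splice, "splice"),
            (with_stability, "stability"),
            (with_tertiary, "tertiary"),
        ]
        if flag
    )
    return FPRateEstimate(hits, scanned, hits / scanned, lo, hi, stack)
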