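"""Descriptor placement search on nucleotide sequence.

The matcher treats a descriptor as a small constraint-satisfaction
problem: walking the elements 5'→3', it assigns a concrete length to
every strand and helix such that helix sides base-pair under the
descriptor's allowed pair classes and strand patterns match.  Placements
are anchored at candidate start positions (in practice, occurrences of
the 5' splice-site pattern) and solved by backtracking with interval
propagation: a memoized existence table over (element, interval) states
prunes dead branches before any enumeration work is spent on them, and
helix feasibility is screened with vectorized complementarity masks.

Matching is single-strand, 5'→3', forward-only; callers that want the
reverse complement scan it explicitly and track strand themselves.
``N`` residues never pair and match only ``N`` pattern positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .descriptor import (
    Descriptor,
    HelixSide,
    StrandElement,
    matches_pattern,
    min_span,
)

__all__ = [
    "NucleotideSequence",
    "StructureMatch",
    "scan",
    "match_at",
    "render_dot_bracket",
    "validate_match",
    "SequenceAlphabetError",
]

_ALPHABET = frozenset("ACGUN")
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_NTS = "ACGUN"


class SequenceAlphabetError(ValueError):
    """Residues outside A/C/G/U/N (after T→U mapping)."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An uppercase RNA sequence; T is mapped to U on construction."""

    id: str
    residues: str

    @staticmethod
    def from_string(seq_id: str, raw: str) -> "NucleotideSequence":
        residues = raw.upper().replace("T", "U")
        bad = set(residues) - _ALPHABET
        if bad:
            raise SequenceAlphabetError(
                f"{seq_id}: residues outside alphabet: {sorted(bad)}"
            )
        return NucleotideSequence(seq_id, residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class StructureMatch:
    """One placement of a descriptor on a sequence.

    ``element_spans`` maps strand ids to (start, end) and each helix to
    two entries ``<id>.5p`` and ``<id>.3p``.  Coordinates are 0-based
    half-open on the scanned sequence.  ``energy`` is the evaluated free
    energy of the placement under the model used by the scanner.
    """

    seq_id: str
    start: int
    end: int
    element_spans: dict[str, tuple[int, int]]
    dot_bracket: str
    descriptor_name: str
    intron_class: str
    energy: float = 0.0
    strand: str = "+"

    def window(self, seq: NucleotideSequence) -> str:
        return seq.residues[self.start : self.end]


# ---------------------------------------------------------------------------
# descriptor compilation

@dataclass(frozen=True)
class _Forest:
    nodes: tuple
    # suffix_min[k] / suffix_max[k]: span bounds of nodes[k:]
    suffix_min: tuple[int, ...]
    suffix_max: tuple[int, ...]
    key: int


def _node_bounds(node) -> tuple[int, int]:
    kind = node[0]
    if kind == "S":
        el = node[1]
        return el.min_len, el.max_len
    if kind == "K":  # pseudoknot half-side: matched as an unconstrained strand
        h = node[1]
        return h.min_len, h.max_len
    h, inner = node[1], node[2]
    return 2 * h.min_len + inner.suffix_min[0], 2 * h.max_len + inner.suffix_max[0]


_forest_counter = [0]


def _make_forest(nodes: list) -> _Forest:
    n = len(nodes)
    smin = [0] * (n + 1)
    smax = [0] * (n + 1)
    for k in range(n - 1, -1, -1):
        lo, hi = _node_bounds(nodes[k])
        smin[k] = smin[k + 1] + lo
        smax[k] = smax[k + 1] + hi
    _forest_counter[0] += 1
    return _Forest(tuple(nodes), tuple(smin), tuple(smax), _forest_counter[0])


def _compile(d: Descriptor) -> _Forest:
    # cached on the descriptor itself so the cache dies with the object
    cached = getattr(d, "_compiled_forest", None)
    if cached is not None:
        return cached

    def build(elements, pos) -> tuple[list, int]:
        nodes: list = []
        i = pos
        while i < len(elements):
            el = elements[i]
            if isinstance(el, StrandElement):
                nodes.append(("S", el))
                i += 1
            elif isinstance(el, HelixSide) and el.helix.pseudoknot:
                nodes.append(("K", el.helix, el.side))
                i += 1
            elif isinstance(el, HelixSide) and el.side == "5":
                inner_nodes, i = build(elements, i + 1)
                nodes.append(("H", el.helix, _make_forest(inner_nodes)))
                i += 1
            else:  # our parent's 3' side
                return nodes, i
        return nodes, i

    nodes, _ = build(list(d.elements), 0)
    forest = _make_forest(nodes)
    object.__setattr__(d, "_compiled_forest", forest)
    return forest


# ---------------------------------------------------------------------------
# the match engine

class _Engine:
    def __init__(self, seq: NucleotideSequence, d: Descriptor, model=None):
        self.s = seq.residues
        self.n = len(seq.residues)
        self.seq = seq
        self.d = d
        if model is None:
            from . import energetics  # deferred: energetics pulls in nullsim

            model = energetics.default_model()
        self.model = model
        self.forest = _compile(d)
        self.exists_memo: dict[tuple, bool] = {}
        self.idx = np.frombuffer(
            self.s.encode().translate(bytes.maketrans(b"ACGUN", bytes(range(5)))),
            dtype=np.uint8,
        )
        self._masks: dict[frozenset, list[np.ndarray]] = {}

    # -- pairing -----------------------------------------------------------
    def _mask(self, allowed: frozenset) -> list[np.ndarray]:
        cached = self._masks.get(allowed)
        if cached is not None:
            return cached
        M = np.zeros((5, 5), dtype=bool)
        for p in allowed:
            if p[0] in _CODE and p[1] in _CODE and "N" not in p:
                M[_CODE[p[0]], _CODE[p[1]]] = True
        masks = [M[b][self.idx] for b in range(5)]
        self._masks[allowed] = masks
        return masks

    def _run(self, i: int, y: int, allowed: frozenset, cap: int) -> int:
        """Length of the contiguous pairing run s[i]·s[y], s[i+1]·s[y-1], ..."""
        s = self.s
        t = 0
        while t < cap and i + t < y - t and (s[i + t] + s[y - t]) in allowed:
            t += 1
        return t

    def _helix_ends(self, i: int, h, e_lo: int, e_hi: int) -> Iterator[int]:
        """Candidate subtree-end positions e where the helix could close.

        The outermost pair is s[i]·s[e-1]; candidates need a contiguous
        run of at least ``min_len`` pairs on the (i, e-1) diagonal.
        """
        if e_hi < e_lo:
            return
        width = e_hi - e_lo + 1
        if width > 32:
            ys = np.arange(e_lo - 1, e_hi)
            masks = self._mask(h.allowed_pairs)
            ok = np.ones(width, dtype=bool)
            for t in range(h.min_len):
                if i + t >= self.n:
                    return
                ok &= masks[self.idx[i + t]][ys - t]
                ok &= ys - t > i + t
            for e in (np.nonzero(ok)[0] + e_lo):
                yield int(e)
        else:
            allowed = h.allowed_pairs
            for e in range(e_lo, e_hi + 1):
                if self._run(i, e - 1, allowed, h.min_len) >= h.min_len:
                    yield e

    # -- existence DP ------------------------------------------------------
    def _exists(self, forest: _Forest, k: int, i: int, j: int) -> bool:
        """Can nodes[k:] of ``forest`` exactly tile [i, j)?"""
        span = j - i
        if not (forest.suffix_min[k] <= span <= forest.suffix_max[k]):
            return False
        if k == len(forest.nodes):
            return True
        state = (forest.key, k, i, j)
        memo = self.exists_memo
        hit = memo.get(state)
        if hit is not None:
            return hit
        result = False
        node = forest.nodes[k]
        tail_min, tail_max = forest.suffix_min[k + 1], forest.suffix_max[k + 1]
        kind = node[0]
        if kind in ("S", "K"):
            lo, hi = _node_bounds(node)
            lo = max(lo, span - tail_max)
            hi = min(hi, span - tail_min)
            pat = node[1].pattern if kind == "S" else None
            for l in range(lo, hi + 1):
                if pat is not None and not matches_pattern(self.s[i : i + l], pat):
                    continue
                if self._exists(forest, k + 1, i + l, j):
                    result = True
                    break
        else:
            h, inner = node[1], node[2]
            imin, imax = inner.suffix_min[0], inner.suffix_max[0]
            e_lo = max(i + 2 * h.min_len + imin, j - tail_max)
            e_hi = min(i + 2 * h.max_len + imax, j - tail_min)
            for e in self._helix_ends(i, h, e_lo, e_hi):
                r = self._run(i, e - 1, h.allowed_pairs, h.max_len)
                L_lo = max(h.min_len, -((i + imax - e) // 2))  # ceil((e-i-imax)/2)
                L_hi = min(r, h.max_len, (e - i - imin) // 2)
                for L in range(L_lo, L_hi + 1):
                    if self._exists(inner, 0, i + L, e - L) and self._exists(
                        forest, k + 1, e, j
                    ):
                        result = True
                        break
                if result:
                    break
        memo[state] = result
        return result

    # -- enumeration -------------------------------------------------------
    def _gen_exact(self, forest: _Forest, k: int, i: int, j: int) -> Iterator[tuple]:
        """Yield span assignments (tuples of (key, start, end)) for nodes[k:]."""
        if k == len(forest.nodes):
            if i == j:
                yield ()
            return
        if not self._exists(forest, k, i, j):
            return
        span = j - i
        node = forest.nodes[k]
        tail_min, tail_max = forest.suffix_min[k + 1], forest.suffix_max[k + 1]
        kind = node[0]
        if kind in ("S", "K"):
            lo, hi = _node_bounds(node)
            lo = max(lo, span - tail_max)
            hi = min(hi, span - tail_min)
            key = node[1].id if kind == "S" else f"{node[1].id}.{node[2]}p"
            pat = node[1].pattern if kind == "S" else None
            for l in range(lo, hi + 1):
                if pat is not None and not matches_pattern(self.s[i : i + l], pat):
                    continue
                for rest in self._gen_exact(forest, k + 1, i + l, j):
                    yield ((key, i, i + l),) + rest
        else:
            h, inner = node[1], node[2]
            imin, imax = inner.suffix_min[0], inner.suffix_max[0]
            e_lo = max(i + 2 * h.min_len + imin, j - tail_max)
            e_hi = min(i + 2 * h.max_len + imax, j - tail_min)
            for e in self._helix_ends(i, h, e_lo, e_hi):
                r = self._run(i, e - 1, h.allowed_pairs, h.max_len)
                L_lo = max(h.min_len, -((i + imax - e) // 2))
                L_hi = min(r, h.max_len, (e - i - imin) // 2)
                for L in range(L_lo, L_hi + 1):
                    if not self._exists(inner, 0, i + L, e - L):
                        continue
                    own = ((f"{h.id}.5p", i, i + L), (f"{h.id}.3p", e - L, e))
                    for inner_sol in self._gen_exact(inner, 0, i + L, e - L):
                        for rest in self._gen_exact(forest, k + 1, e, j):
                            yield own + inner_sol + rest

    def _gen_open(self, k: int, i: int) -> Iterator[tuple[tuple, int]]:
        """Open-ended top-level walk: yield (assignment, end) pairs."""
        forest = self.forest
        if k == len(forest.nodes):
            yield (), i
            return
        node = forest.nodes[k]
        tail_min = forest.suffix_min[k + 1]
        room = self.n - i - tail_min
        kind = node[0]
        if kind in ("S", "K"):
            lo, hi = _node_bounds(node)
            hi = min(hi, room)
            key = node[1].id if kind == "S" else f"{node[1].id}.{node[2]}p"
            pat = node[1].pattern if kind == "S" else None
            for l in range(lo, hi + 1):
                if pat is not None and not matches_pattern(self.s[i : i + l], pat):
                    continue
                for rest, end in self._gen_open(k + 1, i + l):
                    yield ((key, i, i + l),) + rest, end
        else:
            h, inner = node[1], node[2]
            imin, imax = inner.suffix_min[0], inner.suffix_max[0]
            e_lo = i + 2 * h.min_len + imin
            e_hi = min(i + 2 * h.max_len + imax, i + room)
            for e in self._helix_ends(i, h, e_lo, e_hi):
                r = self._run(i, e - 1, h.allowed_pairs, h.max_len)
                L_lo = max(h.min_len, -((i + imax - e) // 2))
                L_hi = min(r, h.max_len, (e - i - imin) // 2)
                for L in range(L_lo, L_hi + 1):
                    if not self._exists(inner, 0, i + L, e - L):
                        continue
                    own = ((f"{h.id}.5p", i, i + L), (f"{h.id}.3p", e - L, e))
                    for inner_sol in self._gen_exact(inner, 0, i + L, e - L):
                        for rest, end in self._gen_open(k + 1, e):
                            yield own + inner_sol + rest, end

    def solutions_at(self, anchor: int, limit: int) -> list[tuple[tuple, int]]:
        out = []
        for sol, end in self._gen_open(0, anchor):
            out.append((sol, end))
            if len(out) >= limit:
                break
        return out

    # -- exact minimum-energy placement (DP over the descriptor tree) -------
    #
    # The energy of a placement decomposes over helix subtrees: each helix
    # contributes its internal stacking plus the penalty of the loop its
    # innermost pair closes.  That loop term depends only on the layout of
    # the helix's immediate interior, and the coaxial-stack special case
    # (single child, no gaps) only on residues at interval boundaries — so
    # a minimum over placements is computable state-by-state, without
    # enumerating the (often astronomically many) satisfying assignments.

    def _closing_term(self, a: int, b: int, extents: tuple) -> float:
        """Penalty of the loop [a, b) closed by the enclosing pair (a-1, b)."""
        model = self.model
        if not extents:
            return model.hairpin(b - a)
        if len(extents) == 1:
            (xa, xb), = extents
            left, right = xa - a, b - xb
            if left == 0 and right == 0:
                s = self.s
                return model.stacks.get((s[a - 1] + s[b], s[a] + s[b - 1]), 0.0)
            if left == 0 or right == 0:
                return model.bulge(left + right)
            return model.interior(left + right)
        unpaired = (b - a) - sum(xb - xa for xa, xb in extents)
        return self.model.multiloop(unpaired, len(extents))

    def _stack_sum(self, a: int, b: int, L: int) -> float:
        s = self.s
        stacks = self.model.stacks
        total = 0.0
        for t in range(L - 1):
            total += stacks.get(
                (s[a + t] + s[b - 1 - t], s[a + t + 1] + s[b - 2 - t]), 0.0
            )
        return total

    def _helix_L_range(self, node, a: int, b: int) -> range:
        h, inner = node[1], node[2]
        imin, imax = inner.suffix_min[0], inner.suffix_max[0]
        span = b - a
        r = self._run(a, b - 1, h.allowed_pairs, h.max_len)
        L_lo = max(h.min_len, -((imax - span) // 2))  # ceil((span-imax)/2)
        L_hi = min(r, h.max_len, (span - imin) // 2)
        return range(L_lo, L_hi + 1)

    def _Hmin(self, node, a: int, b: int) -> float:
        """Min energy of one helix subtree occupying exactly [a, b)."""
        key = ("H", node[2].key, a, b)
        hit = self.exists_memo.get(key)
        if hit is not None:
            return hit
        inner = node[2]
        best = float("inf")
        for L in self._helix_L_range(node, a, b):
            c = self._Cmin(inner, a + L, b - L)
            if c == float("inf"):
                continue
            best = min(best, self._stack_sum(a, b, L) + c)
        self.exists_memo[key] = best
        return best

    def _Cmin(self, forest: _Forest, a: int, b: int) -> float:
        """Min energy of a helix interior: forest on [a, b) + closing term."""
        key = ("C", forest.key, a, b)
        hit = self.exists_memo.get(key)
        if hit is not None:
            return hit
        nodes = forest.nodes

        def go(k: int, pos: int, extents: tuple) -> float:
            if k == len(nodes):
                return self._closing_term(a, b, extents) if pos == b else float("inf")
            node = nodes[k]
            tail_min = forest.suffix_min[k + 1]
            tail_max = forest.suffix_max[k + 1]
            span = b - pos
            best = float("inf")
            if node[0] in ("S", "K"):
                lo, hi = _node_bounds(node)
                lo = max(lo, span - tail_max)
                hi = min(hi, span - tail_min)
                pat = node[1].pattern if node[0] == "S" else None
                for l in range(lo, hi + 1):
                    if pat is not None and not matches_pattern(
                        self.s[pos : pos + l], pat
                    ):
                        continue
                    best = min(best, go(k + 1, pos + l, extents))
            else:
                h, inner = node[1], node[2]
                imin, imax = inner.suffix_min[0], inner.suffix_max[0]
                e_lo = max(pos + 2 * h.min_len + imin, b - tail_max)
                e_hi = min(pos + 2 * h.max_len + imax, b - tail_min)
                for e in self._helix_ends(pos, h, e_lo, e_hi):
                    v = self._Hmin(node, pos, e)
                    if v == float("inf"):
                        continue
                    rest = go(k + 1, e, extents + ((pos, e),))
                    if rest != float("inf"):
                        best = min(best, v + rest)
            return best

        result = go(0, a, ())
        self.exists_memo[key] = result
        return result

    def best_at(self, anchor: int) -> Optional[tuple[tuple, int, float]]:
        """Minimum-energy placement starting at ``anchor``: (sol, end, energy).

        Energy ties break toward longer helices, then smaller element
        lengths, greedily 5'→3' during reconstruction.
        """
        forest = self.forest
        nodes = forest.nodes

        def go(k: int, pos: int):
            # returns (value, list-of-(node_k, choice)) or None; open-ended
            if k == len(nodes):
                return 0.0, []
            node = nodes[k]
            tail_min = forest.suffix_min[k + 1]
            room = self.n - pos - tail_min
            best = None
            if node[0] in ("S", "K"):
                lo, hi = _node_bounds(node)
                hi = min(hi, room)
                pat = node[1].pattern if node[0] == "S" else None
                for l in range(lo, hi + 1):
                    if pat is not None and not matches_pattern(
                        self.s[pos : pos + l], pat
                    ):
                        continue
                    rest = go(k + 1, pos + l)
                    if rest is not None and (best is None or rest[0] < best[0]):
                        best = (rest[0], [(k, l)] + rest[1])
            else:
                h, inner = node[1], node[2]
                imin, imax = inner.suffix_min[0], inner.suffix_max[0]
                e_lo = pos + 2 * h.min_len + imin
                e_hi = min(pos + 2 * h.max_len + imax, pos + room)
                for e in self._helix_ends(pos, h, e_lo, e_hi):
                    v = self._Hmin(node, pos, e)
                    if v == float("inf"):
                        continue
                    rest = go(k + 1, e)
                    if rest is not None and (
                        best is None or v + rest[0] < best[0]
                    ):
                        best = (v + rest[0], [(k, e)] + rest[1])
            return best

        top = go(0, anchor)
        if top is None:
            return None
        value, choices = top
        spans: list[tuple] = []
        pos = anchor
        for k, choice in choices:
            node = nodes[k]
            if node[0] in ("S", "K"):
                key = (
                    node[1].id if node[0] == "S" else f"{node[1].id}.{node[2]}p"
                )
                spans.append((key, pos, pos + choice))
                pos += choice
            else:
                target = self._Hmin(node, pos, choice)
                spans.extend(self._H_rec(node, pos, choice, target))
                pos = choice
        return tuple(spans), pos, value

    def _H_rec(self, node, a: int, b: int, target: float) -> list[tuple]:
        h, inner = node[1], node[2]
        for L in sorted(self._helix_L_range(node, a, b), reverse=True):
            c = self._Cmin(inner, a + L, b - L)
            if c == float("inf"):
                continue
            if abs(self._stack_sum(a, b, L) + c - target) < 1e-9:
                own = [(f"{h.id}.5p", a, a + L), (f"{h.id}.3p", b - L, b)]
                return own + self._C_rec(inner, a + L, b - L, c)
        raise AssertionError("helix DP reconstruction failed")

    def _C_rec(self, forest: _Forest, a: int, b: int, target: float) -> list[tuple]:
        nodes = forest.nodes

        def go(k: int, pos: int, extents: tuple, remaining: float):
            if k == len(nodes):
                if pos == b and abs(
                    self._closing_term(a, b, extents) - remaining
                ) < 1e-9:
                    return []
                return None
            node = nodes[k]
            tail_min = forest.suffix_min[k + 1]
            tail_max = forest.suffix_max[k + 1]
            span = b - pos
            if node[0] in ("S", "K"):
                lo, hi = _node_bounds(node)
                lo = max(lo, span - tail_max)
                hi = min(hi, span - tail_min)
                key = (
                    node[1].id if node[0] == "S" else f"{node[1].id}.{node[2]}p"
                )
                pat = node[1].pattern if node[0] == "S" else None
                for l in range(lo, hi + 1):
                    if pat is not None and not matches_pattern(
                        self.s[pos : pos + l], pat
                    ):
                        continue
                    rest = go(k + 1, pos + l, extents, remaining)
                    if rest is not None:
                        return [(key, pos, pos + l)] + rest
            else:
                h, inner = node[1], node[2]
                imin, imax = inner.suffix_min[0], inner.suffix_max[0]
                e_lo = max(pos + 2 * h.min_len + imin, b - tail_max)
                e_hi = min(pos + 2 * h.max_len + imax, b - tail_min)
                for e in self._helix_ends(pos, h, e_lo, e_hi):
                    v = self._Hmin(node, pos, e)
                    if v == float("inf"):
                        continue
                    rest = go(k + 1, e, extents + ((pos, e),), remaining - v)
                    if rest is not None:
                        return self._H_rec(node, pos, e, v) + rest
            return None

        out = go(0, a, (), target)
        if out is None:
            raise AssertionError("interior DP reconstruction failed")
        return out

    # -- fast energy over span assignments ---------------------------------
    def sol_energy(self, sol: tuple) -> float:
        """Energy of an assignment, identical to evaluating its dot-bracket.

        Computed directly from helix spans: stacking terms along each
        helix, the loop penalty each helix closes, and coaxial stacks
        where a helix abuts its single child with no gap.
        """
        model = self.model
        s = self.s
        stacks = model.stacks
        spans = {key: (a, b) for key, a, b in sol}
        helices = []  # (a5, b5, a3, b3) for non-pseudoknot helices
        for el in self.d.elements:
            if (
                isinstance(el, HelixSide)
                and el.side == "5"
                and not el.helix.pseudoknot
            ):
                a5, b5 = spans[f"{el.id}.5p"]
                a3, b3 = spans[f"{el.id}.3p"]
                helices.append((a5, b5, a3, b3))
        energy = 0.0
        extents = sorted((a5, b3) for a5, b5, a3, b3 in helices)
        for a5, b5, a3, b3 in helices:
            L = b5 - a5
            for t in range(L - 1):
                outer = s[a5 + t] + s[b3 - 1 - t]
                inner_p = s[a5 + t + 1] + s[b3 - 2 - t]
                energy += stacks.get((outer, inner_p), 0.0)
            # loop closed by the innermost pair: region [b5, a3)
            children = [
                (xa, xb) for xa, xb in extents if b5 <= xa and xb <= a3
            ]
            # keep only top-level children (not nested inside one another)
            top = [
                (xa, xb)
                for xa, xb in children
                if not any(
                    (ya < xa and xb <= yb) or (ya <= xa and xb < yb)
                    for ya, yb in children
                    if (ya, yb) != (xa, xb)
                )
            ]
            if not top:
                energy += model.hairpin(a3 - b5)
            elif len(top) == 1:
                (xa, xb), = top
                left, right = xa - b5, a3 - xb
                if left == 0 and right == 0:
                    outer = s[b5 - 1] + s[a3]
                    inner_p = s[xa] + s[xb - 1]
                    energy += stacks.get((outer, inner_p), 0.0)
                elif left == 0 or right == 0:
                    energy += model.bulge(left + right)
                else:
                    energy += model.interior(left + right)
            else:
                unpaired = (a3 - b5) - sum(xb - xa for xa, xb in top)
                energy += model.multiloop(unpaired, len(top))
        return energy


# ---------------------------------------------------------------------------
# public API

#: Enumeration cap per anchor: satisfying assignments beyond this many are
#: not examined when choosing the representative fold.
MAX_SOLUTIONS_PER_ANCHOR = 2000


def _anchors(seq: NucleotideSequence, d: Descriptor) -> list[int]:
    """Candidate start positions.

    When the first element is a fixed-length patterned strand (the usual
    5' splice-site gate), anchors are exactly the pattern's occurrence
    positions; otherwise every position with room for ``min_span`` is a
    candidate.
    """
    n = len(seq)
    lo = min_span(d)
    last = n - lo
    if last < 0:
        return []
    first = d.elements[0]
    if (
        isinstance(first, StrandElement)
        and first.pattern is not None
        and first.min_len == first.max_len
        and all(len(a) == first.min_len for a in first.pattern)
    ):
        w = first.min_len
        s = seq.residues
        return [
            i
            for i in range(last + 1)
            if matches_pattern(s[i : i + w], first.pattern)
        ]
    return list(range(last + 1))


def _sol_to_match(
    eng: _Engine, sol: tuple, start: int, end: int, energy: Optional[float] = None
) -> StructureMatch:
    spans = {key: (a, b) for key, a, b in sol}
    d = eng.d
    db = _render(spans, start, end, d)
    if energy is None:
        energy = eng.sol_energy(sol)
    return StructureMatch(
        seq_id=eng.seq.id,
        start=start,
        end=end,
        element_spans=spans,
        dot_bracket=db,
        descriptor_name=d.name,
        intron_class=d.intron_class,
        energy=energy,
    )


def _render(spans: dict[str, tuple[int, int]], start: int, end: int, d: Descriptor) -> str:
    chars = ["."] * (end - start)
    for el in d.elements:
        if isinstance(el, HelixSide) and el.side == "5" and not el.helix.pseudoknot:
            a5, b5 = spans[f"{el.id}.5p"]
            a3, b3 = spans[f"{el.id}.3p"]
            for x in range(a5, b5):
                chars[x - start] = "("
            for x in range(a3, b3):
                chars[x - start] = ")"
    return "".join(chars)


def render_dot_bracket(m: StructureMatch) -> str:
    """Rebuild the dot-bracket string of a match from its element spans.

    Pseudoknot half-sides are rendered unpaired; pseudoknot pairings are
    tertiary annotations, not secondary structure.
    """
    chars = ["."] * (m.end - m.start)
    sides: dict[str, dict[str, tuple[int, int]]] = {}
    for key, span in m.element_spans.items():
        if key.endswith(".5p") or key.endswith(".3p"):
            hid, side = key[:-3], key[-2:]
            sides.setdefault(hid, {})[side] = span
    for hid, two in sides.items():
        if set(two) != {"5p", "3p"}:
            continue
        (a5, b5), (a3, b3) = two["5p"], two["3p"]
        if b5 <= a3:  # nested helix; pseudoknot sides left unpaired
            for x in range(a5, b5):
                chars[x - m.start] = "("
            for x in range(a3, b3):
                chars[x - m.start] = ")"
    return "".join(chars)


def match_at(
    seq: NucleotideSequence,
    d: Descriptor,
    anchor: int,
    energy_model=None,
    _engine: Optional[_Engine] = None,
) -> Optional[StructureMatch]:
    """Best satisfying placement starting exactly at ``anchor``, or None.

    Among all satisfying length assignments at the anchor the minimum-energy
    fold is returned (computed exactly by dynamic programming); energy ties
    break toward longer helices, then smaller element lengths, greedily in
    5'→3' order during reconstruction.
    """
    eng = _engine or _Engine(seq, d, energy_model)
    if anchor < 0 or anchor + min_span(d) > len(seq):
        return None
    best = eng.best_at(anchor)
    if best is None:
        return None
    sol, end, energy = best
    return _sol_to_match(eng, sol, anchor, end, energy)


def scan(
    seq: NucleotideSequence,
    d: Descriptor,
    policy: str = "best_per_locus",
    energy_model=None,
    overlap_frac: float = 0.5,
) -> list[StructureMatch]:
    """Find placements of a descriptor on a sequence.

    policy="all" enumerates every satisfying placement at every anchor
    (up to the per-anchor cap); policy="best_per_anchor" keeps one match
    per anchor (the minimum-energy representative); policy=
    "best_per_locus" additionally reduces clusters of overlapping
    matches — intervals sharing at least ``overlap_frac`` of the
    shorter — to the lowest-energy member.
    """
    if policy not in ("all", "best_per_anchor", "best_per_locus"):
        raise ValueError(f"unknown policy {policy!r}")
    eng = _Engine(seq, d, energy_model)
    matches: list[StructureMatch] = []
    for anchor in _anchors(seq, d):
        if policy == "all":
            for sol, end in eng.solutions_at(anchor, MAX_SOLUTIONS_PER_ANCHOR):
                matches.append(_sol_to_match(eng, sol, anchor, end))
        else:
            m = match_at(seq, d, anchor, energy_model, _engine=eng)
            if m is not None:
                matches.append(m)
    if policy in ("all", "best_per_anchor"):
        return matches
    return _reduce_loci(matches, overlap_frac)


def _reduce_loci(matches: list[StructureMatch], overlap_frac: float) -> list[StructureMatch]:
    kept: list[StructureMatch] = []
    for m in sorted(matches, key=lambda m: (m.energy, m.start)):
        clash = False
        for other in kept:
            ov = min(m.end, other.end) - max(m.start, other.start)
            if ov > 0 and ov >= overlap_frac * min(
                m.end - m.start, other.end - other.start
            ):
                clash = True
                break
        if not clash:
            kept.append(m)
    return sorted(kept, key=lambda m: m.start)


# ---------------------------------------------------------------------------
# independent re-validation (used by tests and the pipeline's final audit)

def validate_match(m: StructureMatch, seq: NucleotideSequence, d: Descriptor) -> list[str]:
    """Re-check every StructureMatch invariant from scratch.

    Deliberately independent of the matcher: walks the descriptor's
    element list against the recorded spans and the raw sequence.
    """
    diags: list[str] = []
    s = seq.residues
    pos = m.start
    for el in d.elements:
        if isinstance(el, HelixSide):
            key = f"{el.id}.{el.side}p"
            lo, hi = el.helix.min_len, el.helix.max_len
        else:
            key = el.id
            lo, hi = el.min_len, el.max_len
        if key not in m.element_spans:
            diags.append(f"{key}: span missing")
            return diags
        a, b = m.element_spans[key]
        if a != pos:
            diags.append(f"{key}: spans do not tile (expected start {pos}, got {a})")
        if not (lo <= b - a <= hi):
            diags.append(f"{key}: length {b - a} outside [{lo}, {hi}]")
        if isinstance(el, StrandElement):
            if not matches_pattern(s[a:b], el.pattern):
                diags.append(f"{key}: pattern mismatch on {s[a:b]!r}")
        pos = b
    if pos != m.end:
        diags.append(f"element spans end at {pos}, match ends at {m.end}")
    # helix side lengths equal and paired under allowed_pairs
    for h in d.helices():
        k5, k3 = f"{h.id}.5p", f"{h.id}.3p"
        if k5 not in m.element_spans or k3 not in m.element_spans:
            continue
        (a5, b5), (a3, b3) = m.element_spans[k5], m.element_spans[k3]
        if b5 - a5 != b3 - a3:
            diags.append(f"helix {h.id}: unequal side lengths")
            continue
        if h.pseudoknot:
            continue
        for t in range(b5 - a5):
            pair = s[a5 + t] + s[b3 - 1 - t]
            if pair not in h.allowed_pairs:
                diags.append(f"helix {h.id}: disallowed pair {pair} at offset {t}")
    # dot-bracket balanced and consistent with helix spans
    db = m.dot_bracket
    if len(db) != m.end - m.start:
        diags.append("dot-bracket length mismatch")
    depth = 0
    for c in db:
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                diags.append("dot-bracket unbalanced")
                break
    if depth != 0:
        diags.append("dot-bracket unbalanced")
    if db != render_dot_bracket(m):
        diags.append("dot-bracket inconsistent with element spans")
    return diags
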