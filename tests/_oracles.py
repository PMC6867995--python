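"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: exhaustive enumeration and
textbook recursions, sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from introscan.descriptor import (
    Descriptor,
    HelixSide,
    IUPAC,
    StrandElement,
)

WC_GU = {"AU", "UA", "GC", "CG", "GU", "UG"}


# ---------------------------------------------------------------------------
# descriptor placement enumeration

def brute_force_scan(seq: str, d: Descriptor) -> set:
    """Every satisfying placement, as frozensets of (key, start, end).

    Enumerates the full cross product of element lengths at every anchor
    and checks each candidate placement directly against the sequence.
    """
    n = len(seq)
    var_ids: list[str] = []
    ranges: list[range] = []
    seen = set()
    for el in d.elements:
        if isinstance(el, HelixSide):
            if el.id not in seen:
                seen.add(el.id)
                var_ids.append(el.id)
                ranges.append(range(el.helix.min_len, el.helix.max_len + 1))
        else:
            var_ids.append(el.id)
            ranges.append(range(el.min_len, el.max_len + 1))
    results = set()
    for anchor in range(n + 1):
        for combo in itertools.product(*ranges):
            lengths = dict(zip(var_ids, combo))
            pos = anchor
            spans = []
            for el in d.elements:
                L = lengths[el.id]
                key = (
                    f"{el.id}.{el.side}p" if isinstance(el, HelixSide) else el.id
                )
                spans.append((key, pos, pos + L))
                pos += L
            if pos > n:
                continue
            if _placement_ok(seq, d, dict((k, (a, b)) for k, a, b in spans)):
                results.add(frozenset(spans))
    return results


def _placement_ok(seq: str, d: Descriptor, spans: dict) -> bool:
    for el in d.elements:
        if isinstance(el, StrandElement):
            a, b = spans[el.id]
            if not _pattern_ok(seq[a:b], el.pattern):
                return False
    for h in d.helices():
        (a5, b5) = spans[f"{h.id}.5p"]
        (a3, b3) = spans[f"{h.id}.3p"]
        if h.pseudoknot:
            continue
        for t in range(b5 - a5):
            if seq[a5 + t] + seq[b3 - 1 - t] not in h.allowed_pairs:
                return False
    return True


def _pattern_ok(residues: str, pattern) -> bool:
    if pattern is None:
        return True
    for alt in pattern:
        if len(alt) > len(residues):
            continue
        ok = True
        for s, p in zip(residues, alt):
            if s == "N":
                if p != "N":
                    ok = False
                    break
            elif s not in IUPAC[p]:
                ok = False
                break
        if ok:
            return True
    return False


# ---------------------------------------------------------------------------
# tree edit distance (classic forest recursion on nested tuples)

def parse_tree(db: str):
    """Dot-bracket to nested ('label', (children...)) tuples with an R root."""
    stack = [["R", []]]
    for c in db:
        if c == "(":
            stack.append(["P", []])
        elif c == ")":
            lab, kids = stack.pop()
            stack[-1][1].append((lab, tuple(kids)))
        elif c == ".":
            stack[-1][1].append(("U", ()))
        else:
            raise ValueError(c)
    assert len(stack) == 1
    lab, kids = stack[0]
    return (lab, tuple(kids))


def ted_oracle(a: str, b: str, scheme: str = "unit") -> int:
    if scheme == "unit":
        indel = {"U": 1, "P": 1, "R": 1}
        rel = lambda x, y: 0 if x == y else 1
    elif scheme == "vienna":
        indel = {"U": 1, "P": 2, "R": 1}
        rel = lambda x, y: 0 if x == y else 1
    else:
        raise ValueError(scheme)

    def tree_cost(t) -> int:
        return indel[t[0]] + sum(tree_cost(c) for c in t[1])

    @lru_cache(maxsize=None)
    def fd(F1, F2) -> int:
        if not F1 and not F2:
            return 0
        if not F1:
            return sum(tree_cost(t) for t in F2)
        if not F2:
            return sum(tree_cost(t) for t in F1)
        v, w = F1[-1], F2[-1]
        return min(
            fd(F1[:-1] + v[1], F2) + indel[v[0]],
            fd(F1, F2[:-1] + w[1]) + indel[w[0]],
            fd(F1[:-1], F2[:-1]) + fd(v[1], w[1]) + rel(v[0], w[0]),
        )

    ta, tb = parse_tree(a), parse_tree(b)
    return fd((ta,), (tb,))


# ---------------------------------------------------------------------------
# ungapped antiparallel complementarity

def complementarity_oracle(a: str, b: str, min_pairs: int) -> int:
    """Longest contiguous antiparallel run over all (start-a, start-b) pairs."""
    best = 0
    for ia in range(len(a)):
        for ib in range(len(b)):
            t = 0
            while ia + t < len(a) and ib - t >= 0 and a[ia + t] + b[ib - t] in WC_GU:
                t += 1
            best = max(best, t)
    return best


# ---------------------------------------------------------------------------
# peptide identity sliding window

def identity_oracle(frames: list[str], block: str) -> float:
    best = 0.0
    L = len(block)
    for aa in frames:
        for i in range(len(aa) - L + 1):
            m = sum(x == y for x, y in zip(aa[i : i + L], block))
            best = max(best, 100.0 * m / L)
    return best


# ---------------------------------------------------------------------------
# random structures / descriptors

def random_dot_bracket(rng, length: int) -> str:
    """Uniform-ish random balanced structure of exactly ``length`` chars."""
    out = []
    depth = 0
    for k in range(length):
        remaining = length - k
        choices = []
        if depth > 0:
            choices.append(")")
        if remaining > depth + 1:
            choices.append("(")
        choices.append(".")
        if remaining == depth:
            c = ")"
        else:
            c = choices[int(rng.integers(len(choices)))]
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
        out.append(c)
    while depth > 0:  # shouldn't happen, but stay safe
        out.append(")")
        depth -= 1
    return "".join(out[:length]) if depth == 0 else random_dot_bracket(rng, length)
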