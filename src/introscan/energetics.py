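"""Free-energy evaluation and stability Z-scores.

The shipped energy model is a reduced nearest-neighbor scheme: a 36-entry
stacking table over the six allowed pair classes (Watson–Crick plus G·U)
and Jacobson–Stockmayer-style logarithmic loop penalties.  Absolute
energies are therefore not comparable to a full Turner-parameter
evaluator, but the stability filter is defined on the Z-score — the
structure's energy standardized against dinucleotide-preserving shuffles
of its own window — which is robust to the energy scale.  A structure
passes the filter when Z < −1.48, strictly.

An alternative evaluator with the same call signature can be passed
anywhere an :class:`EnergyModel` is accepted (``evaluate`` hook), leaving
the filter logic unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Optional

import numpy as np

from .nullsim import dinucleotide_shuffle

__all__ = [
    "EnergyModel",
    "ZScoreResult",
    "EnergyEvalError",
    "DegenerateNullError",
    "evaluate_energy",
    "z_score",
    "stability_filter",
    "default_model",
    "Z_THRESHOLD",
]

#: The stability criterion: structures pass only when Z < −1.48 (strict).
Z_THRESHOLD = -1.48

_RT = 0.616  # kcal/mol at 37 C


class EnergyEvalError(ValueError):
    """A paired position holds a pair outside the model's pair classes."""


class DegenerateNullError(ValueError):
    """The shuffle null has zero variance; no Z-score is defined."""


def _hairpin(n: int) -> float:
    if n >= 3:
        return 5.4 + 1.75 * _RT * math.log(n / 3)
    return 7.0 + (3 - n)  # sub-3-nt loops: heavily penalized, never stabilizing


def _bulge(n: int) -> float:
    return 3.8 + 1.75 * _RT * math.log(max(n, 1))


def _interior(n: int) -> float:
    return 1.7 + 1.75 * _RT * math.log(max(n, 2) / 2)


def _multiloop(unpaired: int, branches: int) -> float:
    return 3.4 + 0.4 * branches + 0.1 * unpaired


@dataclass(frozen=True)
class EnergyModel:
    """Stacking table plus loop penalty functions, all in kcal/mol."""

    stacks: dict[tuple[str, str], float]
    hairpin: Callable[[int], float] = _hairpin
    bulge: Callable[[int], float] = _bulge
    interior: Callable[[int], float] = _interior
    multiloop: Callable[[int, int], float] = _multiloop
    name: str = "reduced-nn"

    @property
    def allowed_pairs(self) -> frozenset[str]:
        out = set()
        for p, q in self.stacks:
            out.add(p)
            out.add(q)
        return frozenset(out)


_default: Optional[EnergyModel] = None


def load_model(path_or_text: str, name: str = "custom") -> EnergyModel:
    """Load a stacking table (``pair5' pair3' dG`` per line, kcal/mol)."""
    stacks: dict[tuple[str, str], float] = {}
    for line in path_or_text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        p, q, v = line.split()
        stacks[(p.upper(), q.upper())] = float(v)
    if not stacks:
        raise ValueError("empty stacking table")
    for v in stacks.values():
        if not math.isfinite(v):
            raise ValueError("non-finite stacking term")
    return EnergyModel(stacks=stacks, name=name)


def default_model() -> EnergyModel:
    global _default
    if _default is None:
        text = resources.files("introscan").joinpath(
            "data/stack_energies.tsv"
        ).read_text()
        _default = load_model(text, name="reduced-nn/shipped")
    return _default


def _pair_table(db: str) -> list[int]:
    pt = [-1] * len(db)
    stack = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"illegal dot-bracket character {c!r} at {i}")
    if stack:
        raise ValueError(f"unbalanced dot-bracket: unclosed '(' at {stack[-1]}")
    return pt


def evaluate_energy(
    seq_window: str,
    dot_bracket: str,
    model: Optional[EnergyModel] = None,
    on_disallowed: str = "raise",
) -> float:
    """Sum stacking terms and loop penalties for a fixed structure.

    With ``on_disallowed="skip"`` (used when re-evaluating the same
    structure on shuffled sequence) a disallowed pair contributes no
    stacking stabilization — the adjacent stack terms are simply dropped —
    while loop penalties apply as usual.
    """
    model = model or default_model()
    seq = seq_window.upper().replace("T", "U")
    if len(seq) != len(dot_bracket):
        raise ValueError("sequence and structure lengths differ")
    pt = _pair_table(dot_bracket)
    allowed = model.allowed_pairs

    def pair(i: int) -> str:
        return seq[i] + seq[pt[i]]

    if on_disallowed == "raise":
        for i, j in enumerate(pt):
            if j > i and pair(i) not in allowed:
                raise EnergyEvalError(
                    f"disallowed pair {pair(i)} at positions {i},{j}"
                )
    elif on_disallowed != "skip":
        raise ValueError("on_disallowed must be 'raise' or 'skip'")

    energy = 0.0
    for i, j in enumerate(pt):
        if j <= i:
            continue
        # children directly enclosed by (i, j)
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if pt[k] > k:
                children.append((k, pt[k]))
                k = pt[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            energy += model.hairpin(j - i - 1)
        elif len(children) == 1:
            a, b = children[0]
            if a == i + 1 and b == j - 1:
                outer, inner = seq[i] + seq[j], seq[a] + seq[b]
                if outer in allowed and inner in allowed:
                    energy += model.stacks.get((outer, inner), 0.0)
            else:
                left, right = a - i - 1, j - b - 1
                if left == 0 or right == 0:
                    energy += model.bulge(left + right)
                else:
                    energy += model.interior(left + right)
        else:
            energy += model.multiloop(unpaired, len(children))
    return energy


@dataclass(frozen=True)
class ZScoreResult:
    """Energy of a structure against its dinucleotide-shuffle null."""

    energy: float
    null_mean: float
    null_sd: float
    n_shuffles: int
    z: float


def z_score(
    seq_window: str,
    dot_bracket: str,
    model: Optional[EnergyModel] = None,
    n_shuffles: int = 100,
    rng_seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ZScoreResult:
    """Standardize a structure's energy against Euler-shuffle nulls.

    The *same* dot-bracket is re-evaluated on ``n_shuffles``
    dinucleotide-preserving shuffles of the window; pairs broken by a
    shuffle contribute no stacking term (they are never an error here).
    Raises :class:`DegenerateNullError` when the null has zero spread —
    e.g. when the window is its own only valid shuffle.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if len(seq_window) < 2:
        raise ValueError("window too short to shuffle")
    model = model or default_model()
    rng = rng if rng is not None else np.random.default_rng(rng_seed)
    energy = evaluate_energy(seq_window, dot_bracket, model, on_disallowed="skip")
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuf = dinucleotide_shuffle(seq_window, rng=rng)
        null[k] = evaluate_energy(shuf, dot_bracket, model, on_disallowed="skip")
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd <= 1e-9 * max(1.0, abs(mean)):
        raise DegenerateNullError(
            "shuffle null has zero variance; Z-score undefined"
        )
    return ZScoreResult(
        energy=energy,
        null_mean=mean,
        null_sd=sd,
        n_shuffles=n_shuffles,
        z=(energy - mean) / sd,
    )


def stability_filter(results, threshold: float = Z_THRESHOLD) -> list[bool]:
    """Apply the strict Z < threshold criterion to each result."""
    return [r.z < threshold for r in results]
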