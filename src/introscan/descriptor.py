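"""Descriptor language for RNA secondary-structure models.

A *descriptor* encodes a structural model of an RNA element — here, the DI
domain of group II introns — as an ordered 5'→3' arrangement of helix
half-sides and single-stranded elements.  Each helix carries a base-pair
length range and a set of allowed pair classes (Watson–Crick plus G·U
wobble by default); each strand carries a nucleotide length range, an
optional IUPAC pattern anchored at its 5' end, and an optional functional
role tag (5' splice site, EBS/IBS anchor, tertiary-interaction partner).

Descriptors are written in a small YAML dialect: ``elements`` lists the
half-sides and strands in sequence order, a helix contributing a
``helix5`` entry (which carries its parameters) and a matching ``helix3``
entry.  Nesting is implied by side order, exactly as brackets imply
nesting in dot-bracket notation; helices flagged ``pseudoknot: true`` are
exempt from the nesting check and are handled downstream as
complementarity filters, never by the matcher.

The canonical IIA and IIB DI-domain models ship with the package and are
loaded with :func:`load_model`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Union

import yaml

__all__ = [
    "IUPAC",
    "WATSON_CRICK_WOBBLE",
    "HelixElement",
    "StrandElement",
    "HelixSide",
    "Descriptor",
    "DescriptorError",
    "DescriptorSyntaxError",
    "TopologyError",
    "RangeError",
    "parse_descriptor",
    "serialize_descriptor",
    "validate_topology",
    "min_span",
    "max_span",
    "load_model",
    "list_models",
]

#: IUPAC nucleotide codes over the RNA alphabet.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

#: Watson–Crick pairs plus the G·U wobble — the default pair universe
#: ("non-canonical base pairs prohibited, except G-U").
WATSON_CRICK_WOBBLE: frozenset[str] = frozenset(
    {"AU", "UA", "GC", "CG", "GU", "UG"}
)

ROLES = {
    "SPLICE5",
    "EBS1",
    "EBS2",
    "IBS1",
    "IBS2",
    "ALPHA",
    "ALPHA_P",
    "BETA",
    "BETA_P",
    "KAPPA",
    "EPSILON",
    "EPSILON_P",
    "NONE",
}

INTRON_CLASSES = {"IIA", "IIB", "CUSTOM"}


class DescriptorError(ValueError):
    """Base class for descriptor parsing/validation failures."""


class DescriptorSyntaxError(DescriptorError):
    """Malformed descriptor document."""


class TopologyError(DescriptorError):
    """Helix sides unbalanced, misordered, or illegally crossing."""


class RangeError(DescriptorError):
    """A length range violates min <= max or a sign constraint."""


@dataclass(frozen=True)
class HelixElement:
    """A helix: two antiparallel strands of equal length that base-pair."""

    id: str
    min_len: int
    max_len: int
    allowed_pairs: frozenset[str] = WATSON_CRICK_WOBBLE
    pseudoknot: bool = False


@dataclass(frozen=True)
class StrandElement:
    """A single-stranded element with an optional anchored pattern and role.

    ``pattern`` is either a single IUPAC string or a tuple of alternative
    IUPAC strings (any one may match), anchored at the element's 5' end.
    """

    id: str
    min_len: int
    max_len: int
    pattern: Optional[tuple[str, ...]] = None
    role: str = "NONE"


@dataclass(frozen=True)
class HelixSide:
    """One half-side of a helix as it appears along the sequence."""

    helix: HelixElement
    side: str  # "5" or "3"

    @property
    def id(self) -> str:
        return self.helix.id


Element = Union[StrandElement, HelixSide]


@dataclass(frozen=True)
class Descriptor:
    """An ordered arrangement of helix half-sides and strands.

    ``nesting`` maps each non-pseudoknot helix id to the id of the helix
    that immediately encloses it (``None`` at top level); it is derived
    from side order and cached here for convenience.
    """

    name: str
    intron_class: str
    elements: tuple[Element, ...]
    nesting: dict[str, Optional[str]] = field(default_factory=dict, compare=False)

    def helices(self) -> list[HelixElement]:
        seen, out = set(), []
        for el in self.elements:
            if isinstance(el, HelixSide) and el.id not in seen:
                seen.add(el.id)
                out.append(el.helix)
        return out

    def strands(self) -> list[StrandElement]:
        return [el for el in self.elements if isinstance(el, StrandElement)]

    def element_by_role(self, role: str) -> Optional[StrandElement]:
        for el in self.elements:
            if isinstance(el, StrandElement) and el.role == role:
                return el
        return None


def _compute_nesting(elements: Iterable[Element]) -> dict[str, Optional[str]]:
    nesting: dict[str, Optional[str]] = {}
    stack: list[str] = []
    for el in elements:
        if isinstance(el, HelixSide) and not el.helix.pseudoknot:
            if el.side == "5":
                nesting[el.id] = stack[-1] if stack else None
                stack.append(el.id)
            elif stack and stack[-1] == el.id:
                stack.pop()
    return nesting


def validate_topology(d: Descriptor) -> list[str]:
    """Return diagnostics for every violated descriptor invariant.

    An empty list means the descriptor is valid.  Diagnostics name the
    offending element; no exception is raised.
    """
    diags: list[str] = []
    sides: dict[str, list[str]] = {}
    order: dict[str, list[int]] = {}
    for i, el in enumerate(d.elements):
        if isinstance(el, HelixSide):
            sides.setdefault(el.id, []).append(el.side)
            order.setdefault(el.id, []).append(i)
    for hid, ss in sides.items():
        if sorted(ss) != ["3", "5"]:
            diags.append(f"helix {hid}: needs exactly one 5' and one 3' side, got {ss}")
        elif ss != ["5", "3"]:
            diags.append(f"helix {hid}: 3' side precedes 5' side")
    # nesting: non-pseudoknot sides must form a balanced, properly nested string
    stack: list[str] = []
    for el in d.elements:
        if isinstance(el, HelixSide) and not el.helix.pseudoknot:
            if el.side == "5":
                stack.append(el.id)
            else:
                if not stack:
                    continue  # already diagnosed as unbalanced above
                if stack[-1] != el.id:
                    if el.id in stack:
                        diags.append(
                            f"helix {el.id}: crosses helix {stack[-1]} "
                            "(undeclared pseudoknot)"
                        )
                        stack.remove(el.id)
                    # unbalanced cases diagnosed above
                else:
                    stack.pop()
    for el in d.elements:
        if isinstance(el, HelixSide):
            h = el.helix
            if el.side != "5":
                continue
            if not (1 <= h.min_len <= h.max_len):
                diags.append(
                    f"helix {h.id}: invalid range {h.min_len}..{h.max_len}"
                )
            if not h.allowed_pairs:
                diags.append(f"helix {h.id}: empty allowed_pairs")
            for p in h.allowed_pairs:
                if len(p) != 2 or any(c not in "ACGU" for c in p):
                    diags.append(f"helix {h.id}: bad pair class {p!r}")
        else:
            if not (0 <= el.min_len <= el.max_len):
                diags.append(
                    f"strand {el.id}: invalid range {el.min_len}..{el.max_len}"
                )
            if el.role not in ROLES:
                diags.append(f"strand {el.id}: unknown role {el.role!r}")
            if el.pattern is not None:
                for alt in el.pattern:
                    if len(alt) > el.max_len:
                        diags.append(
                            f"strand {el.id}: pattern {alt!r} longer than max_len"
                        )
                    for c in alt:
                        if c not in IUPAC:
                            diags.append(
                                f"strand {el.id}: bad IUPAC code {c!r} in pattern"
                            )
    if d.intron_class not in INTRON_CLASSES:
        diags.append(f"descriptor {d.name}: unknown intron_class {d.intron_class!r}")
    ids = [el.id for el in d.elements if isinstance(el, StrandElement)]
    dup = {x for x in ids if ids.count(x) > 1}
    for x in sorted(dup):
        diags.append(f"strand {x}: duplicate element id")
    return diags


def min_span(d: Descriptor) -> int:
    """Minimum number of nucleotides a placement of ``d`` can cover."""
    total = 0
    for el in d.elements:
        total += el.helix.min_len if isinstance(el, HelixSide) else el.min_len
    return total


def max_span(d: Descriptor) -> int:
    """Maximum number of nucleotides a placement of ``d`` can cover."""
    total = 0
    for el in d.elements:
        total += el.helix.max_len if isinstance(el, HelixSide) else el.max_len
    return total


# ---------------------------------------------------------------------------
# parsing / serialization

_ID_RE = re.compile(r"^[A-Za-z0-9_.\-]+$")


def _normalize_pattern(raw) -> Optional[tuple[str, ...]]:
    if raw is None:
        return None
    if isinstance(raw, str):
        raw = [raw]
    if not isinstance(raw, (list, tuple)) or not raw:
        raise DescriptorSyntaxError(f"pattern must be a string or list: {raw!r}")
    return tuple(str(a).upper().replace("T", "U") for a in raw)


def parse_descriptor(text: str) -> Descriptor:
    """Parse and validate a descriptor document.

    Raises :class:`DescriptorSyntaxError` on malformed documents,
    :class:`RangeError` when a length range has min > max, and
    :class:`TopologyError` when helix sides are unbalanced, misordered or
    cross without a pseudoknot flag.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough detail
        raise DescriptorSyntaxError(f"not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise DescriptorSyntaxError("descriptor document must be a mapping")
    for key in ("name", "elements"):
        if key not in doc:
            raise DescriptorSyntaxError(f"missing required key {key!r}")
    name = str(doc["name"])
    intron_class = str(doc.get("intron_class", "CUSTOM"))
    raw_elements = doc["elements"]
    if not isinstance(raw_elements, list) or not raw_elements:
        raise DescriptorSyntaxError("'elements' must be a non-empty list")

    helices: dict[str, HelixElement] = {}
    elements: list[Element] = []
    for pos, entry in enumerate(raw_elements):
        if not isinstance(entry, dict) or "type" not in entry:
            raise DescriptorSyntaxError(
                f"element {pos}: each entry needs a 'type' key"
            )
        etype = entry["type"]
        eid = str(entry.get("id", f"e{pos}"))
        if not _ID_RE.match(eid):
            raise DescriptorSyntaxError(f"element {pos}: bad id {eid!r}")
        if etype == "strand":
            lo, hi = int(entry.get("min", 0)), int(entry.get("max", 0))
            if lo < 0 or lo > hi:
                raise RangeError(f"strand {eid}: invalid range {lo}..{hi}")
            pattern = _normalize_pattern(entry.get("pattern"))
            if pattern:
                for alt in pattern:
                    if len(alt) > hi:
                        raise RangeError(
                            f"strand {eid}: pattern {alt!r} longer than max {hi}"
                        )
                    bad = [c for c in alt if c not in IUPAC]
                    if bad:
                        raise DescriptorSyntaxError(
                            f"strand {eid}: bad IUPAC code {bad[0]!r}"
                        )
            role = str(entry.get("role", "NONE")).upper()
            if role not in ROLES:
                raise DescriptorSyntaxError(f"strand {eid}: unknown role {role!r}")
            elements.append(StrandElement(eid, lo, hi, pattern, role))
        elif etype == "helix5":
            if eid in helices:
                raise TopologyError(f"helix {eid}: duplicate 5' side")
            lo, hi = int(entry.get("min", 1)), int(entry.get("max", 1))
            if lo < 1 or lo > hi:
                raise RangeError(f"helix {eid}: invalid range {lo}..{hi}")
            pairs = entry.get("pairs")
            if pairs is None:
                allowed = WATSON_CRICK_WOBBLE
            else:
                allowed = frozenset(
                    str(p).upper().replace("T", "U") for p in pairs
                )
                if not allowed or any(len(p) != 2 for p in allowed):
                    raise DescriptorSyntaxError(
                        f"helix {eid}: bad 'pairs' entry {pairs!r}"
                    )
            helix = HelixElement(
                eid, lo, hi, allowed, bool(entry.get("pseudoknot", False))
            )
            helices[eid] = helix
            elements.append(HelixSide(helix, "5"))
        elif etype == "helix3":
            if eid not in helices:
                raise TopologyError(
                    f"element {pos}: 3' side of helix {eid} before its 5' side"
                )
            elements.append(HelixSide(helices[eid], "3"))
        else:
            raise DescriptorSyntaxError(
                f"element {pos}: unknown type {etype!r} "
                "(expected strand/helix5/helix3)"
            )

    d = Descriptor(
        name=name,
        intron_class=intron_class,
        elements=tuple(elements),
        nesting=_compute_nesting(elements),
    )
    diags = validate_topology(d)
    if diags:
        raise TopologyError("; ".join(diags))
    return d


def serialize_descriptor(d: Descriptor) -> str:
    """Render a descriptor back to its YAML document form (lossless)."""
    entries = []
    for el in d.elements:
        if isinstance(el, HelixSide):
            if el.side == "5":
                e = {
                    "type": "helix5",
                    "id": el.id,
                    "min": el.helix.min_len,
                    "max": el.helix.max_len,
                }
                if el.helix.allowed_pairs != WATSON_CRICK_WOBBLE:
                    e["pairs"] = sorted(el.helix.allowed_pairs)
                if el.helix.pseudoknot:
                    e["pseudoknot"] = True
            else:
                e = {"type": "helix3", "id": el.id}
        else:
            e = {"type": "strand", "id": el.id, "min": el.min_len, "max": el.max_len}
            if el.pattern is not None:
                e["pattern"] = list(el.pattern)
            if el.role != "NONE":
                e["role"] = el.role
        entries.append(e)
    doc = {"name": d.name, "intron_class": d.intron_class, "elements": entries}
    return yaml.safe_dump(doc, sort_keys=False)


def load_model(name: str) -> Descriptor:
    """Load a shipped descriptor model (``IIA_DI`` or ``IIB_DI``) by name."""
    ref = resources.files("introscan").joinpath(f"data/models/{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"no shipped model {name!r}; available: {', '.join(list_models())}"
        ) from None
    return parse_descriptor(text)


def list_models() -> list[str]:
    """Names of the descriptor models shipped with the package."""
    root = resources.files("introscan").joinpath("data/models")
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def matches_pattern(residues: str, pattern: Optional[tuple[str, ...]]) -> bool:
    """True if ``residues`` satisfies the 5'-anchored IUPAC pattern.

    ``N`` in the sequence matches only an ``N`` pattern position; an
    element longer than the pattern is unconstrained past the pattern.
    """
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
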