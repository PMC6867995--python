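import pytest
from hypothesis import given, settings, strategies as st

from introscan.descriptor import (
    Descriptor,
    HelixElement,
    HelixSide,
    RangeError,
    StrandElement,
    TopologyError,
    WATSON_CRICK_WOBBLE,
    load_model,
    matches_pattern,
    max_span,
    min_span,
    parse_descriptor,
    serialize_descriptor,
    validate_topology,
)

MINIMAL = """
name: hp
elements:
  - {type: helix5, id: h1, min: 4, max: 6}
  - {type: strand, id: loop, min: 3, max: 8}
  - {type: helix3, id: h1}
"""


class TestParsing:
    def test_minimal_hairpin(self):
        d = parse_descriptor(MINIMAL)
        assert len(d.helices()) == 1
        assert len(d.strands()) == 1
        assert d.helices()[0].allowed_pairs == WATSON_CRICK_WOBBLE

    def test_shipped_iia_splice_site(self):
        d = load_model("IIA_DI")
        assert d.intron_class == "IIA"
        first = d.elements[0]
        assert isinstance(first, StrandElement)
        assert first.role == "SPLICE5"
        assert set(first.pattern) == {"GUGCG", "UUGCG", "GGGCG"}
        for site in ("GUGCG", "UUGCG", "GGGCG"):
            assert matches_pattern(site, first.pattern)
        assert not matches_pattern("AUGCG", first.pattern)
        assert not matches_pattern("UGGCG", first.pattern)

    def test_min_greater_than_max_is_range_error(self):
        bad = MINIMAL.replace("min: 4, max: 6", "min: 5, max: 3")
        with pytest.raises(RangeError):
            parse_descriptor(bad)

    def test_unbalanced_sides_topology_error(self):
        with pytest.raises(TopologyError):
            parse_descriptor(
                """
name: bad
elements:
  - {type: helix3, id: h1}
  - {type: strand, id: s, min: 1, max: 1}
"""
            )


class TestTopologyDiagnostics:
    def test_shipped_models_are_clean(self):
        assert validate_topology(load_model("IIA_DI")) == []
        assert validate_topology(load_model("IIB_DI")) == []

    def test_misordered_sides_one_diagnostic(self):
        h = HelixElement("h1", 2, 3)
        d = Descriptor(
            "bad", "CUSTOM",
            (HelixSide(h, "3"), StrandElement("s", 1, 2), HelixSide(h, "5")),
        )
        diags = validate_topology(d)
        assert len(diags) == 1 and "h1" in diags[0]

    def test_undeclared_crossing_is_pseudoknot_diagnostic(self):
        h1, h2 = HelixElement("h1", 1, 2), HelixElement("h2", 1, 2)
        d = Descriptor(
            "bad", "CUSTOM",
            (
                HelixSide(h1, "5"), HelixSide(h2, "5"),
                HelixSide(h1, "3"), HelixSide(h2, "3"),
            ),
        )
        diags = validate_topology(d)
        assert any("pseudoknot" in x for x in diags)

    def test_declared_pseudoknot_is_clean(self):
        h1 = HelixElement("h1", 1, 2)
        h2 = HelixElement("h2", 1, 2, pseudoknot=True)
        d = Descriptor(
            "pk", "CUSTOM",
            (
                HelixSide(h1, "5"), HelixSide(h2, "5"),
                HelixSide(h1, "3"), HelixSide(h2, "3"),
            ),
        )
        assert validate_topology(d) == []


class TestSpans:
    def test_hairpin_spans(self):
        d = parse_descriptor(MINIMAL)
        assert min_span(d) == 2 * 4 + 3 == 11
        assert max_span(d) == 2 * 6 + 8 == 20

    def test_zero_length_strand(self):
        d = parse_descriptor(
            "name: s0\nelements:\n  - {type: strand, id: s, min: 0, max: 5}\n"
        )
        assert min_span(d) == 0
        assert max_span(d) == 5

    def test_shipped_models_by_independent_summation(self):
        for name in ("IIA_DI", "IIB_DI"):
            d = load_model(name)
            lo = hi = 0
            for el in d.elements:
                if isinstance(el, HelixSide):
                    lo += el.helix.min_len
                    hi += el.helix.max_len
                else:
                    lo += el.min_len
                    hi += el.max_len
            assert min_span(d) == lo <= hi == max_span(d)


# -- serialization round trip -------------------------------------------------

@st.composite
def descriptors(draw):
    n_helices = draw(st.integers(0, 3))
    elements = []
    counter = [0]

    def strand():
        counter[0] += 1
        lo = draw(st.integers(0, 3))
        hi = lo + draw(st.integers(0, 4))
        role = draw(st.sampled_from(["NONE", "NONE", "EBS1", "KAPPA"]))
        pattern = None
        if hi >= 2 and draw(st.booleans()):
            pattern = (draw(st.text(alphabet="ACGUNRY", min_size=1, max_size=hi)),)
        return StrandElement(f"s{counter[0]}", lo, hi, pattern, role)

    def helix():
        counter[0] += 1
        lo = draw(st.integers(1, 4))
        hi = lo + draw(st.integers(0, 3))
        return HelixElement(f"h{counter[0]}", lo, hi)

    def emit(depth, remaining):
        if draw(st.booleans()):
            elements.append(strand())
        while remaining[0] > 0 and draw(st.booleans()):
            h = helix()
            remaining[0] -= 1
            elements.append(HelixSide(h, "5"))
            if depth < 2:
                emit(depth + 1, remaining)
            else:
                elements.append(strand())
            elements.append(HelixSide(h, "3"))
        elements.append(strand())

    emit(0, [n_helices])
    d = Descriptor("rt", "CUSTOM", tuple(elements))
    assert validate_topology(d) == []
    return d


@settings(max_examples=60, derandomize=True, deadline=None)
@given(descriptors())
def test_serialization_round_trip(d):
    """parse(serialize(d)) is structurally identical to d."""
    d2 = parse_descriptor(serialize_descriptor(d))
    assert d2.elements == d.elements
    assert d2.name == d.name and d2.intron_class == d.intron_class
    assert min_span(d2) == min_span(d) and max_span(d2) == max_span(d)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(descriptors())
def test_span_bounds_match_brute_force(d):
    """min/max span equal the extremes over enumerated length assignments."""
    import itertools

    seen = set()
    ranges = []
    for el in d.elements:
        if isinstance(el, HelixSide):
            if el.id in seen:
                continue
            seen.add(el.id)
            ranges.append(
                [2 * x for x in range(el.helix.min_len, el.helix.max_len + 1)]
            )
        else:
            ranges.append(list(range(el.min_len, el.max_len + 1)))
    size = 1
    for r in ranges:
        size *= len(r)
    if size > 50_000:  # enumeration is the oracle only at small sizes
        assert min_span(d) <= max_span(d)
        return
    totals = [sum(c) for c in itertools.product(*ranges)] or [0]
    assert min_span(d) == min(totals)
    assert max_span(d) == max(totals)
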