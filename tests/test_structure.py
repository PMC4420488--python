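"""Junction classification, category table, enrichment and attributes."""

import math

import pytest

from ligbias import (
    CategoryTable,
    DEFAULT_CATEGORY_TABLE,
    FavorabilityTable,
    StackingBackend,
    attribute_vectors,
    attributes_to_frame,
    category_distribution,
    classify_junction,
    cofold_pair,
    enrichment,
    favorability_call,
    pool_from_sequences,
)
from ligbias.structure import (
    EXTERIOR_UNPAIRED,
    IMPOSSIBLE_STATE_PAIRS,
    LOOP_UNPAIRED,
    PAIRED_INTER,
    PAIRED_INTRA,
    STATE_ORDER,
)

# one constructed dual dot-bracket for every geometrically realizable
# (state_a, state_b) combination
CONSTRUCTED = {
    (EXTERIOR_UNPAIRED, EXTERIOR_UNPAIRED): "..&..",
    (EXTERIOR_UNPAIRED, PAIRED_INTRA): "..&(...)",
    (LOOP_UNPAIRED, LOOP_UNPAIRED): "(((...&...)))",
    (LOOP_UNPAIRED, PAIRED_INTRA): "((.&(...)))",
    (LOOP_UNPAIRED, PAIRED_INTER): "(.&)",
    (PAIRED_INTRA, EXTERIOR_UNPAIRED): "((..))&...",
    (PAIRED_INTRA, LOOP_UNPAIRED): "((...(....)&.))",
    (PAIRED_INTRA, PAIRED_INTRA): "(....)&(....)",
    (PAIRED_INTRA, PAIRED_INTER): "((....)&)",
    (PAIRED_INTER, LOOP_UNPAIRED): "(&.)",
    (PAIRED_INTER, PAIRED_INTRA): "(&(..))",
    (PAIRED_INTER, PAIRED_INTER): "(((&)))",
}


class TestClassifyJunction:
    @pytest.mark.parametrize("states,db", sorted(CONSTRUCTED.items()))
    def test_constructed_examples(self, states, db):
        cat = classify_junction(db)
        assert (cat.state_a, cat.state_b) == states
        assert cat.category_id == DEFAULT_CATEGORY_TABLE.id_of(*states)

    def test_loop_break_configuration(self):
        cat = classify_junction("(((...&...)))")
        assert (cat.state_a, cat.state_b) == (LOOP_UNPAIRED, LOOP_UNPAIRED)

    def test_intermolecular_duplex(self):
        cat = classify_junction("(((&)))")
        assert (cat.state_a, cat.state_b) == (PAIRED_INTER, PAIRED_INTER)

    def test_intra_vs_exterior(self):
        cat = classify_junction("((..))&...")
        assert (cat.state_a, cat.state_b) == (PAIRED_INTRA, EXTERIOR_UNPAIRED)

    @pytest.mark.parametrize("bad", ["...", "..&..&..", "((&)", ".x&..", "&..", "..&"])
    def test_malformed_notation_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_junction(bad)

    def test_realizable_combinations_cover_exactly_the_possible_12(self):
        """The 4 state pairs absent from CONSTRUCTED are geometrically
        impossible without pseudoknots: a pair enclosing one junction base
        from the other molecule necessarily encloses both."""
        all_pairs = {(a, b) for a in STATE_ORDER for b in STATE_ORDER}
        assert all_pairs - set(CONSTRUCTED) == set(IMPOSSIBLE_STATE_PAIRS)


class TestCategoryTable:
    def test_default_is_a_bijection_onto_1_16(self):
        ids = sorted(
            DEFAULT_CATEGORY_TABLE.id_of(a, b) for a in STATE_ORDER for b in STATE_ORDER
        )
        assert ids == list(range(1, 17))

    def test_round_trip_states_of(self):
        for a in STATE_ORDER:
            for b in STATE_ORDER:
                cid = DEFAULT_CATEGORY_TABLE.id_of(a, b)
                assert DEFAULT_CATEGORY_TABLE.states_of(cid) == (a, b)

    def test_custom_mapping_must_be_bijective(self):
        mapping = {
            (a, b): 1 for a in STATE_ORDER for b in STATE_ORDER
        }
        with pytest.raises(ValueError, match="bijection"):
            CategoryTable(mapping)

    def test_custom_mapping_is_used(self):
        default = {k: v for k, v in DEFAULT_CATEGORY_TABLE.items()}
        # swap two ids
        k1 = (LOOP_UNPAIRED, LOOP_UNPAIRED)
        k2 = (PAIRED_INTER, PAIRED_INTER)
        default[k1], default[k2] = default[k2], default[k1]
        table = CategoryTable(default)
        cat = classify_junction("(((...&...)))", table)
        assert cat.category_id == DEFAULT_CATEGORY_TABLE.id_of(*k2)


class TestCategoryDistribution:
    def _mk(self, cat_ids, rejected=0):
        results = []
        toy = StackingBackend()
        # fabricate CofoldResult-likes via real cofolds is overkill; use the
        # public API with constructed duals through classify + a stub
        from ligbias.structure import CofoldResult, JunctionCategory

        for cid in cat_ids:
            a, b = DEFAULT_CATEGORY_TABLE.states_of(cid)
            results.append(
                CofoldResult(
                    seq_a="A", seq_b="A", dot_bracket=".&.", mfe_ab=-1, mfe_a=0, mfe_b=0,
                    accepted=True, category=JunctionCategory(a, b, cid),
                )
            )
        for _ in range(rejected):
            results.append(
                CofoldResult(
                    seq_a="A", seq_b="A", dot_bracket=".&.", mfe_ab=0, mfe_a=0, mfe_b=0,
                    accepted=False, category=None,
                )
            )
        return results

    def test_percentages(self):
        dist, rejected = category_distribution(self._mk([6, 6, 6, 16]))
        assert dist == {6: 75.0, 16: 25.0}
        assert rejected == 0

    def test_single_category_is_100(self):
        dist, _ = category_distribution(self._mk([1, 1]))
        assert dist == {1: 100.0}

    def test_no_accepted_cofolds_is_an_error(self):
        with pytest.raises(ValueError, match="3 rejected"):
            category_distribution(self._mk([], rejected=3))

    def test_percentages_sum_to_100(self):
        dist, _ = category_distribution(self._mk([1, 6, 6, 8, 16, 12, 12, 12]))
        assert sum(dist.values()) == pytest.approx(100.0, abs=1e-6)


class TestEnrichment:
    def test_signed_fraction(self):
        assert enrichment({"x": 30.0}, {"x": 20.0})["x"] == pytest.approx(0.5)

    def test_identity(self):
        assert enrichment({"x": 20.0}, {"x": 20.0})["x"] == 0.0

    def test_absent_reference_category_is_nan(self):
        e = enrichment({"x": 0.0}, {"x": 0.0})
        assert math.isnan(e["x"])


class TestFavorabilityCall:
    @pytest.mark.parametrize(
        "e,kind,expect",
        [
            (-0.12, "cofold", "unfavorable"),
            (-0.10, "cofold", "unfavorable"),   # "-10% or worse"
            (+0.25, "cofold", "favorable"),
            (+0.20, "cofold", "favorable"),     # "+20% or higher"
            (+0.10, "cofold", "neutral"),
            (+0.10, "contrafold", "favorable"), # "+5% or higher"
            (+0.04, "contrafold", "neutral"),
            (-0.05, "contrafold", "neutral"),
        ],
    )
    def test_thresholds(self, e, kind, expect):
        assert favorability_call(e, kind) == expect

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            favorability_call(0.0, "dicer")

    def test_from_enrichment_builds_calls(self):
        t = FavorabilityTable.from_enrichment(
            {"cofold3": {6: 0.5, 8: -0.2, 1: 0.0}, "fold3": {0: -0.3}}
        )
        assert t.call("cofold3", 6) == "favorable"
        assert t.call("cofold3", 8) == "unfavorable"
        assert t.call("cofold3", 1) == "neutral"
        assert t.call("fold3", 0) == "unfavorable"

    def test_unseen_label_neutral_with_warning(self):
        t = FavorabilityTable()
        with pytest.warns(UserWarning, match="neutral"):
            assert t.call("cofold5", 99) == "neutral"


class TestAttributeVectors:
    def test_four_slots_and_group_partition(self, small_pool, adaptor3, adaptor5, toy_backend):
        fav = FavorabilityTable(
            {
                "fold3": {"no pairing": "neutral", 0: "unfavorable"},
                "fold5": {"no pairing": "unfavorable", 0: "unfavorable"},
                "cofold3": {},
                "cofold5": {},
            }
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse table -> neutral fallbacks
            vectors = attribute_vectors(
                small_pool, adaptor3, adaptor5, fav,
                single_backend=toy_backend, pair_backend=toy_backend,
            )
        assert len(vectors) == len(small_pool)
        for v in vectors:
            assert len(v.calls) == 4
            assert 0 <= v.n_unfavorable <= 4
        frame = attributes_to_frame(vectors)
        assert frame["n_unfavorable"].between(0, 4).all()
        # groups partition the pool
        assert frame["n_unfavorable"].value_counts().sum() == len(small_pool)

    def test_n_unfavorable_counts_unfavorable_slots(self):
        from ligbias.structure import AttributeVector

        v = AttributeVector(
            id="x", fold3_class=0, fold5_class=0, cofold3_category=6, cofold5_category=6,
            calls=("unfavorable", "unfavorable", "unfavorable", "favorable"),
        )
        assert v.n_unfavorable == 3

    def test_randomized_adaptor_rejected_for_attributes(self, small_pool, adaptor5):
        from ligbias.adaptors import AdaptorSpec

        a3n = AdaptorSpec(side="three_prime", sequence="AGAUCGNNNNNNGAGC")
        with pytest.raises(ValueError, match="randomized region"):
            attribute_vectors(small_pool, a3n, adaptor5, FavorabilityTable())
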