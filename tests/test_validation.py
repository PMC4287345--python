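"""Survival, proteomics, chemistry and enrichment validation operations."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from edrug.regions import MissenseMutation, Pfr
from edrug.validation import (
    ClinicalRecord,
    Fingerprint,
    InteractionRecord,
    classify_patients,
    expand_targets_by_similarity,
    expression_activity_correlation,
    expression_group_test,
    fisher_exact,
    go_enrichment,
    kaplan_meier,
    logrank_test,
    tanimoto,
    target_overlap_test,
)


def _mut(gene, iso, pos, sample="p"):
    return MissenseMutation(sample_id=sample, gene_id=gene, isoform_id=iso,
                            position=pos, ref_aa="A", alt_aa="V")


RESISTANCE_REGION = Pfr("R1", "G1", "G1.1", "pfam", 10, 50, "dom")


class TestClassifyPatients:
    def _record(self, pid, mutations):
        return ClinicalRecord(patient_id=pid, drug_id="D1", time=100, event=True,
                              mutations=mutations)

    def test_three_way_classification_and_precedence(self):
        records = [
            self._record("p1", (_mut("G1", "G1.1", 30),)),            # inside
            self._record("p2", (_mut("G1", "G1.1", 80),)),            # same gene, outside
            self._record("p3", (_mut("G2", "G2.1", 5),)),             # other gene
            self._record("p4", (_mut("G1", "G1.1", 80), _mut("G1", "G1.1", 20))),
            self._record("p5", ()),                                   # profiled, clean
        ]
        labels = classify_patients(records, [RESISTANCE_REGION])
        assert labels == {
            "p1": "resistant_pfr_mutated",
            "p2": "other_region_mutated",
            "p3": "gene_unmutated",
            "p4": "resistant_pfr_mutated",  # resistance lesion dominates
            "p5": "gene_unmutated",
        }

    def test_unprofiled_patients_excluded(self):
        records = [self._record("p1", None), self._record("p2", ())]
        labels = classify_patients(records, [RESISTANCE_REGION])
        assert "p1" not in labels and "p2" in labels

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(50):
            muts = tuple(
                _mut("G1", "G1.1", int(rng.integers(1, 100)))
                for _ in range(rng.integers(0, 3))
            )
            records.append(self._record(f"p{i}", muts if rng.random() > 0.1 else None))
        labels = classify_patients(records, [RESISTANCE_REGION])
        n_unprofiled = sum(r.mutations is None for r in records)
        assert len(labels) == len(records) - n_unprofiled


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = kaplan_meier([1, 2, 3], [True, True, True])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat(self):
        curve = kaplan_meier([5, 8, 9], [False, False, False])
        assert curve.times.size == 0
        assert curve.at(100.0) == 1.0

    def test_censoring_tie_convention(self):
        # censored subject at t=2 is still at risk for the event at t=2
        curve = kaplan_meier([1, 2, 2, 4], [True, True, False, True])
        np.testing.assert_allclose(curve.survival, [3 / 4, 3 / 4 * 2 / 3, 0.0])

    def test_five_record_mixed_fixture(self):
        # events at 2 (n=5) and 5 (n=3), censorings at 3 and 6
        curve = kaplan_meier([2, 3, 5, 6, 7], [True, False, True, False, True])
        np.testing.assert_allclose(
            curve.survival, [4 / 5, 4 / 5 * 2 / 3, 4 / 5 * 2 / 3 * 0]
        )

    def test_properties_and_empirical_equivalence(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, size=40)
        curve = kaplan_meier(times, [True] * 40)
        assert np.all(np.diff(curve.survival) <= 1e-15)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))
        # no censoring: S(t) equals the empirical survival function
        for t in times:
            assert curve.at(t) == pytest.approx((times > t).mean())

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        times = rng.exponential(10, size=60).round(1)
        events = rng.random(60) < 0.7
        curve = kaplan_meier(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(kmf.predict(t), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])
        with pytest.raises(ValueError):
            kaplan_meier([1, -2], [True, True])


def hand_logrank_two_groups(t1, e1, t2, e2):
    """Independent two-group log-rank oracle from the O-E table."""
    all_events = sorted(set([t for t, e in zip(t1, e1) if e]
                            + [t for t, e in zip(t2, e2) if e]))
    o_minus_e = 0.0
    var = 0.0
    for et in all_events:
        n1 = sum(t >= et for t in t1)
        n2 = sum(t >= et for t in t2)
        d1 = sum(t == et and e for t, e in zip(t1, e1))
        d2 = sum(t == et and e for t, e in zip(t2, e2))
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        g = ([1.0, 2.0, 3.0], [True, True, True])
        result = logrank_test([g, g])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p == pytest.approx(1.0)

    def test_six_event_hand_fixture(self):
        t1, e1 = [1.0, 2.0, 3.0], [True] * 3
        t2, e2 = [10.0, 20.0, 30.0], [True] * 3
        result = logrank_test([(t1, e1), (t2, e2)])
        assert result.statistic == pytest.approx(hand_logrank_two_groups(t1, e1, t2, e2))
        assert result.worse_group == 0  # early events: group 0 fares worse
        assert result.p < 0.05

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        g1 = (rng.exponential(5, 20), rng.random(20) < 0.8)
        g2 = (rng.exponential(9, 25), rng.random(25) < 0.8)
        a = logrank_test([g1, g2])
        b = logrank_test([(g1[0] * 7.3, g1[1]), (g2[0] * 7.3, g2[1])])
        assert a.statistic == pytest.approx(b.statistic)

    def test_three_groups_df_and_discrimination(self):
        rng = np.random.default_rng(9)
        similar1 = (rng.exponential(10, 30), [True] * 30)
        similar2 = (rng.exponential(10, 30), [True] * 30)
        worse = (rng.exponential(2, 30), [True] * 30)
        three = logrank_test([similar1, similar2, worse])
        pair = logrank_test([similar1, similar2])
        assert three.df == 2
        assert three.p < pair.p

    def test_matches_lifelines_multivariate(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(10)
        groups = [
            (rng.exponential(5, 25).round(1), rng.random(25) < 0.7)
            for _ in range(3)
        ]
        mine = logrank_test(groups)
        times = np.concatenate([g[0] for g in groups])
        events = np.concatenate([g[1] for g in groups])
        labels = np.concatenate([[i] * 25 for i in range(3)])
        ref = lifelines_stats.multivariate_logrank_test(times, labels, events)
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([([1.0], [True]), ([], [])])


class TestExpressionOps:
    def test_group_test_enumeration_value(self):
        expr = {f"s{i}": v for i, v in enumerate([1, 2, 3, 4, 5, 6])}
        p, delta = expression_group_test(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert p == pytest.approx(0.1)
        assert delta == -3.0

    def test_identical_constants(self):
        expr = {"a": 2.0, "b": 2.0, "c": 2.0, "d": 2.0}
        p, delta = expression_group_test(expr, ["a", "b"], ["c", "d"])
        assert p == 1.0 and delta == 0.0

    def test_lower_expression_in_mutant_group(self):
        rng = np.random.default_rng(12)
        expr = {f"m{i}": rng.normal(1.0, 0.3) for i in range(10)}
        expr |= {f"w{i}": rng.normal(3.0, 0.3) for i in range(10)}
        p, delta = expression_group_test(
            expr, [f"m{i}" for i in range(10)], [f"w{i}" for i in range(10)]
        )
        assert p < 1e-3 and delta < 0

    def test_correlation_exact_lines(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert expression_activity_correlation(x, [2 * v + 1 for v in x])[0] == pytest.approx(1.0)
        assert expression_activity_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_correlation_hand_fixture(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        r, p = expression_activity_correlation(x, y)
        assert r == pytest.approx(r_hand, abs=1e-12)
        t = r_hand * math.sqrt(3 / (1 - r_hand**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=3), rel=1e-9)

    def test_correlation_errors(self):
        with pytest.raises(ValueError):
            expression_activity_correlation([1, 2], [3, 4])
        with pytest.raises(ValueError, match="zero variance"):
            expression_activity_correlation([1, 1, 1], [1, 2, 3])


def hypergeom_tail_oracle(a, b, c, d):
    """P(overlap >= a) with fixed margins, as an exact rational number."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    total = math.comb(n, c1)
    num = sum(
        math.comb(r1, k) * math.comb(r2, c1 - k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if k >= a
    )
    return Fraction(num, total)


class TestFisher:
    def test_tail_fixture(self):
        assert fisher_exact([[2, 3], [0, 100]], "greater") == float(
            hypergeom_tail_oracle(2, 3, 0, 100)
        )

    def test_zero_margin(self):
        assert fisher_exact([[0, 0], [5, 7]]) == 1.0
        assert fisher_exact([[0, 5], [0, 7]]) == 1.0

    def test_two_sided_enumeration(self):
        # sum of all tables (fixed margins) no more probable than observed
        a, b, c, d = 1, 9, 11, 3
        r1, r2, c1 = a + b, c + d, a + c
        total = math.comb(r1 + r2, c1)
        obs = math.comb(r1, a) * math.comb(r2, c)
        num = sum(
            w for k in range(max(0, c1 - r2), min(r1, c1) + 1)
            if (w := math.comb(r1, k) * math.comb(r2, c1 - k)) <= obs
        )
        assert fisher_exact([[a, b], [c, d]], "two-sided") == num / total

    @settings(max_examples=100, deadline=None)
    @given(cells=st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_scipy(self, cells):
        a, b, c, d = cells
        for alt in ("greater", "less", "two-sided"):
            mine = fisher_exact([[a, b], [c, d]], alt)
            ref = stats.fisher_exact([[a, b], [c, d]], alternative=alt)[1]
            assert mine == pytest.approx(ref, rel=1e-7, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[1, 2], [3, 4]], "sideways")


INTERACTIONS = [
    InteractionRecord("drugA", "P1", 950),
    InteractionRecord("drugA", "P2", 850),
    InteractionRecord("drugA", "P3", 720),
    InteractionRecord("drugA", "P4", 400),
    InteractionRecord("drugB", "P5", 999),
]


class TestTargetOverlap:
    def test_enrichment_detected(self):
        background = {f"P{i}" for i in range(1, 51)}
        associated = {"P1", "P2", "P9"}
        overlap, p = target_overlap_test(associated, "drugA", INTERACTIONS, 700, background)
        assert overlap == 2
        assert p == float(hypergeom_tail_oracle(2, 1, 1, 46))

    def test_disjoint_sets_null(self):
        background = {f"P{i}" for i in range(1, 21)}
        overlap, p = target_overlap_test({"P10", "P11"}, "drugA", INTERACTIONS, 700, background)
        assert overlap == 0 and p == 1.0

    def test_absent_drug(self):
        assert target_overlap_test({"P1"}, "nosuch", INTERACTIONS, 700, {"P1", "P2"}) == (0, 1.0)

    def test_score_threshold_nesting(self):
        background = {f"P{i}" for i in range(1, 10)}

        def targets(threshold):
            return {
                r.protein_id for r in INTERACTIONS
                if r.chemical_id == "drugA" and r.score >= threshold
            } & background

        assert targets(900) <= targets(800) <= targets(700)

    def test_background_violation(self):
        with pytest.raises(ValueError):
            target_overlap_test({"PX"}, "drugA", INTERACTIONS, 700, {"P1"})


def fp(chem, on_bits, size=16):
    bits = np.zeros(size, dtype=bool)
    bits[list(on_bits)] = True
    return Fingerprint(chemical_id=chem, bits=bits)


class TestTanimoto:
    def test_identity_disjoint_and_overlap(self):
        assert tanimoto(fp("a", {1, 2, 3}), fp("b", {1, 2, 3})) == 1.0
        assert tanimoto(fp("a", {1, 2}), fp("b", {3, 4})) == 0.0
        assert tanimoto(fp("a", {1, 2, 3}), fp("b", {2, 3, 4})) == 0.5

    def test_all_zero_convention(self):
        assert tanimoto(fp("a", set()), fp("b", set())) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(fp("a", {1}, size=8), fp("b", {1}, size=16))

    @settings(max_examples=100, deadline=None)
    @given(
        x=st.sets(st.integers(0, 15)), y=st.sets(st.integers(0, 15)),
        z=st.sets(st.integers(0, 15)),
    )
    def test_symmetry_and_triangle_on_distance(self, x, y, z):
        a, b, c = fp("a", x), fp("b", y), fp("c", z)
        assert tanimoto(a, b) == tanimoto(b, a)
        d_ab, d_bc, d_ac = 1 - tanimoto(a, b), 1 - tanimoto(b, c), 1 - tanimoto(a, c)
        assert d_ac <= d_ab + d_bc + 1e-12


class TestExpandTargets:
    FPS = [fp("drugA", {1, 2, 3, 4}), fp("chem1", {1, 2, 3}),  # sim 3/4
           fp("chem2", {1, 2, 8, 9})]                          # sim 2/6
    INTER = INTERACTIONS + [
        InteractionRecord("chem1", "P7", 800),
        InteractionRecord("chem2", "P8", 800),
    ]

    def test_cutoff_excludes_all(self):
        out = expand_targets_by_similarity("drugA", self.FPS, self.INTER, 1.01, 700)
        assert out == {"P1", "P2", "P3"}

    def test_cutoff_zero_includes_all(self):
        out = expand_targets_by_similarity("drugA", self.FPS, self.INTER, 0.0, 700)
        assert out == {"P1", "P2", "P3", "P7", "P8"}

    def test_selective_cutoff(self):
        out = expand_targets_by_similarity("drugA", self.FPS, self.INTER, 0.70, 700)
        assert out == {"P1", "P2", "P3", "P7"}  # chem1 (0.75) in, chem2 (0.33) out

    def test_missing_fingerprint(self):
        with pytest.raises(ValueError):
            expand_targets_by_similarity("nosuch", self.FPS, self.INTER, 0.7, 700)


class TestGoEnrichment:
    ANNOTATIONS = {
        "g1": {"GO:A", "GO:B"}, "g2": {"GO:A"}, "g3": {"GO:A"},
        "g4": {"GO:B"}, "g5": {"GO:C"},
        **{f"g{i}": {"GO:C"} for i in range(6, 31)},
    }
    BACKGROUND = {f"g{i}" for i in range(1, 31)}

    def test_gene_set_equals_background_all_null(self):
        frame = go_enrichment(self.BACKGROUND, self.ANNOTATIONS, self.BACKGROUND)
        assert (frame["p"] == 1.0).all()

    def test_perfectly_enriched_term(self):
        frame = go_enrichment({"g1", "g2", "g3"}, self.ANNOTATIONS, self.BACKGROUND)
        row = frame.set_index("term").loc["GO:A"]
        assert row["count_in_set"] == 3
        assert row["p"] == float(hypergeom_tail_oracle(3, 0, 0, 27))

    def test_unrepresented_term_not_smaller(self):
        frame = go_enrichment({"g1", "g2", "g3"}, self.ANNOTATIONS, self.BACKGROUND)
        by_term = frame.set_index("term")["p"]
        assert by_term["GO:C"] >= by_term["GO:A"]

    def test_q_values_bounded_and_monotone_with_p(self):
        frame = go_enrichment({"g1", "g2", "g4"}, self.ANNOTATIONS, self.BACKGROUND)
        assert ((frame["q"] >= frame["p"] - 1e-15) & (frame["q"] <= 1.0)).all()

    def test_errors(self):
        with pytest.raises(ValueError):
            go_enrichment({"g1"}, self.ANNOTATIONS, set())
        with pytest.raises(ValueError):
            go_enrichment({"zz"}, self.ANNOTATIONS, self.BACKGROUND)


class TestRecordTypes:
    def test_clinical_invariants(self):
        with pytest.raises(ValueError):
            ClinicalRecord("p", "d", -1.0, True)

    def test_interaction_score_range(self):
        with pytest.raises(ValueError):
            InteractionRecord("c", "p", 1500)
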