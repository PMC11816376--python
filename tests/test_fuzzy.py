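"""Fuzzy partitions, Wang-Mendel rule learning and Mamdani inference.

The reference Mamdani engine used here is an independent dense-grid
implementation written directly from the triangle geometry, so agreement
checks do not share code with the package's inference path.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from copdreadmit import (FuzzyRule, InferenceConfig, RuleBase,
                         build_partition, fit_level2,
                         generate_candidate_rules, mamdani_infer,
                         merge_expert_rules, resolve_conflicts)


# --- independent reference engine -----------------------------------------

def _tri(x, left, peak, right):
    """Triangle membership evaluated pointwise from vertex geometry."""
    mu = np.zeros_like(x)
    rising = (x >= left) & (x <= peak)
    if peak > left:
        mu[rising] = (x[rising] - left) / (peak - left)
    mu[x == peak] = 1.0
    falling = (x > peak) & (x <= right)
    if right > peak:
        mu[falling] = (right - x[falling]) / (right - peak)
    return mu


def _reference_mamdani(rules, r, n_ant=2, n_cons=1, grid_n=100001):
    """Dense-grid min/max/centroid Mamdani over [0,1] partitions."""
    ant_peaks = np.linspace(0, 1, 2 * n_ant + 1)
    ant_h = 0.5 / n_ant
    cons_peaks = np.linspace(0, 1, 2 * n_cons + 1)
    cons_h = 0.5 / n_cons
    grid = np.linspace(0.0, 1.0, grid_n)
    agg = np.zeros(grid_n)
    any_fired = False
    for ant, cons, _deg in rules:
        strength = 1.0
        for j, k in enumerate(ant):
            p = ant_peaks[k]
            mu = _tri(np.array([r[j]]), p - ant_h, p, p + ant_h)[0]
            strength = min(strength, mu)
        if strength <= 0:
            continue
        any_fired = True
        p = cons_peaks[cons]
        mu = _tri(grid, p - cons_h, p, p + cons_h)
        agg = np.maximum(agg, np.minimum(mu, strength))
    if not any_fired:
        return None
    return float((grid * agg).sum() / agg.sum())


# --- partitions ------------------------------------------------------------

class TestPartition:
    def test_antecedent_partition_has_five_sections(self):
        part = build_partition(0.0, 1.0, 2)
        assert part.n_sections == 5
        assert np.allclose(part.peaks, [0.0, 0.25, 0.5, 0.75, 1.0])

    def test_consequent_partition_three_sections_center_suppressed(self):
        part = build_partition(0.0, 1.0, 1, suppressed=(1,))
        assert part.n_sections == 3
        assert part.suppressed == {1}
        assert np.allclose(part.peaks, [0.0, 0.5, 1.0])

    def test_membership_one_at_own_peak_zero_elsewhere(self):
        part = build_partition(0.0, 1.0, 2)
        for k, peak in enumerate(part.peaks):
            mu = part.membership(peak)
            assert mu[k] == 1.0
            assert np.sum(mu) == 1.0

    def test_membership_midpoint_splits_evenly(self):
        mu = build_partition(0.0, 1.0, 2).membership(0.125)
        assert mu[0] == pytest.approx(0.5)
        assert mu[1] == pytest.approx(0.5)
        assert np.all(mu[2:] == 0.0)

    def test_membership_linear_interpolation(self):
        # 0.30 sits 0.05/0.25 of the way from peak 0.25 toward peak 0.5
        mu = build_partition(0.0, 1.0, 2).membership(0.30)
        assert mu[1] == pytest.approx(0.8)
        assert mu[2] == pytest.approx(0.2)

    def test_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            build_partition(0.0, 1.0, 2).membership(1.5)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            build_partition(0.0, 1.0, 0)

    def test_partition_of_unity(self):
        """Active memberships sum to 1 within 1e-12 everywhere."""
        rng = np.random.default_rng(0)
        xs = rng.random(10_000)
        for n in (1, 2, 3):
            part = build_partition(0.0, 1.0, n)
            sums = part.membership_grid(xs).sum(axis=1)
            assert np.all(np.abs(sums - 1.0) <= 1e-12)
            assert all(np.count_nonzero(part.membership(x)) <= 2 for x in xs[:50])


# --- rule generation -------------------------------------------------------

class TestCandidateRules:
    def test_one_rule_per_patient(self, rng):
        R = rng.random((368, 3))
        y = rng.integers(0, 2, 368)
        rules = generate_candidate_rules(R, y)
        assert len(rules) == 368

    @given(n=st.integers(1, 200), seed=st.integers(0, 2**16))
    def test_candidate_count_identity(self, n, seed):
        rng = np.random.default_rng(seed)
        rules = generate_candidate_rules(rng.random((n, 3)),
                                         rng.integers(0, 2, n))
        assert len(rules) == n

    def test_apex_row_full_degree(self):
        rules = generate_candidate_rules(np.array([[0.0, 0.5, 1.0]]), [1])
        (rule,) = rules
        assert rule.antecedents == (0, 2, 4)
        assert rule.consequent == 2
        assert rule.degree == 1.0

    def test_consequent_follows_label(self):
        lo = generate_candidate_rules(np.array([[0.5, 0.5, 0.5]]), [0])[0]
        hi = generate_candidate_rules(np.array([[0.5, 0.5, 0.5]]), [1])[0]
        assert lo.consequent == 0 and hi.consequent == 2

    def test_tie_breaks_to_lower_section_and_degree_product(self):
        # 0.125 is equidistant from peaks 0 and 0.25: tie -> section 0
        rules = generate_candidate_rules(np.array([[0.125, 0.25, 0.25]]), [0])
        (rule,) = rules
        assert rule.antecedents == (0, 1, 1)
        assert rule.degree == pytest.approx(0.5)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            generate_candidate_rules(np.array([[0.5, 0.5, 0.5]]), [2])


class TestConflictResolution:
    def test_highest_degree_wins(self):
        a = FuzzyRule((2, 3, 1), 2, 0.9, origin=0)
        b = FuzzyRule((2, 3, 1), 0, 0.4, origin=1)
        rb = resolve_conflicts([a, b])
        assert len(rb) == 1
        assert rb.rules[0].consequent == 2

    def test_no_conflicts_identity(self, rng):
        R = rng.random((30, 3))
        candidates = generate_candidate_rules(R, rng.integers(0, 2, 30))
        distinct = {}
        for rule in candidates:
            distinct.setdefault(rule.antecedents, rule)
        rb = resolve_conflicts(list(distinct.values()))
        assert len(rb) == len(distinct)

    def test_degree_tie_keeps_earliest_origin(self):
        a = FuzzyRule((1, 1, 1), 2, 0.7, origin=5)
        b = FuzzyRule((1, 1, 1), 0, 0.7, origin=2)
        rb = resolve_conflicts([a, b])
        assert rb.rules[0].origin == 2

    def test_matches_brute_force_oracle(self, rng):
        """1000 random candidates against an exhaustive group-by/max scan."""
        R = rng.random((1000, 3))
        y = rng.integers(0, 2, 1000)
        candidates = generate_candidate_rules(R, y)
        rb = resolve_conflicts(candidates)

        expected = {}
        for rule in candidates:
            cur = expected.get(rule.antecedents)
            if cur is None or rule.degree > cur.degree:
                expected[rule.antecedents] = rule
        assert len(rb) == len(expected)
        assert len(rb) <= 125
        for rule in rb.rules:
            assert expected[rule.antecedents] == rule

    def test_antecedents_unique_after_resolution(self, rng):
        candidates = generate_candidate_rules(rng.random((500, 3)),
                                              rng.integers(0, 2, 500))
        rb = resolve_conflicts(candidates)
        tuples = [r.antecedents for r in rb.rules]
        assert len(tuples) == len(set(tuples))


class TestExpertRules:
    def test_empty_list_identity(self, rng):
        rb = fit_level2(rng.random((40, 3)), rng.integers(0, 2, 40))
        merged = merge_expert_rules(rb, [])
        assert [r.to_dict() for r in merged.rules] == \
            [r.to_dict() for r in rb.rules]

    def test_stronger_expert_rule_wins(self):
        base = resolve_conflicts([FuzzyRule((1, 1, 1), 0, 0.3, origin=0)],
                                 prevalence=0.5)
        merged = merge_expert_rules(base, [FuzzyRule((1, 1, 1), 2, 1.0)])
        assert merged.rules[0].consequent == 2

    def test_new_antecedents_appended(self):
        base = resolve_conflicts([FuzzyRule((1, 1, 1), 0, 0.3, origin=0)])
        merged = merge_expert_rules(base, [FuzzyRule((4, 4, 4), 2, 0.8)])
        assert len(merged) == 2

    def test_invalid_expert_indices_rejected(self):
        base = resolve_conflicts([FuzzyRule((1, 1, 1), 0, 0.3, origin=0)])
        with pytest.raises(ValueError):
            merge_expert_rules(base, [FuzzyRule((9, 1, 1), 2, 0.8)])
        with pytest.raises(ValueError):
            merge_expert_rules(base, [FuzzyRule((1, 1, 1), 1, 0.8)])


# --- inference -------------------------------------------------------------

class TestMamdani:
    def test_single_high_rule_centroid(self):
        """One fully fired 'high' rule defuzzifies to the triangle centroid
        (0.5 + 1 + 1) / 3 = 5/6."""
        rb = resolve_conflicts([FuzzyRule((2, 2, 2), 2, 1.0, origin=0)])
        result = mamdani_infer(rb, (0.5, 0.5, 0.5))
        assert not result.no_rule_fired
        assert result.risk == pytest.approx(5.0 / 6.0, abs=1e-3)

    def test_high_only_rulebase_stays_above_half(self, rng):
        rules = [FuzzyRule((i, j, k), 2, 0.5, origin=0)
                 for i in range(5) for j in range(5) for k in range(5)]
        rb = resolve_conflicts(rules)
        for r in rng.random((20, 3)):
            assert mamdani_infer(rb, r).risk >= 0.5

    def test_no_rule_fired_falls_back_to_prevalence(self):
        rb = resolve_conflicts([FuzzyRule((0, 0, 0), 2, 1.0, origin=0)],
                               prevalence=0.35)
        result = mamdani_infer(rb, (1.0, 1.0, 1.0))
        assert result.no_rule_fired
        assert result.risk == 0.35

    def test_empty_rule_base_errors(self):
        rb = resolve_conflicts([FuzzyRule((0, 0, 0), 2, 1.0, origin=0)])
        rb.rules = []
        with pytest.raises(ValueError):
            mamdani_infer(rb, (0.5, 0.5, 0.5))

    def test_out_of_range_input_rejected(self):
        rb = resolve_conflicts([FuzzyRule((0, 0, 0), 2, 1.0, origin=0)])
        with pytest.raises(ValueError):
            mamdani_infer(rb, (1.2, 0.5, 0.5))

    def test_output_bounds_and_reference_agreement(self, rng):
        """Random rule bases and inputs agree with the independent
        dense-grid engine to 1e-3 absolute."""
        for _ in range(30):
            n_rules = rng.integers(1, 40)
            raw = set()
            while len(raw) < n_rules:
                raw.add(tuple(rng.integers(0, 5, 3)))
            rules = [FuzzyRule(ant, int(rng.choice([0, 2])),
                               float(rng.uniform(0.1, 1.0)), origin=i)
                     for i, ant in enumerate(sorted(raw))]
            rb = resolve_conflicts(rules, prevalence=0.4)
            for r in rng.random((5, 3)):
                result = mamdani_infer(rb, r)
                assert 0.0 <= result.risk <= 1.0
                ref = _reference_mamdani(
                    [(rule.antecedents, rule.consequent, rule.degree)
                     for rule in rb.rules], r)
                if ref is None:
                    assert result.no_rule_fired
                else:
                    assert result.risk == pytest.approx(ref, abs=1e-3)

    def test_monotone_response_along_diagonal(self, rng):
        """A rule base learned from monotone risks responds monotonically
        when all three inputs rise together.

        Monotonicity is exact at the section apexes, where exactly one
        section is active per input; between apexes centroid
        defuzzification shifts the output of a partially clipped triangle
        slightly toward its interior, so only a small bounded wobble is
        tolerated there.
        """
        n = 400
        t = rng.random(n)
        R = np.clip(t[:, None] + rng.normal(0, 0.05, (n, 3)), 0, 1)
        y = (t > 0.5).astype(int)
        rb = fit_level2(R, y)

        apex_out = [mamdani_infer(rb, (a, a, a)).risk
                    for a in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(b >= a for a, b in zip(apex_out, apex_out[1:]))

        diag = np.linspace(0, 1, 21)
        outputs = [mamdani_infer(rb, (x, x, x)).risk for x in diag
                   if not mamdani_infer(rb, (x, x, x)).no_rule_fired]
        assert all(b >= a - 0.05 for a, b in zip(outputs, outputs[1:]))

    def test_alternate_operators_stay_bounded(self, rng):
        rb = fit_level2(rng.random((100, 3)), rng.integers(0, 2, 100))
        for cfg in (InferenceConfig(and_op="product"),
                    InferenceConfig(defuzzification="mom"),
                    InferenceConfig(implication="scale")):
            for r in rng.random((5, 3)):
                assert 0.0 <= mamdani_infer(rb, r, cfg).risk <= 1.0


class TestFitLevel2:
    def test_rule_count_capped(self, rng):
        R = rng.random((368, 3))
        y = rng.integers(0, 2, 368)
        rb = fit_level2(R, y)
        assert len(rb) <= 125
        assert rb.prevalence == pytest.approx(y.mean())

    def test_separated_risks_recover_labels(self, rng):
        """Well-separated level-1 risks classify perfectly at cutoff 0.5."""
        n = 200
        y = rng.integers(0, 2, n)
        R = np.clip(np.where(y[:, None] == 1,
                             rng.uniform(0.85, 1.0, (n, 3)),
                             rng.uniform(0.0, 0.15, (n, 3))), 0, 1)
        rb = fit_level2(R, y)
        predictions = [float(mamdani_infer(rb, r).risk >= 0.5) for r in R]
        assert np.mean(np.array(predictions) == y) == 1.0

    def test_duplicate_rows_same_rule_base(self, rng):
        R = rng.random((50, 3))
        y = rng.integers(0, 2, 50)
        rb1 = fit_level2(R, y)
        rb2 = fit_level2(np.vstack([R, R]), np.concatenate([y, y]))
        assert [(r.antecedents, r.consequent, r.degree) for r in rb1.rules] \
            == [(r.antecedents, r.consequent, r.degree) for r in rb2.rules]

    def test_describe_prints_readable_rules(self, rng):
        rb = fit_level2(rng.random((30, 3)), rng.integers(0, 2, 30))
        text = rb.describe()
        assert "IF R1 is" in text and "THEN readmission risk is" in text

    def test_round_trip_through_dict(self, rng):
        rb = fit_level2(rng.random((60, 3)), rng.integers(0, 2, 60))
        back = RuleBase.from_dict(rb.to_dict())
        assert len(back) == len(rb)
        r = np.array([0.3, 0.6, 0.9])
        assert mamdani_infer(back, r).risk == mamdani_infer(rb, r).risk
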