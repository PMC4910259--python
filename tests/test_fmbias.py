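"""Observed means, Monte-Carlo backgrounds, empirical p-values, and FDR."""

import itertools

import numpy as np
import pytest

import fmlbias as F
from fmlbias.core import Mutation, MutationSet
from fmlbias.fmbias import BackgroundSample, TestConfig, element_rng, sample_background
from fmlbias.genome import ReferenceGenome
from fmlbias.scores import ElementScoreVector, InMemoryScoreStore


def _element(start, end):
    return F.GenomicElement("e", "E", "cds", (F.GenomicInterval("chr1", start, end),), "+")


def _vector(scores, probs=None):
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    probs = np.full(n, 1 / n) if probs is None else np.asarray(probs, dtype=float)
    return ElementScoreVector(
        "e", np.arange(1, n + 1), np.array(["T"] * n), scores,
        np.zeros(n, dtype=np.int64), probs,
    )


class TestObservedMean:
    def _store(self, entries):
        s = InMemoryScoreStore()
        for pos, score in entries:
            s.add("chr1", pos, "A", "T", score)
        return s

    def test_arithmetic_mean(self):
        el = _element(0, 10)
        store = self._store([(2, 2.0), (5, 4.0)])
        muts = [Mutation("s1", "chr1", 2, "A", "T"), Mutation("s2", "chr1", 5, "A", "T")]
        mean, k, n_samp, _ = F.observed_mean(el, muts, store)
        assert (mean, k, n_samp) == (3.0, 2, 2)

    def test_recurrent_position_counts_once_per_occurrence(self):
        el = _element(0, 10)
        store = self._store([(4, 5.0)])
        muts = [Mutation(f"s{i}", "chr1", 4, "A", "T") for i in range(3)]
        mean, k, n_samp, _ = F.observed_mean(el, muts, store)
        assert (mean, k, n_samp) == (5.0, 3, 3)

    def test_unscored_mutation_is_excluded_with_count(self):
        el = _element(0, 10)
        store = self._store([(2, 2.0), (5, 4.0)])
        muts = [
            Mutation("s1", "chr1", 2, "A", "T"),
            Mutation("s2", "chr1", 3, "A", "T"),  # unscored
            Mutation("s3", "chr1", 5, "A", "T"),
        ]
        mean, k, _, n_unscored = F.observed_mean(el, muts, store)
        assert (mean, k, n_unscored) == (3.0, 2, 1)

    def test_no_scored_mutations_returns_none(self):
        el = _element(0, 10)
        mean, k, _, _ = F.observed_mean(el, [Mutation("s1", "chr1", 2, "A", "T")],
                                        InMemoryScoreStore())
        assert mean is None and k == 0


class TestSampleBackground:
    def test_degenerate_single_entry_pool(self):
        vec = _vector([7.0])
        bg = sample_background(vec, k=3, n_iterations=500, rng=np.random.default_rng(0))
        assert (bg.means == 7.0).all() and len(bg.means) == 500

    def test_matches_closed_form_mean_and_variance_for_k2(self):
        """k=2 draws from a 3-entry weighted pool: enumeration of the 9
        ordered outcomes gives the exact mean/variance of the sampled
        means; Monte Carlo must agree within 3 standard errors."""
        scores = np.array([1.0, 4.0, 10.0])
        probs = np.array([0.5, 0.3, 0.2])
        mu1 = (scores * probs).sum()
        var1 = ((scores - mu1) ** 2 * probs).sum()
        exact_mean, exact_var = mu1, var1 / 2  # mean of 2 iid draws
        n = 200_000
        bg = sample_background(_vector(scores, probs), k=2, n_iterations=n,
                               rng=np.random.default_rng(1))
        se_mean = np.sqrt(exact_var / n)
        assert abs(bg.means.mean() - exact_mean) < 3 * se_mean
        # variance of the sample variance for iid means, normal-ish bound
        se_var = exact_var * np.sqrt(2 / (n - 1)) * 2
        assert abs(bg.means.var(ddof=1) - exact_var) < 3 * se_var

    def test_k1_uniform_sampling_recovers_score_histogram(self):
        scores = np.array([0.0, 1.0, 2.0, 3.0])
        bg = sample_background(_vector(scores), k=1, n_iterations=100_000,
                               rng=np.random.default_rng(2))
        freqs = np.array([(bg.means == s).mean() for s in scores])
        assert np.abs(freqs - 0.25).sum() < 0.02  # total-variation distance


class TestEmpiricalP:
    def test_worked_example_two_in_ten_thousand(self):
        """A background of 10,000 means with exactly 2 at or above the
        observed mean yields p = 2e-4 exactly."""
        means = np.full(10_000, 1.0)
        means[:2] = 5.0
        bg = BackgroundSample("e", means, k=1)
        p = F.empirical_p(3.0, bg, TestConfig())
        assert p == 2 / 10_000 == 2e-4

    def test_observed_below_every_background_mean(self):
        bg = BackgroundSample("e", np.linspace(1, 2, 1000), k=1)
        assert F.empirical_p(0.5, bg, TestConfig()) == 1.0

    def test_tie_saturation_on_constant_scores(self):
        bg = BackgroundSample("e", np.full(1000, 3.0), k=1)
        assert F.empirical_p(3.0, bg, TestConfig()) == 1.0

    def test_strict_tie_flag_excludes_equalities(self):
        bg = BackgroundSample("e", np.full(1000, 3.0), k=1)
        assert F.empirical_p(3.0, bg, TestConfig(strict_ties=True)) == 0.0

    def test_monotone_nonincreasing_in_observed_mean(self):
        bg = BackgroundSample("e", np.random.default_rng(3).normal(size=5000), k=1)
        cfg = TestConfig()
        ps = [F.empirical_p(x, bg, cfg) for x in np.linspace(-3, 3, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_left_tail_probes_negative_selection(self):
        bg = BackgroundSample("e", np.arange(100, dtype=float), k=1)
        assert F.empirical_p(0.0, bg, TestConfig(tail="left")) == 1 / 100


class TestAdjustFdr:
    def _res(self, eid, p, n_samples=3):
        return F.FMBiasResult(eid, n_samples, n_samples, 1.0, p, None, 1000)

    def test_bh_step_up_hand_computation(self):
        results = [self._res(f"e{i}", p) for i, p in enumerate([0.01, 0.02, 0.03])]
        out = F.adjust_fdr(results, min_samples=2)
        assert [r.q_value for r in out] == pytest.approx([0.03, 0.03, 0.03])

    def test_single_eligible_element_identity(self):
        out = F.adjust_fdr([self._res("e", 0.004)], min_samples=2)
        assert out[0].q_value == pytest.approx(0.004)

    def test_below_sample_threshold_gets_no_q(self):
        results = [self._res("e0", 0.01, n_samples=1), self._res("e1", 0.02)]
        out = F.adjust_fdr(results, min_samples=2)
        assert out[0].q_value is None and out[1].q_value == pytest.approx(0.02)

    def test_q_at_least_p_and_nondecreasing_in_rank(self, toy_world):
        cohort = F.generate_cohort(toy_world.spec, toy_world.genome,
                                   toy_world.catalog, toy_world.store,
                                   toy_world.hotspots, seed=5)
        sig = F.compute_signature(cohort, toy_world.genome, mode="cohort")
        res = F.run_fml(toy_world.catalog, cohort, toy_world.store, sig,
                        TestConfig(n_iterations=500, escalation_max=10_000, seed=5),
                        scorer=toy_world.scorer)
        withq = [r for r in res if r.q_value is not None]
        assert withq, "no eligible elements"
        for r in withq:
            assert r.q_value >= r.p_value - 1e-12
        ordered = sorted(withq, key=lambda r: r.p_value)
        # BH q-values after step-up are nondecreasing with p
        for a, b in zip(ordered, ordered[1:]):
            assert a.q_value <= b.q_value + 1e-12


class TestRunFml:
    def test_empty_cohort_yields_empty_results(self, toy_world):
        empty = MutationSet([], set())
        sig = F.SignatureMatrix.uniform()
        res = F.run_fml(toy_world.catalog, empty, toy_world.store, sig,
                        TestConfig(sampling_mode="uniform", n_iterations=100,
                                   escalation_max=100),
                        scorer=toy_world.scorer)
        assert res == []

    def test_bit_identical_under_fixed_seed(self, toy_world):
        cohort = F.generate_cohort(toy_world.spec, toy_world.genome,
                                   toy_world.catalog, toy_world.store,
                                   toy_world.hotspots, seed=2)
        sig = F.compute_signature(cohort, toy_world.genome, mode="cohort")
        cfg = TestConfig(n_iterations=300, escalation_max=10_000, seed=42)
        r1 = F.run_fml(toy_world.catalog, cohort, toy_world.store, sig, cfg,
                       scorer=toy_world.scorer)
        r2 = F.run_fml(toy_world.catalog, cohort, toy_world.store, sig, cfg,
                       scorer=toy_world.scorer)
        assert [(a.element_id, a.p_value) for a in r1] == \
               [(b.element_id, b.p_value) for b in r2]

    def test_per_element_streams_do_not_depend_on_iteration_order(self):
        r_a = element_rng(7, "elementA").integers(0, 1 << 30, 5)
        r_a2 = element_rng(7, "elementA").integers(0, 1 << 30, 5)
        r_b = element_rng(7, "elementB").integers(0, 1 << 30, 5)
        assert (r_a == r_a2).all() and not (r_a == r_b).all()

    def test_mutation_in_two_overlapping_elements_is_tested_in_both(self):
        genome = ReferenceGenome({"chr1": "ACGT" * 300})
        e1 = F.GenomicElement("g1:cds", "G1", "cds",
                              (F.GenomicInterval("chr1", 100, 200),), "+")
        e2 = F.GenomicElement("g2:lncrna", "G2", "lncrna",
                              (F.GenomicInterval("chr1", 150, 260),), "+")
        catalog = F.ElementCatalog()
        catalog.add(e1)
        catalog.add(e2)
        store = InMemoryScoreStore()
        rng = np.random.default_rng(0)
        for el in (e1, e2):
            for pos1 in el.positions():
                ref = genome.base("chr1", pos1)
                for alt in "ACGT":
                    if alt != ref and store.get("chr1", pos1, alt) is None:
                        store.add("chr1", pos1, ref, alt, rng.exponential(1.0))
        shared_pos = 180
        ref = genome.base("chr1", shared_pos)
        alt = "A" if ref != "A" else "C"
        muts = MutationSet.from_mutations(
            [Mutation("s1", "chr1", shared_pos, ref, alt),
             Mutation("s2", "chr1", shared_pos, ref, alt)]
        )
        res = F.run_fml(catalog, muts, store, F.SignatureMatrix.uniform(),
                        TestConfig(sampling_mode="uniform", n_iterations=200,
                                   escalation_max=1000),
                        genome=genome)
        assert {r.element_id for r in res} == {"g1:cds", "g2:lncrna"}

    def test_escalation_doubles_to_ceiling_and_reports_bound(self):
        from fmlbias.fmbias import _test_element

        vec = _vector([1.0, 1.1, 0.9])
        cfg = TestConfig(n_iterations=100, escalation_max=800)
        # observed mean above the pool maximum can never be reached
        p, n_used = _test_element(vec, 2.0, 1, cfg, np.random.default_rng(0))
        assert n_used == 800 and p == pytest.approx(1 / 800)
        # a reachable observed mean stops at the base iteration count
        p2, n2 = _test_element(vec, 0.0, 1, cfg, np.random.default_rng(0))
        assert n2 == 100 and p2 == 1.0


class TestExactEnumerationOracle:
    def test_micro_element_empirical_p_matches_full_enumeration(self):
        """For tiny pools and small k the weighted k-tuple enumeration gives
        the exact p; the Monte-Carlo p must agree within 3 binomial SEs."""
        rng = np.random.default_rng(2024)
        cfg = TestConfig(n_iterations=50_000, escalation_max=50_000)
        for _ in range(8):
            n = rng.integers(2, 7)
            k = int(rng.integers(1, 4))
            scores = np.round(rng.exponential(3.0, n), 3)
            probs = rng.dirichlet(np.ones(n))
            vec = _vector(scores, probs)
            obs_idx = rng.choice(n, size=k, p=probs)
            obs = scores[obs_idx].mean()
            exact = 0.0
            for tup in itertools.product(range(n), repeat=k):
                w = np.prod(probs[list(tup)])
                if scores[list(tup)].mean() >= obs:
                    exact += w
            exact = min(max(float(exact), 0.0), 1.0)
            bg = sample_background(vec, k=k, n_iterations=cfg.n_iterations, rng=rng)
            p_hat = F.empirical_p(obs, bg, cfg)
            se = np.sqrt(exact * (1 - exact) / cfg.n_iterations)
            assert abs(p_hat - exact) <= 3 * se + 1e-12
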