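"""Overlap permutation test: draws, separation, enumeration oracle, null behaviour."""

import itertools

import numpy as np
import pytest

from viroshare.homology import HitFlagTable
from viroshare.permutation import (
    PermutationParams,
    draw_shared_fraction,
    household_overlap_test,
    subject_overlap_test,
)

from conftest import mk_key, mk_virome, random_seq


def flag_table(keys, n_contigs, hit_rule, rng=None):
    """Build a HitFlagTable directly from a rule (qk, tk, n) -> bool array."""
    viromes = {}
    flags = {}
    gen = np.random.default_rng(0)
    for k in keys:
        viromes[k] = mk_virome(
            k, {f"{k.subject_id}.{k.timepoint.label}.c{i}": "ACGT" * 50 + "A" * i
                for i in range(n_contigs)}
        )
    for qk in keys:
        for tk in keys:
            flags[(qk, tk)] = np.asarray(hit_rule(qk, tk, n_contigs), dtype=bool)
    return HitFlagTable("feces", viromes, flags)


def household_keys(n_households=2, tps=("day0", "day3")):
    keys = []
    for h in range(1, n_households + 1):
        for m, treatment in ((0, "amoxicillin"), (1, "placebo")):
            subject = f"S{2 * h - 1 + m:02d}"
            for tp in tps:
                keys.append(
                    mk_key(subject, tp, household=f"H{h}", treatment=treatment)
                )
    return keys


class TestDrawSharedFraction:
    def test_all_hits_give_hundred_percent(self, rng):
        assert draw_shared_fraction(np.ones(6, bool), 10, rng) == 100.0

    def test_no_hits_give_zero(self, rng):
        assert draw_shared_fraction(np.zeros(6, bool), 10, rng) == 0.0

    def test_without_replacement_covers_the_virome(self, rng):
        flags = np.array([True, True, False, False])
        assert draw_shared_fraction(flags, 4, rng) == 50.0

    def test_empty_virome_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            draw_shared_fraction(np.zeros(0, bool), 4, rng)


class TestSubjectTest:
    def test_complete_separation_floors_the_p_value(self):
        keys = household_keys()
        table = flag_table(
            keys,
            5,
            lambda qk, tk, n: np.full(n, qk.subject_id == tk.subject_id),
        )
        result = subject_overlap_test(
            "S01", table, PermutationParams(n_iterations=10_000, seed=1)
        )
        assert result.p_value == 0.0
        assert result.p_text == "<0.0001"
        assert result.within_mean == 100.0
        assert result.between_mean == 0.0

    def test_deterministic_given_seed(self):
        keys = household_keys()
        gen = np.random.default_rng(7)
        arrays = {
            (qk, tk): gen.random(5) < 0.4 for qk in keys for tk in keys
        }
        table = flag_table(keys, 5, lambda qk, tk, n: arrays[(qk, tk)])
        params = PermutationParams(n_iterations=500, seed=42)
        r1 = subject_overlap_test("S01", table, params)
        r2 = subject_overlap_test("S01", table, params)
        assert r1 == r2

    def test_single_timepoint_subject_rejected(self):
        keys = household_keys(tps=("day0",))
        table = flag_table(keys, 4, lambda qk, tk, n: np.zeros(n))
        with pytest.raises(ValueError, match="fewer than 2"):
            subject_overlap_test("S01", table, PermutationParams(seed=0))

    def test_p_matches_exhaustive_enumeration(self):
        # two subjects x two timepoints with deterministic, distinct pair
        # fractions; sampling the whole virome without replacement makes each
        # draw exact, so p converges to the enumerated fraction
        keys = household_keys(n_households=1)
        n = 10
        hits = {
            ("S01", "day0", "S01", "day3"): 7,
            ("S01", "day3", "S01", "day0"): 5,
            ("S01", "day0", "S02", "day0"): 6,
            ("S01", "day0", "S02", "day3"): 2,
            ("S01", "day3", "S02", "day0"): 8,
            ("S01", "day3", "S02", "day3"): 1,
        }

        def rule(qk, tk, n_contigs):
            a = (qk.subject_id, qk.timepoint.label, tk.subject_id, tk.timepoint.label)
            b = (tk.subject_id, tk.timepoint.label, qk.subject_id, qk.timepoint.label)
            k = hits.get(a, hits.get(b, 3))
            return np.arange(n_contigs) < k

        table = flag_table(keys, n, rule)
        within = [("S01", "day0", "S01", "day3"), ("S01", "day3", "S01", "day0")]
        between = [
            (sa_tp[0], sa_tp[1], sb_tp[0], sb_tp[1])
            for sa_tp, sb_tp in itertools.product(
                [("S01", "day0"), ("S01", "day3"), ("S02", "day0"), ("S02", "day3")],
                repeat=2,
            )
            if sa_tp[0] != sb_tp[0]
        ]

        def frac(key4):
            return rule(
                mk_key(key4[0], key4[1]), mk_key(key4[2], key4[3]), n
            ).mean()

        exact = np.mean(
            [[frac(b) >= frac(w) for b in between] for w in within]
        )
        n_iter = 20_000
        result = subject_overlap_test(
            "S01", table, PermutationParams(n_iterations=n_iter, n_contigs_per_draw=n, seed=3)
        )
        se = np.sqrt(exact * (1 - exact) / n_iter)
        assert abs(result.p_value - exact) <= 4 * se

    def test_null_rejection_rate_is_conservative(self):
        # iid hit arrays for every ordered pair: within and between draws are
        # exchangeable, the paired-comparison p concentrates near 0.5 and the
        # rejection rate stays at or below the nominal level
        gen = np.random.default_rng(11)
        keys = household_keys(n_households=2, tps=("day0", "day3", "day7"))
        ps = []
        for rep in range(40):
            arrays = {
                (qk, tk): gen.random(12) < 0.35 for qk in keys for tk in keys
            }
            table = flag_table(keys, 12, lambda qk, tk, n: arrays[(qk, tk)])
            r = subject_overlap_test(
                "S01", table, PermutationParams(n_iterations=400, seed=1000 + rep)
            )
            ps.append(r.p_value)
        ps = np.array(ps)
        assert (ps <= 0.05).mean() <= 0.075
        assert 0.35 < ps.mean() < 0.65

    def test_p_invariant_under_relabeling_when_data_identical(self):
        # all between pairs identical: any relabeling of the other subjects
        # leaves every draw, and hence p, unchanged
        keys = household_keys(n_households=2)

        def rule(qk, tk, n):
            if qk.subject_id == tk.subject_id:
                return np.arange(n) < 4
            return np.arange(n) < 2

        table = flag_table(keys, 8, rule)
        relabeled = [
            mk_key(
                {"S03": "S04", "S04": "S03"}.get(k.subject_id, k.subject_id),
                k.timepoint.label,
                household=k.household_id,
                treatment=k.treatment,
            )
            for k in keys
        ]
        table2 = flag_table(relabeled, 8, rule)
        params = PermutationParams(n_iterations=2000, seed=5)
        assert (
            subject_overlap_test("S01", table, params).p_value
            == subject_overlap_test("S01", table2, params).p_value
        )


class TestHouseholdTest:
    def test_complete_separation(self):
        keys = household_keys(n_households=3)
        table = flag_table(
            keys,
            6,
            lambda qk, tk, n: np.full(n, qk.household_id == tk.household_id),
        )
        result = household_overlap_test(
            "H1", table, PermutationParams(n_iterations=4000, seed=2)
        )
        assert result.p_value < 1 / 4000 + 1e-12
        assert result.p_text == "<0.00025"

    def test_singleton_household_rejected(self):
        keys = household_keys(n_households=2) + [
            mk_key("S09", tp, household="C1", treatment="none")
            for tp in ("day0", "day3")
        ]
        table = flag_table(keys, 4, lambda qk, tk, n: np.zeros(n))
        with pytest.raises(ValueError, match="two-person"):
            household_overlap_test("C1", table, PermutationParams(seed=0))
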