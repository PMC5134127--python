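"""Global-virus clustering, persistence, household sharing, transmission rule."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from viroshare.cohort import TimePoint
from viroshare.simulate import simulate_cohort, transmission_recovery
from viroshare.tracking import (
    ClusterParams,
    GlobalVirus,
    HouseholdSharingSummary,
    call_transmissions,
    cluster_global_viruses,
    directionality_summary,
    household_sharing,
    persistence_summary,
)

from conftest import cohort_from_viromes, mk_key, mk_virome, mutate_seq, random_seq
from test_simulate import small_config

PARAMS = ClusterParams()
TPS = ("day0", "day3", "day7", "week8", "month6")


def subject_key(subject, tp=None):
    if tp is None:  # convenience: subject_key("day0") for the default subject
        subject, tp = "S01", subject
    return mk_key(subject, tp, household="C1", treatment="none")


def household_key(subject, tp):
    treatment = {"S01": "amoxicillin", "S02": "placebo"}[subject]
    return mk_key(subject, tp, household="H1", treatment=treatment)


def mk_global_virus(virus_id, presence_spec, key_fn=household_key):
    """presence_spec: {subject: [tp labels]}; members get one contig per sample."""
    members = []
    presence = {}
    for subject, tps in presence_spec.items():
        for tp in tps:
            key = key_fn(subject, tp)
            members.append((key, f"{virus_id}.{subject}.{tp}"))
            presence[(subject, TimePoint(tp))] = True
    return GlobalVirus(virus_id=virus_id, members=tuple(sorted(members)), presence=presence)


def pattern_cohort(sampled, key_fn=household_key):
    """Cohort whose only role is to know which (subject, tp) samples exist.

    sampled: {subject: [tp labels]}
    """
    viromes = []
    missing = []
    for subject, tps in sampled.items():
        for tp in TPS:
            key = key_fn(subject, tp)
            if tp in tps:
                viromes.append(mk_virome(key, {"filler": "ACGT" * 60}))
            else:
                missing.append(key)
    return cohort_from_viromes(viromes, missing)


class TestClustering:
    def test_identical_contigs_across_timepoints_form_one_cluster(self, rng):
        seq = random_seq(rng, 500)
        viromes = [
            mk_virome(subject_key("day0"), {"c0": seq, "x": random_seq(rng, 400)}),
            mk_virome(subject_key("day7"), {"c7": seq}),
        ]
        clusters = cluster_global_viruses(viromes, "subject", PARAMS)
        assert len(clusters) == 2
        big = max(clusters, key=lambda c: len(c.members))
        assert {cid for _, cid in big.members} == {"c0", "c7"}
        assert big.present("S01", TimePoint("day0")) and big.present("S01", TimePoint("day7"))

    def test_transitive_chain_merges_even_without_direct_overlap(self, rng):
        a = random_seq(rng, 400)
        c = random_seq(rng, 400)
        # overlaps >=50% of the shorter contig with both a and c, which share nothing
        b = a[150:] + c[:250]
        viromes = [
            mk_virome(subject_key("day0"), {"a": a}),
            mk_virome(subject_key("day3"), {"b": b}),
            mk_virome(subject_key("day7"), {"c": c}),
        ]
        clusters = cluster_global_viruses(viromes, "subject", PARAMS)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_divergence_beyond_threshold_splits_clusters(self, rng):
        seq = random_seq(rng, 500)
        far = mutate_seq(seq, 25, rng)  # 5% divergence, beyond the 98% criterion
        viromes = [
            mk_virome(subject_key("day0"), {"a": seq}),
            mk_virome(subject_key("day3"), {"b": far}),
        ]
        clusters = cluster_global_viruses(viromes, "subject", PARAMS)
        assert len(clusters) == 2

    def test_order_invariance_of_ids_and_members(self, rng):
        seqs = {f"v{i}": random_seq(rng, 450) for i in range(4)}
        viromes = [
            mk_virome(subject_key("day0"), {f"{k}.d0": s for k, s in seqs.items()}),
            mk_virome(subject_key("week8"), {f"{k}.w8": s for k, s in list(seqs.items())[:2]}),
        ]
        forward = cluster_global_viruses(viromes, "subject", PARAMS)
        backward = cluster_global_viruses(viromes[::-1], "subject", PARAMS)
        assert [c.virus_id for c in forward] == [c.virus_id for c in backward]
        assert [c.members for c in forward] == [c.members for c in backward]

    def test_mixed_scope_rejected(self, rng):
        viromes = [
            mk_virome(subject_key("S01", "day0"), {"a": random_seq(rng, 300)}),
            mk_virome(
                mk_key("S02", "day0", household="C2", treatment="none"),
                {"b": random_seq(rng, 300)},
            ),
        ]
        with pytest.raises(ValueError, match="span multiple"):
            cluster_global_viruses(viromes, "subject", PARAMS)


class TestPersistence:
    def test_span_buckets(self):
        always = mk_global_virus("gv1", {"S01": list(TPS)}, key_fn=subject_key)
        once = mk_global_virus("gv2", {"S01": ["day0"]}, key_fn=subject_key)
        week = mk_global_virus("gv3", {"S01": ["day3", "week8"]}, key_fn=subject_key)
        summary = persistence_summary([always, once, week])
        assert summary["n_viruses"] == 3
        assert summary["fraction_ge_4_days"] == pytest.approx(2 / 3)
        assert summary["fraction_ge_150_days"] == pytest.approx(1 / 3)
        assert summary["span_histogram"] == {0: 1, 53: 1, 182: 1}

    def test_fractions_non_increasing_in_threshold(self):
        rng = np.random.default_rng(3)
        viruses = []
        for i in range(30):
            tps = [tp for tp in TPS if rng.random() < 0.5] or ["day0"]
            viruses.append(mk_global_virus(f"gv{i}", {"S01": tps}, key_fn=subject_key))
        s = persistence_summary(viruses)
        assert s["fraction_ge_4_days"] >= s["fraction_ge_150_days"]


class TestHouseholdSharing:
    def test_all_shared(self):
        viruses = [
            mk_global_virus(f"gv{i}", {"S01": ["day0"], "S02": ["day3"]}) for i in range(4)
        ]
        summary = household_sharing(viruses)
        assert summary.shared_fraction == 1.0

    def test_three_of_ten_shared(self):
        viruses = [
            mk_global_virus(f"gv{i}", {"S01": ["day0"], "S02": ["day0"]}) for i in range(3)
        ]
        viruses += [mk_global_virus(f"gu{i}", {"S01": ["day3"]}) for i in range(4)]
        viruses += [mk_global_virus(f"gp{i}", {"S02": ["day7"]}) for i in range(3)]
        summary = household_sharing(viruses)
        assert summary.shared_fraction == pytest.approx(0.3)
        assert summary.n_unique_to_antibiotic == 4
        assert summary.n_unique_to_placebo == 3

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans()).filter(lambda t: any(t)),
            min_size=1,
            max_size=20,
        )
    )
    def test_partition_identity_always_holds(self, carriers):
        viruses = []
        for i, (in_a, in_b) in enumerate(carriers):
            spec = {}
            if in_a:
                spec["S01"] = ["day0"]
            if in_b:
                spec["S02"] = ["day3"]
            viruses.append(mk_global_virus(f"gv{i}", spec))
        # ensure both subjects appear somewhere so treatments are known
        viruses.append(mk_global_virus("anchor", {"S01": ["day0"], "S02": ["day0"]}))
        summary = household_sharing(viruses)
        assert (
            summary.n_shared + summary.n_unique_to_placebo + summary.n_unique_to_antibiotic
            == summary.n_viruses_total
        )

    def test_singleton_household_rejected(self):
        viruses = [mk_global_virus("gv1", {"S01": ["day0"]})]
        with pytest.raises(ValueError, match="need 2"):
            household_sharing(viruses)


class TestTransmissionRule:
    def test_textbook_pattern_yields_one_directed_call(self):
        virus = mk_global_virus(
            "gv1", {"S01": list(TPS), "S02": ["week8", "month6"]}
        )
        cohort = pattern_cohort({"S01": list(TPS), "S02": list(TPS)})
        calls = call_transmissions([virus], cohort)
        assert len(calls) == 1
        call = calls[0]
        assert (call.donor, call.recipient) == ("S01", "S02")
        assert call.donor_first.label == "day0"
        assert call.recipient_first.label == "week8"
        assert call.recipient_presence_count == 2
        assert call.direction_class == "antibiotic_to_placebo"

    def test_both_always_present_never_called(self):
        virus = mk_global_virus("gv1", {"S01": list(TPS), "S02": list(TPS)})
        cohort = pattern_cohort({"S01": list(TPS), "S02": list(TPS)})
        assert call_transmissions([virus], cohort) == ()

    def test_single_late_presence_is_not_enough(self):
        virus = mk_global_virus("gv1", {"S01": list(TPS), "S02": ["month6"]})
        cohort = pattern_cohort({"S01": list(TPS), "S02": list(TPS)})
        assert call_transmissions([virus], cohort) == ()

    def test_missing_recipient_sample_before_donor_first_vetoes(self):
        virus = mk_global_virus(
            "gv1", {"S01": ["day3", "day7", "week8"], "S02": ["week8", "month6"]}
        )
        # recipient day0 sample was never collected: absence unknowable
        cohort = pattern_cohort(
            {"S01": list(TPS), "S02": ["day3", "day7", "week8", "month6"]}
        )
        assert call_transmissions([virus], cohort) == ()
        # with the sample collected the same pattern is called
        cohort_full = pattern_cohort({"S01": list(TPS), "S02": list(TPS)})
        assert len(call_transmissions([virus], cohort_full)) == 1

    def test_same_first_visit_is_shared_but_tied(self):
        virus = mk_global_virus(
            "gv1", {"S01": ["day3", "day7"], "S02": ["day3", "week8"]}
        )
        cohort = pattern_cohort({"S01": list(TPS), "S02": list(TPS)})
        assert call_transmissions([virus], cohort) == ()

    def test_placebo_to_antibiotic_direction(self):
        virus = mk_global_virus(
            "gv1", {"S02": list(TPS), "S01": ["day7", "week8"]}
        )
        cohort = pattern_cohort({"S01": list(TPS), "S02": list(TPS)})
        calls = call_transmissions([virus], cohort)
        assert calls[0].direction_class == "placebo_to_antibiotic"


class TestDirectionality:
    def test_no_calls_gives_zero_transmission_proportions(self):
        summaries = [
            HouseholdSharingSummary(
                household_id="H1",
                subjects=("S01", "S02"),
                n_viruses_total=10,
                n_shared=4,
                n_unique_to_placebo=3,
                n_unique_to_antibiotic=3,
            )
        ]
        out = directionality_summary([], summaries)
        assert out["transmitted_mean"] == 0.0
        assert out["shared_mean"] == pytest.approx(0.4)

    def test_directional_parts_sum_to_transmission_total(self):
        virus_a = mk_global_virus("gv1", {"S01": list(TPS), "S02": ["week8", "month6"]})
        virus_b = mk_global_virus("gv2", {"S02": list(TPS), "S01": ["day7", "week8"]})
        cohort = pattern_cohort({"S01": list(TPS), "S02": list(TPS)})
        calls = call_transmissions([virus_a, virus_b], cohort)
        summaries = [household_sharing([virus_a, virus_b])]
        out = directionality_summary(calls, summaries)
        assert out["placebo_to_antibiotic_mean"] + out[
            "antibiotic_to_placebo_mean"
        ] == pytest.approx(out["transmitted_mean"])

    def test_planted_one_way_bias_yields_no_reverse_calls(self):
        cfg = small_config(
            transmission_rate=3.0,
            n_background_pool=0,
            missing_sample_prob=0.0,
            seed=17,
        )
        cfg = dataclasses.replace(cfg, transmission_placebo_to_antibiotic_bias=1.0)
        cohort, truth = simulate_cohort(cfg)
        assert truth.transmissions
        all_calls = []
        for h in cohort.two_person_households():
            viromes = [
                cohort.viromes[k]
                for k in cohort.sample_keys()
                if k.household_id == h and k.body_site == "feces"
            ]
            clusters = cluster_global_viruses(viromes, "household", PARAMS)
            all_calls.extend(call_transmissions(clusters, cohort))
        assert all_calls
        assert all(c.direction_class == "placebo_to_antibiotic" for c in all_calls)
        rec = transmission_recovery(all_calls, truth, "feces")
        assert rec["recall"] == 1.0 and rec["precision"] == 1.0
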