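"""Resampling test for individual- and household-specific virome overlap.

Per iteration the test draws a "within" statistic (percent of randomly
sampled contigs from one of the unit's viromes with a homologue in another
virome of the same unit) and a "between" statistic (the same quantity across
two randomly chosen distinct subjects, resp. households). The empirical p
value is the fraction of iterations in which the between draw reaches or
exceeds the within draw, so ties count against significance and strong
subject-specific overlap yields a small p.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SampleKey
from .homology import HitFlagTable


@dataclass(frozen=True)
class PermutationParams:
    n_iterations: int = 10_000
    n_contigs_per_draw: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_contigs_per_draw < 1:
            raise ValueError("n_contigs_per_draw must be >= 1")


@dataclass(frozen=True)
class PermutationResult:
    unit_id: str
    within_mean: float
    within_sd: float
    between_mean: float
    between_sd: float
    p_value: float
    n_iterations: int
    n_contigs_per_draw: int

    def __post_init__(self):
        for v in (self.within_mean, self.between_mean):
            if not 0 <= v <= 100:
                raise ValueError("means are percentages in [0, 100]")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must be in [0, 1]")

    @property
    def p_text(self) -> str:
        """Printed form; a p of zero is reported as below the resolution floor."""
        if self.p_value == 0.0:
            return f"<{1 / self.n_iterations:g}"
        return f"{self.p_value:.4g}"


def draw_shared_fraction(
    flags: np.ndarray, n_contigs: int, rng: np.random.Generator
) -> float:
    """Percent of ``n_contigs`` sampled source contigs with a homologue in the target.

    ``flags`` is the per-contig hit vector of the source virome against the
    target virome. Sampling is without replacement when the virome holds at
    least ``n_contigs`` contigs, with replacement otherwise.
    """
    n_source = len(flags)
    if n_source == 0:
        raise ValueError("source virome is empty")
    if n_source >= n_contigs:
        idx = rng.choice(n_source, size=n_contigs, replace=False)
    else:
        idx = rng.integers(0, n_source, size=n_contigs)
    return 100.0 * float(flags[idx].mean())


def _run_test(
    unit_id: str,
    within_pairs: list[tuple[SampleKey, SampleKey]],
    between_pairs: list[tuple[SampleKey, SampleKey]],
    flags: HitFlagTable,
    params: PermutationParams,
) -> PermutationResult:
    # unit-specific stream so tests of different units are independent draws
    rng = np.random.default_rng([params.seed, zlib.crc32(unit_id.encode())])
    n = params.n_iterations
    w_idx = rng.integers(0, len(within_pairs), size=n)
    b_idx = rng.integers(0, len(between_pairs), size=n)
    w = np.empty(n)
    b = np.empty(n)
    for i in range(n):
        qk, tk = within_pairs[w_idx[i]]
        w[i] = draw_shared_fraction(
            flags.flag_array(qk, tk), params.n_contigs_per_draw, rng
        )
        qk, tk = between_pairs[b_idx[i]]
        b[i] = draw_shared_fraction(
            flags.flag_array(qk, tk), params.n_contigs_per_draw, rng
        )
    p = float((b >= w).mean())
    sd = lambda x: float(x.std(ddof=1)) if len(x) > 1 else 0.0
    return PermutationResult(
        unit_id=unit_id,
        within_mean=float(w.mean()),
        within_sd=sd(w),
        between_mean=float(b.mean()),
        between_sd=sd(b),
        p_value=p,
        n_iterations=n,
        n_contigs_per_draw=params.n_contigs_per_draw,
    )


def subject_overlap_test(
    subject_id: str, flags: HitFlagTable, params: PermutationParams
) -> PermutationResult:
    """Is a subject's virome overlap across time larger than between subjects?

    Within draws compare two distinct random timepoints of the subject;
    between draws compare random timepoints of two distinct randomly chosen
    subjects from the cohort.
    """
    own = sorted(k for k in flags.keys if k.subject_id == subject_id)
    if len(own) < 2:
        raise ValueError(f"subject {subject_id} has fewer than 2 sampled timepoints")
    by_subject: dict[str, list[SampleKey]] = {}
    for k in flags.keys:
        by_subject.setdefault(k.subject_id, []).append(k)
    subjects = sorted(by_subject)
    if len(subjects) < 2:
        raise ValueError("need at least two subjects for the inter-subject null")
    within_pairs = [(a, b) for a in own for b in own if a != b]
    between_pairs = [
        (a, b)
        for sa in subjects
        for sb in subjects
        if sa != sb
        for a in by_subject[sa]
        for b in by_subject[sb]
    ]
    return _run_test(subject_id, within_pairs, between_pairs, flags, params)


def household_overlap_test(
    household_id: str, flags: HitFlagTable, params: PermutationParams
) -> PermutationResult:
    """Is virome overlap across housemates larger than across households?

    Within draws use cross-subject virome pairs inside the household;
    between draws use cross-subject pairs spanning two distinct households.
    """
    by_household: dict[str, dict[str, list[SampleKey]]] = {}
    for k in flags.keys:
        by_household.setdefault(k.household_id, {}).setdefault(k.subject_id, []).append(k)
    if household_id not in by_household:
        raise ValueError(f"unknown household {household_id}")
    members = sorted(by_household[household_id])
    if len(members) != 2:
        raise ValueError(f"household {household_id} is not a two-person household")
    sa, sb = members
    own = by_household[household_id]
    within_pairs = [(a, b) for a in own[sa] for b in own[sb]]
    within_pairs += [(b, a) for a, b in within_pairs]
    households = sorted(by_household)
    between_pairs = [
        (a, b)
        for ha in households
        for hb in households
        if ha != hb
        for subj_a in by_household[ha].values()
        for subj_b in by_household[hb].values()
        for a in subj_a
        for b in subj_b
    ]
    if not between_pairs:
        raise ValueError("no cross-household pairs available")
    return _run_test(household_id, within_pairs, between_pairs, flags, params)


def results_to_dataframe(results) -> pd.DataFrame:
    """Serialise permutation results in the per-unit summary columns."""
    rows = [
        {
            "unit": r.unit_id,
            "within_mean": r.within_mean,
            "within_sd": r.within_sd,
            "between_mean": r.between_mean,
            "between_sd": r.between_sd,
            "p": r.p_value,
            "p_text": r.p_text,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
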