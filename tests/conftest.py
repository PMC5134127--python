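"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from viroshare.cohort import Cohort, ContigRecord, SampleKey, TimePoint, Virome

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def mutate_seq(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply exactly n_subs substitutions at distinct positions."""
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    lookup = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    for p in pos:
        arr[p] = lookup[arr[p]][rng.integers(0, 3)]
    return "".join(arr)


def mk_key(
    subject: str = "S01",
    tp: str = "day0",
    household: str = "H1",
    site: str = "feces",
    treatment: str = "placebo",
) -> SampleKey:
    return SampleKey(
        subject_id=subject,
        household_id=household,
        body_site=site,
        timepoint=TimePoint(tp),
        treatment=treatment,
    )


def mk_virome(key: SampleKey, sequences: dict[str, str]) -> Virome:
    return Virome(
        key, tuple(ContigRecord(cid, seq) for cid, seq in sequences.items())
    )


def cohort_from_viromes(viromes, missing=()) -> Cohort:
    return Cohort(
        viromes={v.key: v for v in viromes}, missing_samples=frozenset(missing)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
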