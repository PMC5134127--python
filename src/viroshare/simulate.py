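"""Synthetic household-virome cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of two-person households plus singleton controls sampled
at five visits (day 0, 3, 7, week 8, month 6) at up to two body sites, with

* a personal "core" of viruses unique to each subject,
* a set of viruses shared by both members of a household from day 0,
* an environment-wide background pool any subject can carry, producing the
  low but nonzero between-subject sharing baseline,
* presence dynamics (retention / reacquisition per visit-to-visit step),
* substitution-only sequence divergence per step, and
* planted inter-housemate transmission events with a directional bias from
  the placebo-taking member toward the antibiotic-taking member.

Every emitted contig derives from exactly one ancestral virus genome; the
machine-readable :class:`TruthTable` records founders, the per-(subject,
visit) presence pattern, and all planted transmissions, so recovery can be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .cohort import (
    Cohort,
    ContigRecord,
    MIN_CONTIG_LENGTH,
    SampleKey,
    TIMEPOINTS,
    TimePoint,
    Virome,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N_TP = len(TIMEPOINTS)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters. Defaults reproduce the reference study design.

    Counts are per the unit named; probabilities apply per visit-to-visit
    step of the five-visit schedule. ``mutation_rate`` is the per-base
    substitution probability per step. ``transmission_rate`` is the expected
    number of planted transmissions per two-person household (Poisson).
    """

    n_households_two_person: int = 8
    n_controls: int = 4
    body_sites: tuple[str, ...] = ("feces", "saliva")
    n_core_viruses_per_subject: int = 18
    n_household_shared_viruses: int = 8
    n_background_pool: int = 300
    background_presence_prob: float = 0.06
    background_retention_prob: float = 0.45
    retention_prob: float = 0.85
    reacquisition_prob: float = 0.005
    transmission_rate: float = 7.0
    transmission_placebo_to_antibiotic_bias: float = 0.75
    mutation_rate: float = 0.002
    genome_length_range: tuple[int, int] = (500, 1500)
    contigs_per_virus: int = 2
    missing_sample_prob: float = 0.02
    lost_households_month6: int = 0
    seed: int = 0

    def __post_init__(self):
        probs = {
            "background_presence_prob": self.background_presence_prob,
            "background_retention_prob": self.background_retention_prob,
            "retention_prob": self.retention_prob,
            "reacquisition_prob": self.reacquisition_prob,
            "transmission_placebo_to_antibiotic_bias": self.transmission_placebo_to_antibiotic_bias,
            "mutation_rate": self.mutation_rate,
            "missing_sample_prob": self.missing_sample_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        counts = {
            "n_households_two_person": self.n_households_two_person,
            "n_controls": self.n_controls,
            "n_core_viruses_per_subject": self.n_core_viruses_per_subject,
            "n_household_shared_viruses": self.n_household_shared_viruses,
            "n_background_pool": self.n_background_pool,
            "contigs_per_virus": self.contigs_per_virus,
            "lost_households_month6": self.lost_households_month6,
        }
        for name, c in counts.items():
            if c < 0:
                raise ValueError(f"{name} must be >= 0, got {c}")
        if self.contigs_per_virus < 1:
            raise ValueError("contigs_per_virus must be >= 1")
        if self.transmission_rate < 0:
            raise ValueError("transmission_rate must be >= 0")
        lo, hi = self.genome_length_range
        if lo < MIN_CONTIG_LENGTH or hi < lo:
            raise ValueError(
                f"genome_length_range must satisfy {MIN_CONTIG_LENGTH} <= lo <= hi"
            )
        if not self.body_sites or not set(self.body_sites) <= {"feces", "saliva"}:
            raise ValueError("body_sites must be a non-empty subset of {feces, saliva}")
        if self.n_household_shared_viruses > self.n_core_viruses_per_subject:
            raise ValueError(
                "n_household_shared_viruses cannot exceed n_core_viruses_per_subject"
            )
        if self.lost_households_month6 > self.n_households_two_person:
            raise ValueError("cannot lose more households than exist")
        if self.n_core_viruses_per_subject + self.n_background_pool == 0:
            raise ValueError("need at least one virus source (core or background pool)")
        if self.n_households_two_person + self.n_controls == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.n_household_shared_viruses > 0 and self.n_households_two_person == 0:
            raise ValueError("household-shared viruses require two-person households")


def default_study_config(seed: int = 0) -> SimulationConfig:
    """The study-design configuration: 8 two-person households + 4 controls,
    five visits, two body sites, one household lost at month 6, and dynamics
    tuned so realized within-subject sharing lands around 20-75% and
    between-subject sharing around 1-17%."""
    return SimulationConfig(lost_households_month6=1, seed=seed)


def null_overlap_config(n_subjects: int = 4, seed: int = 0) -> SimulationConfig:
    """An exchangeable null regime for calibrating the overlap permutation test.

    All subjects are singleton controls drawing viromes from one common
    background pool, and retention equals reacquisition so presence is
    independent across subjects *and* visits: no subject-specific structure
    exists for the test to detect.
    """
    return SimulationConfig(
        n_households_two_person=0,
        n_controls=n_subjects,
        body_sites=("feces",),
        n_core_viruses_per_subject=0,
        n_household_shared_viruses=0,
        n_background_pool=40,
        background_presence_prob=0.3,
        background_retention_prob=0.3,
        retention_prob=0.3,
        reacquisition_prob=0.3,
        transmission_rate=0.0,
        mutation_rate=0.0,
        genome_length_range=(300, 600),
        contigs_per_virus=1,
        missing_sample_prob=0.0,
        lost_households_month6=0,
        seed=seed,
    )


@dataclass(frozen=True)
class PlantedTransmission:
    """One planted donor -> recipient transmission of a virus within a household."""

    body_site: str
    household_id: str
    virus_id: str
    donor: str
    recipient: str
    donor_first: str
    recipient_first: str


@dataclass
class VirusTruth:
    """Ground truth for one simulated virus."""

    virus_id: str
    body_site: str
    kind: str  # personal | shared | background
    founders: tuple[str, ...]
    #: (subject_id, timepoint label) -> present
    presence: dict[tuple[str, str], bool] = field(default_factory=dict)

    def present_timepoints(self, subject_id: str) -> tuple[str, ...]:
        return tuple(
            tp.label
            for tp in TIMEPOINTS
            if self.presence.get((subject_id, tp.label), False)
        )


@dataclass
class TruthTable:
    """All per-virus ground truth plus the planted transmission events."""

    viruses: dict[str, VirusTruth]
    transmissions: tuple[PlantedTransmission, ...]

    def transmissions_at(self, body_site: str) -> tuple[PlantedTransmission, ...]:
        return tuple(t for t in self.transmissions if t.body_site == body_site)

    def to_json(self) -> str:
        payload = {
            "viruses": {
                vid: {
                    "body_site": v.body_site,
                    "kind": v.kind,
                    "founders": list(v.founders),
                    "presence": {
                        f"{s}|{tp}": present
                        for (s, tp), present in sorted(v.presence.items())
                    },
                }
                for vid, v in sorted(self.viruses.items())
            },
            "transmissions": [asdict(t) for t in self.transmissions],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        payload = json.loads(text)
        viruses = {}
        for vid, v in payload["viruses"].items():
            presence = {}
            for key, present in v["presence"].items():
                subject, tp = key.split("|")
                presence[(subject, tp)] = present
            viruses[vid] = VirusTruth(
                virus_id=vid,
                body_site=v["body_site"],
                kind=v["kind"],
                founders=tuple(v["founders"]),
                presence=presence,
            )
        transmissions = tuple(
            PlantedTransmission(**t) for t in payload["transmissions"]
        )
        return cls(viruses=viruses, transmissions=transmissions)


def write_truth(truth: TruthTable, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(truth.to_json())
    return path


def read_truth(path: str | Path) -> TruthTable:
    return TruthTable.from_json(Path(path).read_text())


def truth_virus_of_contig(contig_id: str) -> str:
    """Recover the generating virus id from a simulated contig id."""
    return contig_id.rsplit(".f", 1)[0]


# -- internals ----------------------------------------------------------


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    n = int(rng.binomial(len(codes), rate))
    if n == 0:
        return codes
    pos = rng.choice(len(codes), size=n, replace=False)
    shift = rng.integers(1, 4, size=n)
    out = codes.copy()
    out[pos] = (out[pos] + shift) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return bytes(_BASES[codes]).decode()


def _presence_chain(
    p0: float, retention: float, reacquisition: float, rng: np.random.Generator
) -> np.ndarray:
    out = np.zeros(_N_TP, dtype=bool)
    out[0] = rng.random() < p0
    for k in range(1, _N_TP):
        out[k] = rng.random() < (retention if out[k - 1] else reacquisition)
    return out


class _SimVirus:
    __slots__ = ("virus_id", "kind", "founders", "household_id", "ancestral",
                 "presence", "lineages")

    def __init__(self, virus_id, kind, founders, household_id, ancestral):
        self.virus_id = virus_id
        self.kind = kind
        self.founders = tuple(founders)
        self.household_id = household_id
        self.ancestral = ancestral
        self.presence: dict[str, np.ndarray] = {}
        # subject -> list of 5 code arrays (None before acquisition via transmission)
        self.lineages: dict[str, list] = {}


def _cohort_structure(config: SimulationConfig):
    """Deterministic subject/household layout and treatment assignment."""
    households = []  # (household_id, [(subject, treatment), ...])
    counter = 1
    for h in range(1, config.n_households_two_person + 1):
        arm = "amoxicillin" if h % 2 == 1 else "azithromycin"
        a = f"S{counter:02d}"
        b = f"S{counter + 1:02d}"
        counter += 2
        households.append((f"H{h}", [(a, arm), (b, "placebo")]))
    for c in range(1, config.n_controls + 1):
        subj = f"S{counter:02d}"
        counter += 1
        households.append((f"C{c}", [(subj, "none")]))
    return households


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, TruthTable]:
    """Generate a cohort plus its ground truth. Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    households = _cohort_structure(config)
    subjects = [s for _, members in households for s, _ in members]
    treatment = {s: t for _, members in households for s, t in members}
    household_of = {s: h for h, members in households for s, _ in members}
    two_person = [(h, members) for h, members in households if len(members) == 2]
    sites = tuple(config.body_sites)

    # -- missing samples --------------------------------------------------
    missing: set[tuple[str, str, str]] = set()  # (subject, tp label, site)
    for subject in subjects:
        for tp in TIMEPOINTS:
            for site in sites:
                if rng.random() < config.missing_sample_prob:
                    missing.add((subject, tp.label, site))
    for h, members in two_person[len(two_person) - config.lost_households_month6:]:
        for s, _ in members:
            for site in sites:
                missing.add((s, "month6", site))

    viromes: dict[SampleKey, Virome] = {}
    truth_viruses: dict[str, VirusTruth] = {}
    planted: list[PlantedTransmission] = []

    n_personal = config.n_core_viruses_per_subject - config.n_household_shared_viruses

    for site in sites:
        prefix = site[0]
        counter = 0
        viruses: list[_SimVirus] = []

        def new_virus(kind, founders, household_id):
            nonlocal counter
            counter += 1
            lo, hi = config.genome_length_range
            length = int(rng.integers(lo, hi + 1))
            ancestral = rng.integers(0, 4, size=length).astype(np.uint8)
            v = _SimVirus(f"{prefix}v{counter:04d}", kind, founders, household_id, ancestral)
            viruses.append(v)
            return v

        # ancestral genomes, fixed order: personal by subject, shared by
        # household, then the background pool
        for subject in subjects:
            n_pers = (
                n_personal
                if len(households) and household_of[subject].startswith("H")
                else config.n_core_viruses_per_subject
            )
            for _ in range(n_pers):
                new_virus("personal", (subject,), household_of[subject])
        for h, members in two_person:
            for _ in range(config.n_household_shared_viruses):
                new_virus("shared", tuple(s for s, _ in members), h)
        for _ in range(config.n_background_pool):
            new_virus("background", (), "")

        # presence chains; the background pool flickers with its own retention
        for v in viruses:
            carriers = list(v.founders) if v.kind != "background" else subjects
            for subject in carriers:
                if v.kind == "background":
                    p0 = config.background_presence_prob
                    retention = config.background_retention_prob
                else:
                    p0 = 1.0
                    retention = config.retention_prob
                v.presence[subject] = _presence_chain(
                    p0, retention, config.reacquisition_prob, rng
                )

        # planted transmissions
        by_owner: dict[str, list[_SimVirus]] = {}
        for v in viruses:
            if v.kind == "personal":
                by_owner.setdefault(v.founders[0], []).append(v)
        for h, members in two_person:
            n_events = int(rng.poisson(config.transmission_rate))
            used: set[str] = set()
            for _ in range(n_events):
                placebo = next(s for s, t in members if t == "placebo")
                treated = next(s for s, t in members if t != "placebo")
                donor = (
                    placebo
                    if rng.random() < config.transmission_placebo_to_antibiotic_bias
                    else treated
                )
                recipient = treated if donor == placebo else placebo
                eligible = [
                    v
                    for v in by_owner.get(donor, [])
                    if v.virus_id not in used and v.presence[donor][0]
                ]
                if not eligible:
                    continue
                v = eligible[int(rng.integers(len(eligible)))]
                used.add(v.virus_id)
                # transmit at a visit that still leaves a following visit, so
                # the recipient can be present at >=2 timepoints
                t_x = int(rng.integers(1, _N_TP - 1))
                chain = np.zeros(_N_TP, dtype=bool)
                chain[t_x] = True
                chain[t_x + 1] = True  # floor: guarantees two presences
                for k in range(t_x + 2, _N_TP):
                    chain[k] = rng.random() < (
                        config.retention_prob if chain[k - 1] else config.reacquisition_prob
                    )
                v.presence[recipient] = chain
                donor_first = TIMEPOINTS[int(np.argmax(v.presence[donor]))].label
                planted.append(
                    PlantedTransmission(
                        body_site=site,
                        household_id=h,
                        virus_id=v.virus_id,
                        donor=donor,
                        recipient=recipient,
                        donor_first=donor_first,
                        recipient_first=TIMEPOINTS[t_x].label,
                    )
                )

        # lineage evolution: ancestral sequence at day 0, substitutions per step
        for v in viruses:
            for subject in sorted(v.presence):
                is_recipient = subject not in v.founders and v.kind != "background"
                if is_recipient:
                    continue  # recipients seeded from the donor lineage below
                seqs = [v.ancestral]
                for _ in range(_N_TP - 1):
                    seqs.append(_mutate(seqs[-1], config.mutation_rate, rng))
                v.lineages[subject] = seqs
        for event in planted:
            if event.body_site != site:
                continue
            v = next(x for x in viruses if x.virus_id == event.virus_id)
            t_x = next(i for i, tp in enumerate(TIMEPOINTS) if tp.label == event.recipient_first)
            seqs: list = [None] * t_x
            seqs.append(v.lineages[event.donor][t_x])
            for _ in range(t_x + 1, _N_TP):
                seqs.append(_mutate(seqs[-1], config.mutation_rate, rng))
            v.lineages[event.recipient] = seqs

        # guard: a non-missing sample must not be empty; force one fallback virus
        for subject in subjects:
            for k, tp in enumerate(TIMEPOINTS):
                if (subject, tp.label, site) in missing:
                    continue
                if any(
                    v.presence.get(subject) is not None and v.presence[subject][k]
                    for v in viruses
                ):
                    continue
                fallback = next(
                    v
                    for v in viruses
                    if subject in v.lineages and v.lineages[subject][k] is not None
                )
                fallback.presence[subject][k] = True

        # emission: per-sample fragmentation of each present virus genome
        for subject in subjects:
            for k, tp in enumerate(TIMEPOINTS):
                if (subject, tp.label, site) in missing:
                    continue
                contigs = []
                for v in viruses:
                    chain = v.presence.get(subject)
                    if chain is None or not chain[k]:
                        continue
                    genome = v.lineages[subject][k]
                    length = len(genome)
                    n_frags = max(
                        1, min(config.contigs_per_virus, length // (MIN_CONTIG_LENGTH + 50))
                    )
                    extras = rng.multinomial(
                        length - MIN_CONTIG_LENGTH * n_frags, [1.0 / n_frags] * n_frags
                    )
                    cuts = np.cumsum(MIN_CONTIG_LENGTH + extras)[:-1]
                    for j, frag in enumerate(np.split(genome, cuts)):
                        contigs.append(
                            ContigRecord(f"{v.virus_id}.f{j}", _decode(frag))
                        )
                key = SampleKey(
                    subject_id=subject,
                    household_id=household_of[subject],
                    body_site=site,
                    timepoint=tp,
                    treatment=treatment[subject],
                )
                viromes[key] = Virome(key, tuple(contigs))

        for v in viruses:
            presence = {}
            for subject, chain in v.presence.items():
                for k, tp in enumerate(TIMEPOINTS):
                    presence[(subject, tp.label)] = bool(chain[k])
            truth_viruses[v.virus_id] = VirusTruth(
                virus_id=v.virus_id,
                body_site=site,
                kind=v.kind,
                founders=v.founders,
                presence=presence,
            )

    missing_keys = frozenset(
        SampleKey(
            subject_id=s,
            household_id=household_of[s],
            body_site=site,
            timepoint=TimePoint(tp),
            treatment=treatment[s],
        )
        for (s, tp, site) in missing
    )
    cohort = Cohort(viromes=viromes, missing_samples=missing_keys)
    truth = TruthTable(viruses=truth_viruses, transmissions=tuple(planted))
    return cohort, truth


# -- truth-based scoring -------------------------------------------------


def cluster_truth_virus(member_contig_ids) -> str:
    """Majority generating virus among a cluster's member contig ids."""
    counts: dict[str, int] = {}
    for cid in member_contig_ids:
        vid = truth_virus_of_contig(cid)
        counts[vid] = counts.get(vid, 0) + 1
    return max(sorted(counts), key=lambda v: counts[v])


def transmission_recovery(calls, truth: TruthTable, body_site: str) -> dict:
    """Score transmission calls against the planted events at one body site.

    A call matches a planted event when household, generating virus, donor
    and recipient all agree. Calls are deduplicated by that event key first:
    a fragmented genome can yield several global-virus clusters that each
    re-identify the same event, which is one detection, not several.
    Returns recall over planted events and precision over the distinct
    called events.
    """
    events = {
        (t.household_id, t.virus_id, t.donor, t.recipient): t
        for t in truth.transmissions_at(body_site)
    }
    called_keys = set()
    for call in calls:
        vid = cluster_truth_virus(cid for _, cid in call.members)
        called_keys.add((call.household_id, vid, call.donor, call.recipient))
    matched = called_keys & set(events)
    n_true = len(events)
    n_called = len(called_keys)
    return {
        "n_planted": n_true,
        "n_calls": len(calls),
        "n_called_events": n_called,
        "n_matched": len(matched),
        "n_false": n_called - len(matched),
        "recall": len(matched) / n_true if n_true else float("nan"),
        "precision": len(matched) / n_called if n_called else float("nan"),
    }
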