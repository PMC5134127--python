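"""Global-virus clustering, persistence, household sharing, and transmission calls.

Contigs from all timepoints of a subject (or of both members of a household)
are clustered by single linkage: two contigs are linked when a local
alignment covers at least half of the shorter contig at >= 98% identity
(the same stringency used to assemble highly related viral sequences). Each
connected component is one "global virus" whose presence/absence per
(subject, timepoint) drives persistence statistics, household sharing
proportions, and the putative-transmission rule: a virus present in one
housemate, absent in the other at every sampled visit up to the carrier's
first appearance, and later present in at least two of the other's visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import ANTIBIOTICS, Cohort, SampleKey, TIMEPOINTS, TimePoint
from .homology import HomologyIndex, _best_segment, _candidate_diagonals, encode_sequence

_CLUSTER_WORD_SIZE = 11


@dataclass(frozen=True)
class ClusterParams:
    """Single-linkage criteria: alignment identity and coverage of the shorter contig."""

    min_identity: float = 0.98
    min_overlap: float = 0.50

    def __post_init__(self):
        for name in ("min_identity", "min_overlap"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class GlobalVirus:
    """One cluster of highly similar contigs tracked across samples."""

    virus_id: str
    members: tuple[tuple[SampleKey, str], ...]
    presence: dict[tuple[str, TimePoint], bool] = field(default_factory=dict, compare=False)

    def present(self, subject_id: str, timepoint: TimePoint) -> bool:
        return self.presence.get((subject_id, timepoint), False)

    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted({s for (s, _), p in self.presence.items() if p}))

    def present_timepoints(self, subject_id: str) -> tuple[TimePoint, ...]:
        tps = [tp for (s, tp), p in self.presence.items() if p and s == subject_id]
        return tuple(sorted(tps))

    def first_presence(self, subject_id: str) -> TimePoint | None:
        tps = self.present_timepoints(subject_id)
        return tps[0] if tps else None

    def span_days(self) -> int:
        offsets = [tp.day_offset for (_, tp), p in self.presence.items() if p]
        return max(offsets) - min(offsets)

    def member_contig_ids(self) -> tuple[str, ...]:
        return tuple(cid for _, cid in self.members)


def cluster_global_viruses(
    viromes, scope: str, params: ClusterParams
) -> tuple[GlobalVirus, ...]:
    """Single-linkage clustering of all contigs in a subject or household scope.

    ``scope`` is ``"subject"`` or ``"household"``; all viromes must share the
    corresponding identity. Cluster ids are deterministic, ordered by
    (earliest present timepoint, lexicographically smallest member).
    """
    viromes = sorted(viromes, key=lambda v: v.key)
    if not viromes:
        raise ValueError("no viromes to cluster")
    if scope not in ("subject", "household"):
        raise ValueError("scope must be 'subject' or 'household'")
    attr = "subject_id" if scope == "subject" else "household_id"
    idents = {getattr(v.key, attr) for v in viromes}
    if len(idents) != 1:
        raise ValueError(f"viromes span multiple {scope}s: {sorted(idents)}")

    members: list[tuple[SampleKey, str]] = []
    contigs = []
    for virome in viromes:
        for contig in virome.contigs:
            members.append((virome.key, contig.contig_id))
            contigs.append(contig)
    index = HomologyIndex(
        [c for c in contigs], _CLUSTER_WORD_SIZE
    )
    lengths = index.lengths

    graph = nx.Graph()
    graph.add_nodes_from(range(len(contigs)))
    for i, contig in enumerate(contigs):
        qcodes = index.codes[i]
        for tci, diag in _candidate_diagonals(qcodes, index):
            if tci <= i:  # alignment is symmetric; visit each pair once
                continue
            score, length, n_matches = _best_segment(
                qcodes, index.codes[tci], int(diag), 1, -2
            )
            if length == 0:
                continue
            min_len = min(lengths[i], lengths[tci])
            if (
                length >= params.min_overlap * min_len
                and n_matches / length >= params.min_identity
            ):
                graph.add_edge(i, int(tci))

    clusters = []
    for component in nx.connected_components(graph):
        mem = tuple(sorted(((members[i][0], members[i][1]) for i in component)))
        presence: dict[tuple[str, TimePoint], bool] = {}
        for key, _ in mem:
            presence[(key.subject_id, key.timepoint)] = True
        earliest = min(tp.day_offset for (_, tp) in presence)
        sort_key = (earliest, tuple((k.subject_id, cid) for k, cid in mem))
        clusters.append((sort_key, mem, presence))
    clusters.sort(key=lambda c: c[0])
    return tuple(
        GlobalVirus(virus_id=f"gv{i:04d}", members=mem, presence=presence)
        for i, (_, mem, presence) in enumerate(clusters, start=1)
    )


def presence_dataframe(viruses) -> pd.DataFrame:
    """Virus x (subject, timepoint) boolean presence matrix."""
    cols = sorted({key for v in viruses for key in v.presence})
    rows = {}
    for v in viruses:
        rows[v.virus_id] = {
            f"{s}:{tp.label}": int(v.present(s, tp)) for s, tp in cols
        }
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)


def persistence_summary(viruses) -> dict:
    """Persistence of a subject's global viruses across sampling intervals.

    A virus's span is the day range between its first and last detection.
    Reported: fractions of viruses spanning >= 4 days and >= 150 days
    (detectable 5-6 months apart), plus the span histogram.
    """
    viruses = list(viruses)
    if not viruses:
        return {
            "n_viruses": 0,
            "fraction_ge_4_days": float("nan"),
            "fraction_ge_150_days": float("nan"),
            "span_histogram": {},
        }
    spans = np.array([v.span_days() for v in viruses])
    hist: dict[int, int] = {}
    for s in spans:
        hist[int(s)] = hist.get(int(s), 0) + 1
    return {
        "n_viruses": len(viruses),
        "fraction_ge_4_days": float((spans >= 4).mean()),
        "fraction_ge_150_days": float((spans >= 150).mean()),
        "span_histogram": dict(sorted(hist.items())),
    }


@dataclass(frozen=True)
class TransmissionCall:
    """One putative inter-housemate transmission with directionality."""

    household_id: str
    virus_id: str
    donor: str
    recipient: str
    donor_first: TimePoint
    recipient_first: TimePoint
    recipient_presence_count: int
    direction_class: str
    members: tuple[tuple[SampleKey, str], ...] = ()

    def __post_init__(self):
        if self.donor_first.day_offset >= self.recipient_first.day_offset:
            raise ValueError("donor must appear strictly before the recipient")
        if self.recipient_presence_count < 1:
            raise ValueError("recipient must be present at >= 1 timepoint")


@dataclass(frozen=True)
class HouseholdSharingSummary:
    """Per-household partition of global viruses into shared and member-unique."""

    household_id: str
    subjects: tuple[str, str]
    n_viruses_total: int
    n_shared: int
    n_unique_to_placebo: int
    n_unique_to_antibiotic: int

    def __post_init__(self):
        if (
            self.n_shared + self.n_unique_to_placebo + self.n_unique_to_antibiotic
            != self.n_viruses_total
        ):
            raise ValueError("shared + unique counts must partition the virus total")

    @property
    def shared_fraction(self) -> float:
        return self.n_shared / self.n_viruses_total if self.n_viruses_total else float("nan")


def _household_members(viruses) -> tuple[str, dict[str, str]]:
    """household id and subject -> treatment from the member sample keys."""
    treatments: dict[str, str] = {}
    household_ids = set()
    for v in viruses:
        for key, _ in v.members:
            household_ids.add(key.household_id)
            treatments[key.subject_id] = key.treatment
    if len(household_ids) != 1:
        raise ValueError(f"clusters span households {sorted(household_ids)}")
    return household_ids.pop(), treatments


def household_sharing(viruses) -> HouseholdSharingSummary:
    """Partition a household's global viruses into shared and member-unique sets.

    A virus is shared when detected in at least one timepoint of each
    housemate; unique viruses are attributed to their single carrier's
    treatment arm.
    """
    viruses = list(viruses)
    household_id, treatments = _household_members(viruses)
    if len(treatments) != 2:
        raise ValueError(
            f"household {household_id} has {len(treatments)} subjects with data; need 2"
        )
    n_shared = n_placebo = n_antibiotic = 0
    for v in viruses:
        carriers = v.subjects()
        if len(carriers) == 2:
            n_shared += 1
        else:
            if treatments[carriers[0]] in ANTIBIOTICS:
                n_antibiotic += 1
            else:
                n_placebo += 1
    return HouseholdSharingSummary(
        household_id=household_id,
        subjects=tuple(sorted(treatments)),
        n_viruses_total=len(viruses),
        n_shared=n_shared,
        n_unique_to_placebo=n_placebo,
        n_unique_to_antibiotic=n_antibiotic,
    )


def _direction_class(donor_treatment: str, recipient_treatment: str) -> str:
    if donor_treatment == "placebo" and recipient_treatment in ANTIBIOTICS:
        return "placebo_to_antibiotic"
    if donor_treatment in ANTIBIOTICS and recipient_treatment == "placebo":
        return "antibiotic_to_placebo"
    return "involving_control_na"


def call_transmissions(
    viruses, cohort: Cohort, min_recipient_timepoints: int = 2
) -> tuple[TransmissionCall, ...]:
    """Apply the putative-transmission rule to a household's global viruses.

    For each virus detected in both housemates, the earlier carrier is the
    donor. A call is emitted when (a) the recipient was sampled and negative
    at every visit up to and including the donor's first detection (a missing
    sample there makes absence unknowable and vetoes the call), (b) the
    recipient's first detection is strictly later, and (c) the recipient is
    positive at >= ``min_recipient_timepoints`` visits.
    """
    viruses = list(viruses)
    if not viruses:
        return ()
    _, treatments = _household_members(viruses)
    body_sites = {key.body_site for v in viruses for key, _ in v.members}
    if len(body_sites) != 1:
        raise ValueError("clusters span multiple body sites")
    site = body_sites.pop()

    calls = []
    for v in viruses:
        carriers = v.subjects()
        if len(carriers) != 2:
            continue
        firsts = {s: v.first_presence(s) for s in carriers}
        (s1, f1), (s2, f2) = sorted(firsts.items(), key=lambda kv: kv[1])
        if f1 == f2:
            continue  # tie: shared but no direction assignable
        donor, recipient = s1, s2
        sampled = set(cohort.sampled_timepoints(recipient, site))
        early = [tp for tp in TIMEPOINTS if tp.day_offset <= f1.day_offset]
        if any(tp not in sampled for tp in early):
            continue  # recipient status unknown at or before the donor's first visit
        n_recipient = len(v.present_timepoints(recipient))
        if n_recipient < min_recipient_timepoints:
            continue
        calls.append(
            TransmissionCall(
                household_id=v.members[0][0].household_id,
                virus_id=v.virus_id,
                donor=donor,
                recipient=recipient,
                donor_first=f1,
                recipient_first=f2,
                recipient_presence_count=n_recipient,
                direction_class=_direction_class(treatments[donor], treatments[recipient]),
                members=v.members,
            )
        )
    return tuple(calls)


def calls_to_dataframe(calls) -> pd.DataFrame:
    rows = [
        {
            "household": c.household_id,
            "virus_id": c.virus_id,
            "donor": c.donor,
            "recipient": c.recipient,
            "donor_first": c.donor_first.label,
            "recipient_first": c.recipient_first.label,
            "recipient_presence_count": c.recipient_presence_count,
            "direction_class": c.direction_class,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "household",
            "virus_id",
            "donor",
            "recipient",
            "donor_first",
            "recipient_first",
            "recipient_presence_count",
            "direction_class",
        ],
    )


def directionality_summary(calls, sharing_summaries) -> dict:
    """Cohort-level proportions of shared and transmitted viruses.

    Per household the denominators are its total distinct global viruses, so
    the directional parts sum to the transmission proportion and remain
    commensurable with the shared proportion. Reports mean +/- standard
    error across households.
    """
    summaries = list(sharing_summaries)
    if not summaries:
        raise ValueError("need at least one household summary")
    by_household = {s.household_id: s for s in summaries}
    rows = []
    for household_id, summary in sorted(by_household.items()):
        n_total = summary.n_viruses_total
        hh_calls = [c for c in calls if c.household_id == household_id]
        n_p2a = sum(1 for c in hh_calls if c.direction_class == "placebo_to_antibiotic")
        n_a2p = sum(1 for c in hh_calls if c.direction_class == "antibiotic_to_placebo")
        rows.append(
            {
                "household": household_id,
                "n_viruses_total": n_total,
                "shared": summary.n_shared / n_total if n_total else np.nan,
                "transmitted": len(hh_calls) / n_total if n_total else np.nan,
                "placebo_to_antibiotic": n_p2a / n_total if n_total else np.nan,
                "antibiotic_to_placebo": n_a2p / n_total if n_total else np.nan,
            }
        )
    frame = pd.DataFrame(rows)

    def mean_se(col):
        x = frame[col].to_numpy(dtype=float)
        se = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
        return float(x.mean()), se

    out = {"per_household": frame, "n_households": len(frame)}
    for col in ("shared", "transmitted", "placebo_to_antibiotic", "antibiotic_to_placebo"):
        mean, se = mean_se(col)
        out[f"{col}_mean"] = mean
        out[f"{col}_se"] = se
    return out
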