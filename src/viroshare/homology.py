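"""Pairwise virome homology search and shared-fraction tables.

Each virome is turned into an exact-word index (the analogue of a per-sample
BLAST database). A query contig is declared homologous to the indexed virome
when a seeded local alignment reaches the configured minimum length and
identity and its Karlin-Altschul E-value falls below the significance bound
(default 1e-10, the BLASTN cutoff used for inter-virome comparisons).

Because the simulator introduces substitutions only, extension is exact
optimal *ungapped* local alignment along each seeded diagonal (a cumulative
-sum formulation of the maximum-scoring-segment problem), scored match +1 /
mismatch -2. The decision contract therefore matches a gapped
Smith-Waterman search on substitution-divergent sequences while remaining
dependency-free and fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Cohort, ContigRecord, SampleKey, Virome

logger = logging.getLogger(__name__)

_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i

#: Karlin-Altschul K for ungapped +1/-2 nucleotide scoring (NCBI tabulated value).
_KA_K = 0.621


def encode_sequence(sequence: str) -> np.ndarray:
    """Map an ACGT string to a uint8 code array."""
    arr = _CODES[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


@dataclass(frozen=True)
class HomologyParams:
    """Thresholds for the seed-and-extend homology decision.

    word_size: exact-match seed length.
    min_alignment_length: shortest alignment that can count as a hit (nt).
    min_identity: minimum fraction of matching columns in the alignment.
    evalue_threshold: significance bound; a hit needs E < this value.
    match/mismatch: nucleotide scoring used for extension and E-values.
    """

    word_size: int = 11
    min_alignment_length: int = 50
    min_identity: float = 0.90
    evalue_threshold: float = 1e-10
    match: int = 1
    mismatch: int = -2

    def __post_init__(self):
        if self.word_size < 8:
            raise ValueError("word_size must be >= 8")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be positive and mismatch negative")

    @property
    def karlin_lambda(self) -> float:
        return _karlin_lambda(self.match, self.mismatch)


@lru_cache(maxsize=None)
def _karlin_lambda(match: int, mismatch: int) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform base frequencies."""

    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-9, 10.0))


def evalue(score: int, query_length: int, database_length: int, params: HomologyParams) -> float:
    """Karlin-Altschul E = K * m * n * exp(-lambda * S)."""
    return float(
        _KA_K * query_length * database_length * np.exp(-params.karlin_lambda * score)
    )


@dataclass(frozen=True)
class Hit:
    """Best alignment summary for one query contig against an index."""

    target_id: str
    score: int
    alignment_length: int
    n_matches: int
    evalue: float

    @property
    def identity(self) -> float:
        return self.n_matches / self.alignment_length


class HomologyIndex:
    """Exact-word seed index over one set of target contigs."""

    def __init__(self, contigs: list[ContigRecord], word_size: int):
        if not contigs:
            raise ValueError("cannot index an empty contig set")
        self.word_size = word_size
        self.contig_ids: tuple[str, ...] = tuple(c.contig_id for c in contigs)
        self.codes: list[np.ndarray] = [encode_sequence(c.sequence) for c in contigs]
        self.lengths = np.array([len(c) for c in self.codes], dtype=np.int64)
        self.total_length = int(self.lengths.sum())
        self.max_length = int(self.lengths.max())

        words = []
        contig_idx = []
        positions = []
        for i, codes in enumerate(self.codes):
            w = _words(codes, word_size)
            words.append(w)
            contig_idx.append(np.full(len(w), i, dtype=np.int64))
            positions.append(np.arange(len(w), dtype=np.int64))
        # unsorted concatenation doubles as the query-side word pack
        self._q_words = np.concatenate(words)
        self._q_contig = np.concatenate(contig_idx)
        self._q_pos = np.concatenate(positions)
        order = np.argsort(self._q_words, kind="stable")
        self._sorted_words = self._q_words[order]
        self._word_contig = self._q_contig[order]
        self._word_pos = self._q_pos[order]
        self._offsets: np.ndarray | None = None

    def ensure_offsets(self) -> None:
        """Build a direct-address bucket table (word value -> sorted-row range).

        Speeds repeated lookups against this index; ~4^word_size int64 slots,
        so it is built lazily and only for practical word sizes.
        """
        if self._offsets is None and 4 ** self.word_size <= 1 << 26:
            n_slots = 4 ** self.word_size
            counts = np.bincount(self._sorted_words, minlength=n_slots)
            offsets = np.zeros(n_slots + 1, dtype=np.int64)
            np.cumsum(counts, out=offsets[1:])
            self._offsets = offsets

    def drop_offsets(self) -> None:
        self._offsets = None


def _words(codes: np.ndarray, word_size: int) -> np.ndarray:
    if len(codes) < word_size:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, word_size).astype(np.int64)
    weights = 4 ** np.arange(word_size - 1, -1, -1, dtype=np.int64)
    return windows @ weights


def _multi_arange(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate arange(start, start+count) for each pair, vectorised."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    steps = np.ones(total, dtype=np.int64)
    ends = np.cumsum(counts)
    steps[0] = starts[0]
    steps[ends[:-1]] = starts[1:] - (starts[:-1] + counts[:-1]) + 1
    return np.cumsum(steps)


def build_index(virome: Virome, params: HomologyParams) -> HomologyIndex:
    """Index a non-empty virome's contigs for seeded search."""
    if virome.n_contigs == 0:
        raise ValueError(f"cannot index empty virome {virome.key.label}")
    return HomologyIndex(list(virome.contigs), params.word_size)


def _candidate_diagonals(qcodes: np.ndarray, index: HomologyIndex) -> np.ndarray:
    """Unique (target_contig, diagonal) pairs sharing >=1 exact word with the query."""
    qw = _words(qcodes, index.word_size)
    if len(qw) == 0:
        return np.empty((0, 2), dtype=np.int64)
    lo = np.searchsorted(index._sorted_words, qw, side="left")
    hi = np.searchsorted(index._sorted_words, qw, side="right")
    counts = hi - lo
    nz = counts > 0
    if not nz.any():
        return np.empty((0, 2), dtype=np.int64)
    rows = _multi_arange(lo[nz], counts[nz])
    qpos = np.repeat(np.arange(len(qw), dtype=np.int64)[nz], counts[nz])
    tci = index._word_contig[rows]
    diag = index._word_pos[rows] - qpos
    span = index.max_length + len(qcodes) + 1
    key = tci * (2 * span) + (diag + len(qcodes))
    uniq = np.unique(key)
    out = np.empty((len(uniq), 2), dtype=np.int64)
    out[:, 0] = uniq // (2 * span)
    out[:, 1] = uniq % (2 * span) - len(qcodes)
    return out


def _best_segment(qcodes: np.ndarray, tcodes: np.ndarray, diag: int,
                  match: int, mismatch: int) -> tuple[int, int, int]:
    """Optimal ungapped local alignment on one diagonal.

    Returns (score, alignment_length, n_matches) of the maximum-scoring
    segment of the match/mismatch score sequence along the diagonal
    (query position q aligns to target position q + diag).
    """
    qs = max(0, -diag)
    qe = min(len(qcodes), len(tcodes) - diag)
    if qe <= qs:
        return 0, 0, 0
    eq = qcodes[qs:qe] == tcodes[qs + diag:qe + diag]
    scores = np.where(eq, match, mismatch).astype(np.int64)
    prefix = np.concatenate(([0], np.cumsum(scores)))
    best_prefix = np.minimum.accumulate(prefix[:-1])
    ending = prefix[1:] - best_prefix
    j = int(np.argmax(ending))
    score = int(ending[j])
    if score <= 0:
        return 0, 0, 0
    i = int(np.argmin(prefix[: j + 1]))
    length = j - i + 1
    n_matches = int(eq[i:j + 1].sum())
    return score, length, n_matches


def _passes(hit: Hit, params: HomologyParams) -> bool:
    return (
        hit.alignment_length >= params.min_alignment_length
        and hit.identity >= params.min_identity
        and hit.evalue < params.evalue_threshold
    )


def contig_has_homologue(
    contig: ContigRecord, index: HomologyIndex, params: HomologyParams
) -> tuple[bool, Hit | None]:
    """Decide whether a contig has a significant homologue in the index.

    Returns the decision plus the best passing hit (or the best-scoring
    candidate when nothing passes; None without any seeded candidate).
    """
    qcodes = encode_sequence(contig.sequence)
    best: Hit | None = None
    best_passing: Hit | None = None
    for tci, diag in _candidate_diagonals(qcodes, index):
        score, length, n_matches = _best_segment(
            qcodes, index.codes[tci], int(diag), params.match, params.mismatch
        )
        if score <= 0:
            continue
        hit = Hit(
            target_id=index.contig_ids[tci],
            score=score,
            alignment_length=length,
            n_matches=n_matches,
            evalue=evalue(score, len(qcodes), index.total_length, params),
        )
        if best is None or hit.score > best.score:
            best = hit
        if _passes(hit, params) and (
            best_passing is None or hit.score > best_passing.score
        ):
            best_passing = hit
    if best_passing is not None:
        return True, best_passing
    return False, best


def _pair_candidates(qpack: HomologyIndex, tindex: HomologyIndex):
    """Candidate (query contig, target contig, diagonal, n_seeds) quadruples
    for one ordered virome pair, one batched lookup for the whole pair.

    Candidates are ordered by query contig, then by seed count descending,
    so evaluation can stop at the first passing hit per query contig.
    """
    qwords = qpack._sorted_words  # sorted queries keep the lookup cache-friendly
    if tindex._offsets is not None:
        lo = tindex._offsets[qwords]
        hi = tindex._offsets[qwords + 1]
    else:
        lo = np.searchsorted(tindex._sorted_words, qwords, side="left")
        hi = np.searchsorted(tindex._sorted_words, qwords, side="right")
    counts = hi - lo
    nz = counts > 0
    if not nz.any():
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty, empty
    reps = counts[nz]
    rows = _multi_arange(lo[nz], reps)
    word_idx = np.repeat(np.nonzero(nz)[0], reps)
    qc = qpack._word_contig[word_idx]
    qpos = qpack._word_pos[word_idx]
    tc = tindex._word_contig[rows]
    diag = tindex._word_pos[rows] - qpos
    span = 2 * (tindex.max_length + qpack.max_length + 1)
    key = (qc * len(tindex.contig_ids) + tc) * span + (diag + qpack.max_length)
    uniq, n_seeds = np.unique(key, return_counts=True)
    diag_u = uniq % span - qpack.max_length
    rest = uniq // span
    tc_u = rest % len(tindex.contig_ids)
    qc_u = rest // len(tindex.contig_ids)
    order = np.lexsort((-n_seeds, qc_u))
    return qc_u[order], tc_u[order], diag_u[order], n_seeds[order]


def _flags_between(qpack: HomologyIndex, tindex: HomologyIndex, params: HomologyParams) -> np.ndarray:
    """Boolean hit flag per query contig of one virome against another's index."""
    flags = np.zeros(len(qpack.contig_ids), dtype=bool)
    qc, tc, diag, _ = _pair_candidates(qpack, tindex)
    for i in range(len(qc)):
        q = qc[i]
        if flags[q]:
            continue
        score, length, n_matches = _best_segment(
            qpack.codes[q], tindex.codes[tc[i]], int(diag[i]), params.match, params.mismatch
        )
        if (
            length >= params.min_alignment_length
            and n_matches / max(length, 1) >= params.min_identity
            and evalue(score, len(qpack.codes[q]), tindex.total_length, params)
            < params.evalue_threshold
        ):
            flags[q] = True
    return flags


def contig_hit_flags(query: Virome, index: HomologyIndex, params: HomologyParams) -> np.ndarray:
    """Boolean hit flag per query contig (in the virome's sorted contig order)."""
    qpack = build_index(query, params)
    return _flags_between(qpack, index, params)


@dataclass(frozen=True)
class SharedFractionRecord:
    """Fraction of one virome's contigs with a homologue in another virome."""

    query_key: SampleKey
    target_key: SampleKey
    n_query_contigs: int
    n_query_with_hit: int

    def __post_init__(self):
        if not 0 <= self.n_query_with_hit <= self.n_query_contigs:
            raise ValueError("hit count out of range")

    @property
    def fraction(self) -> float:
        return self.n_query_with_hit / self.n_query_contigs


@dataclass(frozen=True)
class SharedFractionTable:
    """Shared-fraction records for every ordered pair of viromes at one site."""

    body_site: str
    keys: tuple[SampleKey, ...]
    records: dict[tuple[SampleKey, SampleKey], SharedFractionRecord]

    def __post_init__(self):
        for qk in self.keys:
            for tk in self.keys:
                if (qk, tk) not in self.records:
                    raise ValueError(
                        f"incomplete table: missing pair {qk.label} -> {tk.label}"
                    )

    def record(self, query_key: SampleKey, target_key: SampleKey) -> SharedFractionRecord:
        return self.records[(query_key, target_key)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (qk, tk), rec in sorted(self.records.items()):
            rows.append(
                {
                    "query_subject": qk.subject_id,
                    "query_timepoint": qk.timepoint.label,
                    "target_subject": tk.subject_id,
                    "target_timepoint": tk.timepoint.label,
                    "body_site": self.body_site,
                    "n_query": rec.n_query_contigs,
                    "n_hit": rec.n_query_with_hit,
                    "fraction": rec.fraction,
                }
            )
        return pd.DataFrame(rows)


class HitFlagTable:
    """Per-contig homology flags for all ordered virome pairs at one body site.

    This is the cached product the downstream modules reuse: the permutation
    test resamples contigs against these flags, and the shared-fraction table
    is a row summary of them.
    """

    def __init__(
        self,
        body_site: str,
        viromes: dict[SampleKey, Virome],
        flags: dict[tuple[SampleKey, SampleKey], np.ndarray],
    ):
        self.body_site = body_site
        self.viromes = dict(sorted(viromes.items()))
        self.flags = flags
        self.keys: tuple[SampleKey, ...] = tuple(self.viromes)

    def flag_array(self, query_key: SampleKey, target_key: SampleKey) -> np.ndarray:
        return self.flags[(query_key, target_key)]

    def to_shared_fraction_table(self) -> SharedFractionTable:
        records = {}
        for (qk, tk), arr in self.flags.items():
            records[(qk, tk)] = SharedFractionRecord(
                query_key=qk,
                target_key=tk,
                n_query_contigs=len(arr),
                n_query_with_hit=int(arr.sum()),
            )
        return SharedFractionTable(self.body_site, self.keys, records)

    def to_dataframe(self) -> pd.DataFrame:
        """Compact serialisation: one row per ordered pair, flags as a 0/1 string."""
        rows = []
        for (qk, tk), arr in sorted(self.flags.items()):
            rows.append(
                {
                    "query_subject": qk.subject_id,
                    "query_timepoint": qk.timepoint.label,
                    "target_subject": tk.subject_id,
                    "target_timepoint": tk.timepoint.label,
                    "body_site": self.body_site,
                    "flags": "".join("1" if f else "0" for f in arr),
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, cohort: Cohort) -> "HitFlagTable":
        sites = set(frame["body_site"])
        if len(sites) != 1:
            raise ValueError(f"expected a single body site, got {sorted(sites)}")
        body_site = sites.pop()
        by_label = {
            (k.subject_id, k.timepoint.label): k
            for k in cohort.viromes
            if k.body_site == body_site
        }
        viromes: dict[SampleKey, Virome] = {}
        flags: dict[tuple[SampleKey, SampleKey], np.ndarray] = {}
        for row in frame.itertuples(index=False):
            qk = by_label[(row.query_subject, row.query_timepoint)]
            tk = by_label[(row.target_subject, row.target_timepoint)]
            viromes[qk] = cohort.viromes[qk]
            viromes[tk] = cohort.viromes[tk]
            flags[(qk, tk)] = np.array([c == "1" for c in row.flags], dtype=bool)
        return cls(body_site, viromes, flags)


def shared_fraction(query: Virome, target: Virome, params: HomologyParams) -> SharedFractionRecord:
    """Fraction of query contigs with a significant homologue in the target virome."""
    if query.n_contigs == 0 or target.n_contigs == 0:
        raise ValueError("shared_fraction requires two non-empty viromes")
    index = build_index(target, params)
    flags = contig_hit_flags(query, index, params)
    return SharedFractionRecord(
        query_key=query.key,
        target_key=target.key,
        n_query_contigs=query.n_contigs,
        n_query_with_hit=int(flags.sum()),
    )


def all_pairs_hit_flags(
    cohort: Cohort, body_site: str, params: HomologyParams
) -> HitFlagTable:
    """Per-contig hit flags for every ordered pair of non-missing viromes at a site."""
    viromes = {v.key: v for v in cohort.viromes_at(body_site)}
    if len(viromes) < 2:
        raise ValueError(
            f"need >=2 non-missing viromes at {body_site}, found {len(viromes)}"
        )
    skipped = [k for k in cohort.missing_samples if k.body_site == body_site]
    if skipped:
        logger.info(
            "excluding %d missing %s samples from all-pairs comparison", len(skipped), body_site
        )
    indexes = {key: build_index(v, params) for key, v in viromes.items()}
    flags: dict[tuple[SampleKey, SampleKey], np.ndarray] = {}
    for tk in viromes:
        tindex = indexes[tk]
        tindex.ensure_offsets()
        for qk in viromes:
            flags[(qk, tk)] = _flags_between(indexes[qk], tindex, params)
        tindex.drop_offsets()
    return HitFlagTable(body_site, viromes, flags)


def all_pairs_shared(
    cohort: Cohort, body_site: str, params: HomologyParams
) -> SharedFractionTable:
    """Complete ordered-pair shared-fraction table for one body site."""
    return all_pairs_hit_flags(cohort, body_site, params).to_shared_fraction_table()
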