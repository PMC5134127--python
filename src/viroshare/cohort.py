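"""Data model and I/O for longitudinal household virome cohorts.

A cohort is a set of specimens, each identified by subject, household, body
site, and sampling time point. Every specimen carries the assembled viral
contigs recovered from it. Households contain one or two subjects; in
two-person households one member received an antibiotic (amoxicillin or
azithromycin) and the other a placebo, while singleton "control" households
received no therapy.

Contigs shorter than 200 nt or containing ambiguous characters are excluded
from analysis, so the model enforces that filter at load time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BODY_SITES = ("feces", "saliva")
TREATMENTS = ("placebo", "amoxicillin", "azithromycin", "none")
ANTIBIOTICS = ("amoxicillin", "azithromycin")

MIN_CONTIG_LENGTH = 200

#: Fixed label -> days-since-day0 mapping for the five sampling visits.
DAY_OFFSETS = {"day0": 0, "day3": 3, "day7": 7, "week8": 56, "month6": 182}

_VALID_SEQ = re.compile(r"^[ACGT]+$")

METADATA_COLUMNS = (
    "subject_id",
    "household_id",
    "body_site",
    "timepoint",
    "treatment",
    "fasta_file",
)


@dataclass(frozen=True, order=True)
class TimePoint:
    """One of the five sampling visits, ordered by days since day 0."""

    day_offset: int
    label: str

    def __init__(self, label: str):
        if label not in DAY_OFFSETS:
            raise ValueError(
                f"unknown timepoint label {label!r}; expected one of {sorted(DAY_OFFSETS)}"
            )
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "day_offset", DAY_OFFSETS[label])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TimePoint({self.label!r})"


#: All five visits in chronological order.
TIMEPOINTS = tuple(TimePoint(label) for label in DAY_OFFSETS)


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one specimen: who, where on the body, and when."""

    subject_id: str
    household_id: str
    body_site: str
    timepoint: TimePoint
    treatment: str

    def __post_init__(self):
        if self.body_site not in BODY_SITES:
            raise ValueError(f"body_site must be one of {BODY_SITES}, got {self.body_site!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")

    @property
    def label(self) -> str:
        return f"{self.subject_id}:{self.body_site}:{self.timepoint.label}"


@dataclass(frozen=True)
class ContigRecord:
    """A single assembled contig: unique id plus an unambiguous ACGT sequence."""

    contig_id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < MIN_CONTIG_LENGTH:
            raise ValueError(
                f"contig {self.contig_id!r} is {len(self.sequence)} nt; "
                f"minimum is {MIN_CONTIG_LENGTH}"
            )
        if not _VALID_SEQ.match(self.sequence):
            raise ValueError(f"contig {self.contig_id!r} contains non-ACGT characters")

    def __len__(self) -> int:
        return len(self.sequence)


def contig_passes_filter(sequence: str) -> bool:
    """True if a raw sequence survives the length/ambiguity contig filter."""
    return len(sequence) >= MIN_CONTIG_LENGTH and bool(_VALID_SEQ.match(sequence))


@dataclass(frozen=True)
class Virome:
    """One specimen's contig set. Contigs are kept sorted by id for determinism."""

    key: SampleKey
    contigs: tuple[ContigRecord, ...]

    def __post_init__(self):
        ordered = tuple(sorted(self.contigs, key=lambda c: c.contig_id))
        object.__setattr__(self, "contigs", ordered)
        ids = [c.contig_id for c in ordered]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate contig ids in virome {self.key.label}: {dupes}")

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(c.contig_id for c in self.contigs)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)


@dataclass(frozen=True)
class Cohort:
    """All viromes of a study plus the sample keys that were never collected."""

    viromes: dict[SampleKey, Virome] = field(default_factory=dict)
    missing_samples: frozenset[SampleKey] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "missing_samples", frozenset(self.missing_samples))
        for key, virome in self.viromes.items():
            if key != virome.key:
                raise ValueError(f"virome stored under mismatched key {key.label}")
            if key in self.missing_samples:
                raise ValueError(f"sample {key.label} is both present and flagged missing")
            if virome.n_contigs == 0:
                raise ValueError(f"non-missing sample {key.label} has no contigs")
        self._validate_households()

    def _validate_households(self) -> None:
        members: dict[str, set[str]] = {}
        treatments: dict[str, str] = {}
        for key in list(self.viromes) + list(self.missing_samples):
            members.setdefault(key.household_id, set()).add(key.subject_id)
            prev = treatments.setdefault(key.subject_id, key.treatment)
            if prev != key.treatment:
                raise ValueError(f"subject {key.subject_id} has inconsistent treatments")
        for household, subjects in members.items():
            if not 1 <= len(subjects) <= 2:
                raise ValueError(
                    f"household {household} has {len(subjects)} subjects; expected 1 or 2"
                )
            arms = sorted(treatments[s] for s in subjects)
            if len(subjects) == 1:
                if arms[0] not in ("none", "placebo"):
                    # singleton households are untreated controls
                    raise ValueError(
                        f"singleton household {household} has treatment {arms[0]!r}"
                    )
            else:
                if arms[0] not in ANTIBIOTICS or arms[1] != "placebo":
                    raise ValueError(
                        f"two-person household {household} must pair an antibiotic with "
                        f"placebo; got {arms}"
                    )

    # -- accessors -------------------------------------------------------

    def sample_keys(self) -> tuple[SampleKey, ...]:
        return tuple(sorted(self.viromes))

    def viromes_at(self, body_site: str) -> tuple[Virome, ...]:
        return tuple(
            self.viromes[k] for k in self.sample_keys() if k.body_site == body_site
        )

    def subjects(self) -> tuple[str, ...]:
        seen = {k.subject_id for k in self.viromes} | {
            k.subject_id for k in self.missing_samples
        }
        return tuple(sorted(seen))

    def households(self) -> dict[str, tuple[str, ...]]:
        """household_id -> sorted subject ids."""
        members: dict[str, set[str]] = {}
        for key in list(self.viromes) + list(self.missing_samples):
            members.setdefault(key.household_id, set()).add(key.subject_id)
        return {h: tuple(sorted(s)) for h, s in sorted(members.items())}

    def two_person_households(self) -> dict[str, tuple[str, str]]:
        return {h: s for h, s in self.households().items() if len(s) == 2}

    def subject_treatment(self, subject_id: str) -> str:
        for key in list(self.viromes) + list(self.missing_samples):
            if key.subject_id == subject_id:
                return key.treatment
        raise KeyError(subject_id)

    def subject_household(self, subject_id: str) -> str:
        for key in list(self.viromes) + list(self.missing_samples):
            if key.subject_id == subject_id:
                return key.household_id
        raise KeyError(subject_id)

    def subject_viromes(self, subject_id: str, body_site: str) -> tuple[Virome, ...]:
        """Non-missing viromes of one subject at one site, chronological order."""
        keys = sorted(
            (k for k in self.viromes if k.subject_id == subject_id and k.body_site == body_site),
            key=lambda k: k.timepoint,
        )
        return tuple(self.viromes[k] for k in keys)

    def sampled_timepoints(self, subject_id: str, body_site: str) -> tuple[TimePoint, ...]:
        return tuple(v.key.timepoint for v in self.subject_viromes(subject_id, body_site))


# -- I/O ----------------------------------------------------------------


def _fasta_name(key: SampleKey) -> str:
    return f"{key.subject_id}_{key.body_site}_{key.timepoint.label}.fasta"


def read_cohort(metadata_path: str | Path, fasta_dir: str | Path | None = None) -> Cohort:
    """Load a cohort from a metadata TSV plus per-sample contig FASTA files.

    The metadata table must carry the columns ``subject_id, household_id,
    body_site, timepoint, treatment, fasta_file``; an empty ``fasta_file``
    flags the sample as missing. FASTA paths are resolved relative to
    ``fasta_dir`` (default: the metadata file's directory). Contigs failing
    the length/ambiguity filter are dropped with a logged count.
    """
    metadata_path = Path(metadata_path)
    base = Path(fasta_dir) if fasta_dir is not None else metadata_path.parent
    table = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(METADATA_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"metadata is missing columns {sorted(missing_cols)}")

    viromes: dict[SampleKey, Virome] = {}
    missing: set[SampleKey] = set()
    n_dropped = 0
    for row_no, row in enumerate(table.itertuples(index=False), start=2):
        try:
            key = SampleKey(
                subject_id=row.subject_id,
                household_id=row.household_id,
                body_site=row.body_site,
                timepoint=TimePoint(row.timepoint),
                treatment=row.treatment,
            )
        except ValueError as exc:
            raise ValueError(f"malformed metadata row {row_no}: {exc}") from exc
        if key in viromes or key in missing:
            raise ValueError(f"duplicate sample key at metadata row {row_no}: {key.label}")
        if not row.fasta_file:
            missing.add(key)
            continue
        fasta_path = base / row.fasta_file
        if not fasta_path.exists():
            raise FileNotFoundError(
                f"metadata row {row_no}: FASTA file not found: {fasta_path}"
            )
        contigs = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            seq = str(rec.seq).upper()
            if contig_passes_filter(seq):
                contigs.append(ContigRecord(rec.id, seq))
            else:
                n_dropped += 1
        viromes[key] = Virome(key, tuple(contigs))
    if n_dropped:
        logger.info("dropped %d contigs failing the length/ambiguity filter", n_dropped)
    return Cohort(viromes=viromes, missing_samples=frozenset(missing))


def write_cohort(cohort: Cohort, out_dir: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write a cohort as ``metadata.tsv`` plus one 80-column FASTA per sample.

    Returns a mapping of emitted logical names to paths. Missing samples get
    a metadata row with an empty ``fasta_file`` and no FASTA on disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_path = out_dir / "metadata.tsv"
    if meta_path.exists() and not overwrite:
        raise FileExistsError(f"{meta_path} exists; pass overwrite=True to replace")

    rows = []
    paths: dict[str, Path] = {"metadata": meta_path}
    all_keys = sorted(list(cohort.viromes) + list(cohort.missing_samples))
    for key in all_keys:
        is_missing = key in cohort.missing_samples
        fasta_file = "" if is_missing else _fasta_name(key)
        rows.append(
            {
                "subject_id": key.subject_id,
                "household_id": key.household_id,
                "body_site": key.body_site,
                "timepoint": key.timepoint.label,
                "treatment": key.treatment,
                "fasta_file": fasta_file,
            }
        )
        if is_missing:
            continue
        fasta_path = out_dir / fasta_file
        if fasta_path.exists() and not overwrite:
            raise FileExistsError(f"{fasta_path} exists; pass overwrite=True to replace")
        records = [
            SeqRecord(Seq(c.sequence), id=c.contig_id, description="")
            for c in cohort.viromes[key].contigs
        ]
        with open(fasta_path, "w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=80)
            writer.write_file(records)
        paths[key.label] = fasta_path

    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        meta_path, sep="\t", index=False
    )
    return paths
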