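# Methods

## Overview

`viroshare` analyses longitudinal virome contig sets from a household cohort:
who shares viruses with whom, how long viruses persist in a subject, and
which presence/absence patterns between housemates look like transmissions.
The pipeline consumes assembled contigs (one FASTA per subject × body site ×
visit) plus a metadata table, and is exercised end-to-end on a synthetic
cohort generator with planted, machine-readable ground truth.

The study design modelled throughout is fixed: five visits (day 0, day 3,
day 7, week 8, month 6 — day offsets 0/3/7/56/182), two body sites (feces,
saliva), eight two-person households in which one member takes an antibiotic
(amoxicillin or azithromycin) and the other a placebo, plus four untreated
singleton controls. Week-8 and month-6 day offsets are calendar conventions
(56 and 182 days) chosen so interval thresholds such as "at least 4 days
apart" and "5-6 months" are computable.

## Homology engine

Per-virome comparison mirrors an all-pairs BLASTN protocol: each virome is
indexed, and a query contig counts as *shared* if it has at least one
significant local alignment in the target virome.

The engine is a self-contained seed-and-extend search:

* exact-word seeds (default word size 11) located via a sorted word index
  (a direct-address bucket table accelerates repeated lookups);
* on every seeded (target contig, diagonal), the exact optimal *ungapped*
  local alignment is computed by a maximum-scoring-segment scan (cumulative
  sums with a running prefix minimum), scored match +1 / mismatch -2;
* a hit requires alignment length >= 50 nt, identity >= 0.90, and
  Karlin-Altschul E-value `E = K·m·n·exp(-lambda·S) < 1e-10`, with lambda
  solved from the scoring scheme (1.33 for +1/-2), K = 0.621, and the
  database size n equal to the total target virome length.

Only the E-value bound is anchored to the comparison protocol the analysis
reproduces; word size, minimum length and identity are conventions chosen to
be permissive at the simulator's divergence scales (<= a few percent). The
ungapped extension is exact for substitution-only divergence, which is what
the generator produces; the test suite checks decision-level equivalence
against a full Smith-Waterman oracle (biotite) on randomized mini-cohorts.
A known, accepted heuristic gap: an alignment at exactly 90% identity with
adversarially even mismatch spacing can lack an 11-mer seed; random
substitution processes essentially never produce this.

## Distances and ordination

For an unordered virome pair the Sørensen similarity is
`(hits A->B + hits B->A) / (n_A + n_B)` — the classic `2C/(S1+S2)` when hits
are reciprocal — on a 0 (no sharing) to 1 (identical viromes) scale. The
Bray-Curtis dissimilarity used for ordination is exactly `1 - Sørensen` with
a zero diagonal.

PCoA is classical metric MDS: double-centre `-D²/2`, eigendecompose, scale
eigenvectors by the square root of their eigenvalues. Axes with negative
eigenvalues are dropped (and logged); the negative eigenvalues themselves
are still reported for diagnostics. No Lingoes/Cailliez correction is
applied, so coordinates are always real-valued. Proportions explained are
taken over the positive eigenvalue total.

The within- vs between-household comparison pools *all* cross-subject sample
pairs (every timepoint combination), excludes same-subject pairs, and tests
the two groups with a two-sided Mann-Whitney U: exact enumeration when both
groups have <= 8 tie-free values, tie-corrected normal approximation
otherwise. Pooling per pair (rather than averaging per household first)
maximizes use of the matrix; the choice matters only for the standard errors
of the group means.

## Overlap permutation test

For a subject, each of N iterations (default 10,000) draws

* `w_i`: the percent of `n` randomly sampled contigs (default n = 1,000;
  without replacement when the virome is large enough, with replacement
  otherwise) from one of the subject's viromes with a homologue in a second,
  distinct random visit of the same subject;
* `b_i`: the same quantity across random visits of two distinct randomly
  chosen subjects;

and reports `p = #{i : b_i >= w_i} / N` with the mean ± sd of both draw
sets. Ties count toward the null, making the test conservative. A p of zero
is printed as `< 1/N` and stored as 0.0. The household-level variant draws
`w_i` from cross-subject pairs inside one household and `b_i` from
cross-subject pairs spanning two different households. No multiple-testing
correction is applied across subjects.

**Calibration caveat (important).** The paired statistic estimates
`P(B >= W | data)`, the overlap probability between two *distributions* of
pair fractions. Under an exchangeable null this quantity concentrates near
0.5 (empirically sd ≈ 0.10) instead of being uniform: the test is markedly
conservative, with a null rejection rate at the 0.05 level near zero, and
its p-values are not uniformly distributed. This is a property of the
statistic itself, not of any implementation choice; the test suite measures
it. Under genuine separation (within-subject sharing far above
between-subject sharing) p still collapses below 1/N, so power in the
intended regime is unaffected.

## Global viruses, persistence, sharing, transmissions

Contigs from all visits of a subject (or of both members of a household) are
clustered by single linkage: two contigs link when a local alignment covers
at least 50% of the shorter contig at >= 98% identity — the stringency used
to discriminate highly related viral sequences. Connected components are
"global viruses" with a presence/absence profile per (subject, visit).
Cluster ids are deterministic (ordered by earliest visit, then smallest
member) and invariant to input order. Note that a genome emitted as two
non-overlapping fragments legitimately yields two clusters; downstream
proportions are unaffected, and truth-based scoring deduplicates by event.

*Persistence*: a virus's span is the day range between first and last
detection; reported are the fractions of a subject's viruses with span
>= 4 days and >= 150 days, plus the span histogram. Missing visits simply
contribute no detections.

*Household sharing*: a virus is shared when detected in >= 1 visit of each
housemate; unique viruses are attributed to their carrier's treatment arm.
Shared + unique-placebo + unique-antibiotic always partitions the household
total (a tested invariant).

*Putative transmission rule*: for a shared virus, the earlier carrier is the
donor; a call requires (a) the recipient sampled and negative at every visit
up to and including the donor's first detection — a missing sample there
makes absence unknowable and vetoes the call, (b) the recipient's first
detection strictly later, and (c) the recipient positive at >= 2 visits.
First detections at the same visit are shared-but-tied: no direction is
assignable. Direction is classed placebo→antibiotic or antibiotic→placebo
from the treatment arms. The >= 2-visit floor is configurable
(`min_recipient_timepoints`) because a single-late-visit appearance,
however suggestive, fails the rule by definition.

*Directionality summary*: per household, proportions are over its total
distinct global viruses, so the directional parts sum to the transmission
proportion and stay commensurable with the shared proportion; the cohort
summary is the mean ± standard error across households.

## Synthetic cohort generator

Each virus is an ancestral uniform-random genome (default 500-1,500 nt).
Per subject and visit-to-visit step, presence follows a two-state Markov
chain and sequences accumulate substitutions (default 0.002/base/step,
substitution-only so identity thresholds stay analytically predictable).
Genomes are emitted per sample as (default) two non-overlapping fragments
>= 200 nt with independently re-drawn breakpoints, so clustering must merge
fragments across visits. Three virus classes:

* **core** (default 18/subject, retention 0.85/step, reacquisition 0.005):
  founded present at day 0; of these, 8 are *household-shared* — the same
  ancestral genome founded in both housemates (identical at day 0, diverging
  independently afterwards).
* **background pool** (default 300 environment-wide viruses, day-0 presence
  0.06, retention 0.45, reacquisition 0.005): sparse, flickering
  acquisitions producing the low between-subject sharing baseline.
* **planted transmissions** (Poisson, default mean 7/household, 75% from the
  placebo member toward the antibiotic member): a donor-personal virus is
  copied into the recipient at a random later visit; the recipient is forced
  present at that visit and the next (guaranteeing the rule can recover the
  event) and follows retention dynamics afterwards.

Missing samples are Bernoulli per (subject, visit, site), default 0.02, and
the study configuration additionally removes one household's month-6
visit entirely. A non-missing sample that would be empty is given one
fallback virus (vanishingly rare under the defaults). Everything is driven
by one seeded generator, so equal seeds give byte-identical FASTA output.

Default dynamics were tuned once, by simulation, to the regimes the analysis
assumes, and then frozen: realized fecal within-subject shared fractions
~0.70 (target band 0.20-0.75), between-subject ~0.02 (band 0.01-0.17),
household-shared proportion ~0.24, transmitted ~0.10 with a ~7.5%/2.5%
directional split. Two classes of retention are genuinely necessary: a
single retention parameter cannot express persistent personal cores
alongside transient environmental exposure, and the transience of the
background pool is also what keeps coincidental housemate
acquisition patterns (false-positive transmissions) rare.

**What the generator does not emulate.** Contig abundance structure: real
persistent viruses assemble into many more contigs than transient ones, so
contig-weighted sharing and virus-weighted persistence decouple in real
data. With a fixed two fragments per virus the two statistics are coupled,
and the default cohort's virus-level persistence (~50% at >= 4 days) sits
below the contig-rich empirical regime (> 70%) even while the sharing
magnitudes match. Passing tests therefore demonstrate correct recovery of
planted structure under this generative model, not distributional realism of
read-level virome assembly; no attempt is made to model antibiotic
pharmacology (treatment arms are labels for directionality bookkeeping),
within-host recombination, indels, or contamination.

## Numerical and degenerate-input conventions

* Word encoding is A,C,G,T -> 0..3; any other character is rejected at the
  data-model boundary (contigs < 200 nt or with ambiguous characters are
  dropped on load, with a logged count).
* The maximum-scoring-segment scan breaks score ties toward the earliest
  end position; clustering and cluster ids are independent of contig input
  order (tested).
* Empty viromes cannot be indexed or compared; missing samples are excluded
  from all-pairs tables and logged.
* PCoA eigenvalues within 1e-10 of zero are treated as zero.
* Mann-Whitney switches to the exact method only for tie-free groups of
  <= 8; otherwise the tie-corrected normal approximation is used (agreement
  within 0.02 for tie-free groups of 5-8, tested).
* p = 0 permutation results are stored as 0.0 and printed as `< 1/N`.
* Standard errors across households use ddof = 1.

## Problem sizes

Defaults were chosen so a full fecal analysis of the 20-subject cohort
(~95 viromes, ~60 contigs each) completes in a few minutes on one CPU:
all-pairs homology ~0.5-1 min, 10,000-iteration permutation tests a few
seconds per cohort, clustering a few seconds per household. The acceptance
checks scale the same code down (e.g. 500-iteration permutation runs for
the 200-cohort null calibration) rather than switching algorithms.
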