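# viroshare

Sharing, persistence, and transmission of viruses in household viromes.

People who live together share more than bacteria: bacteriophage-dominated
gut and oral viromes overlap between housemates, and presence/absence
patterns over time can reveal putative virus transmissions from one
household member to the other. `viroshare` implements, as a tested
pipeline, the contig-level analysis behind that kind of longitudinal
household study:

* **all-pairs virome homology** — a self-contained seed-and-extend
  nucleotide search (Karlin–Altschul E < 10⁻¹⁰, match +1 / mismatch −2)
  standing in for per-virome BLASTN databases, yielding the fraction of
  each virome's contigs with a homologue in every other virome;
* **beta diversity** — Sørensen similarity `2C/(S₁+S₂)` computed from
  reciprocal hit counts, its Bray–Curtis complement, classical PCoA, and a
  Mann–Whitney U comparison of within- vs between-household similarities;
* **overlap permutation test** — resampling test (default 10,000
  iterations × 1,000 contigs) of whether a subject's virome overlaps itself
  across time more than it overlaps other subjects, with an empirical
  p-value `p = #{bᵢ ≥ wᵢ}/N`, plus a household-level variant;
* **global-virus tracking** — single-linkage clustering of contigs at
  ≥ 98% identity over ≥ 50% of the shorter contig into "global viruses",
  persistence spans, household sharing proportions, and the
  putative-transmission rule (present in one housemate, absent in the
  other up to the carrier's first visit, later present in ≥ 2 of the
  other's visits) with placebo→antibiotic / antibiotic→placebo
  directionality;
* **synthetic cohort generator** — a seeded household-cohort simulator
  (8 two-person households + 4 controls, 5 visits, 2 body sites, missing
  samples, planted transmissions) with machine-readable ground truth, used
  by the tests to score the pipeline against known answers.

See `docs/methods.md` for the model, parameter defaults, and known
limitations (including a measured conservativeness property of the
permutation statistic).

## Worked example

Simulate the default cohort and run the whole fecal pipeline:

```bash
viroshare all --config configs/study_cohort.yaml --seed 1 --out runs/demo
```

or, from Python, compute the headline quantities directly (this is exactly
what `scripts/acceptance.py` does):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which prints, for seed 1:

```
within_subject_homologous_pct: 67.35 (n=16)
between_subject_homologous_pct: 2.16 (n=16)
fecal_subjects_significant: 16 (n=16)
household_shared_pct: 22.7 (n=8)
putative_transmission_pct: 8.9 (n=8)
transmission_placebo_to_antibiotic_pct: 6.7 (n=8)
transmission_antibiotic_to_placebo_pct: 2.2 (n=8)
persistence_ge_4_days_pct: 47.5 (n=1768)
persistence_5_to_6_months_pct: 23.9 (n=1768)
```

Reading this: averaged over the 16 household subjects, 67% of a subject's
fecal contigs sampled at one visit have a homologue at another of their own
visits, versus 2% against other subjects' visits — and all 16 subjects test
individually significant for that contrast. Across the 8 households, 22.7%
of distinct global viruses are detected in both housemates; 8.9% show the
putative-transmission pattern, of which three quarters (6.7 points) run
from the placebo-taking member to the antibiotic-taking member — the
directional bias planted by the generator. About half of each subject's
global viruses are re-detected ≥ 4 days apart and about a quarter are still
identifiable 5–6 months later.

## Command-line interface

`viroshare` exposes each stage over the library:

```
viroshare simulate  --seed 7 --out d/           # cohort + truth.json
viroshare homology  --cohort d/cohort --site feces --out d/
viroshare distance  --cohort d/cohort --hitflags d/hit_flags_feces.tsv --out d/
viroshare permtest  --cohort d/cohort --hitflags d/hit_flags_feces.tsv --out d/
viroshare track     --cohort d/cohort --site feces --out d/
viroshare transmit  --cohort d/cohort --site feces --out d/
viroshare all       --config c.yaml --seed 7 --out d/
```

Every stage reads and writes plain text (TSV/FASTA/JSON/YAML); `all` writes
a `manifest.json` with parameters, seed, and sha256 checksums, and two runs
with the same seed are byte-identical.

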