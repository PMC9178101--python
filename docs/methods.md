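# Methods

## Pipeline model

The package reconstructs, as a reusable library, the secondary analysis of
a longitudinal newborn-screening registry: per-disease case review,
variant-string normalisation, comparison against ClinVar-style gene
extracts, evidence-criteria assignment from longitudinal clinical data,
ACMG/AMP combining-rule classification, and a time-stamped re-audit
against a later extract snapshot.

### Variant normalisation

Registry submissions arrive in five dialects: HGVS c. (`c.549A>C`),
spaced HGVS c. (`c.549A > C`), three-letter protein (`p. Phe256Leu`),
single-letter protein (`F256L`), and invalid free-text tokens (`none`,
`negative`, empty — a configurable, case-insensitive list). Parsing never
raises: every input lands in exactly one mapping status (`mapped`,
`invalid_token`, `unparseable`, or — after reference validation —
`unmapped_reference_mismatch`).

Conventions, stated explicitly:

* Protein positions are 1-based (HGVS).
* Stop spellings `Ter`, `*`, and trailing `X` unify to `*`; `X` is read
  as a stop **only** in the alternate position, so unknown-residue usage
  elsewhere is unparseable rather than silently misread.
* When both c. and p. are present (ClinVar names), c. is the canonical
  matching key and p. is secondary; a protein-only registry submission
  never matches a c.-only extract row (cross-level inference would need
  transcript translation, out of scope).
* Transcript accession versions are ignored during matching and
  reference lookup — registry submissions are rarely versioned.
* Consequence is assigned from notation alone: stop alternate ⇒ nonsense;
  `fs` suffix, or c. indel with net length change not divisible by 3 ⇒
  frameshift; intronic offset ±1/±2 ⇒ canonical splice; change at Met1 ⇒
  start loss; identical residues ⇒ synonymous. A bare c. substitution
  without protein information stays `unknown`. The predicted-null
  predicate (PVS1) is {nonsense, frameshift, canonical splice, start
  loss}; since the source analyses made this call at notation level, no
  sequence recomputation is attempted.

Reference validation compares the stated reference residue with the
reference protein at that position (positions past the end count as
mismatches). Mismatched ("unmapped") variants are excluded from all
criteria assignment and reported as `Excluded-Unmapped`.

### Evidence criteria

PS3 and PP4 are global for this cohort: every enrollee has a
newborn-screen plus confirmatory functional diagnosis of a
well-characterised early-onset disorder. They are withheld, with a
warning, if any supporting subject lacks the confirmed-diagnosis flag.
The data-driven criteria:

| code | rule |
|------|------|
| PVS1 | predicted-null consequence |
| PM3  | autosomal recessive disease and some supporter's other allele is published Pathogenic/Likely Pathogenic (reported variants assumed in trans; VUS partners and unpublished partners do not qualify) |
| PM5  | missense at a residue with a published P/LP missense of different alternate |
| PM6  | de novo indication in family history, parentage unconfirmed |
| PP1  | an affected relative carries the same variant |
| PP3 / BP4 | all available predictor calls deleterious / neutral (≥1 call); discordant or absent ⇒ neither. The concordance rule across the two predictors is a documented choice — the source did not state one |
| PP5  | Pathogenic/Likely Pathogenic in a secondary variant database |
| BP7  | synonymous with no deleterious predictor call |

Population-data criteria (PM2, BA1, BS1, …) are representable by the
engine but never auto-assigned — the registry generates no population
data. A manual-override CSV (`variant_key, criterion, add/remove`) can
inject or retract any code; every application is logged into provenance.
PP5/BP6 are implemented although later guideline revisions deprecate
them, because the reconstructed analysis used PP5.

### Combining rules

The full ACMG/AMP table: 8 Pathogenic rules (1a–1d, 2, 3a–3c), 6 Likely
Pathogenic rules, 2 Benign, 2 Likely Benign. Strength counts use the
rules as written ("1 strong" means exactly one). Both a pathogenic and a
benign rule firing ⇒ VUS with a conflict flag; none firing ⇒ default VUS.
The rule label records the first satisfied rule in canonical order
(Pathogenic before Likely Pathogenic), giving deterministic provenance;
the category itself is order-independent. Likely Pathogenic 3 defaults to
the published standard's "≥2 supporting"; `strict_lp3=True` applies the
alternative "more than two" reading for sensitivity analysis — neither
mode guesses the original analysts' intent, both are exposed.

### Time-stamp re-audit

Classified (mapped unpublished) variants are looked up in an updated
extract. The enrichment probability is an upper-tail hypergeometric,
`P(X ≥ n_overlap)` with population `n_universe` (distinct variants in the
union snapshot), successes `n_added`, draws `n_query`, computed with
`scipy.stats.hypergeom.sf`; a `tail="lower"` flag gives depletion. The
parameterisation is exposed because published figures of this kind are
often not reproducible from any standard tail convention; the module
documents its own convention instead of imitating an ambiguous number.
Concordance means both classifications pathogenic-side (P/LP), or both
uncertain (snapshot "Conflicting interpretations" counts as uncertain).

## Synthetic cohort generator

The generator's defaults are the study conditions: 32 diseases
(10 amino-acid, 8 fatty-acid-oxidation, 11 organic-acid, 3 other), 1904
subjects spread as evenly as possible (59–60 per disease; an equal
`subjects_per_disease` mode exists for controlled experiments), genotyping
rate 0.516, unpublished fraction 0.285 among distinct variants, wrong
reference-residue fraction 0.068 among unpublished (11/161), and
per-criterion availability set to the observed proportions among the 150
mapped unpublished variants (PM3 0.44, PM5 0.13 of protein-level
missense, PM6 0.013, PP1 0.047, PP5 0.153; predictor outcomes for
missense: concordant-deleterious 0.755, concordant-neutral 0.01,
discordant 0.10, otherwise absent). The null fraction is 44/150 with
subtypes nonsense 0.5 / frameshift 0.3 / splice 0.2, and the synonymous
fraction 4/150. Values the source did not state — the fraction of
genotyped subjects reporting two alleles (0.8, biallelic recessive
disorders dominate the screening panel), homozygosity (0.15), distinct
variants per genotyped subject (0.574 = 564/982), dialect mix (half
single-letter, reflecting the dominance of that shorthand) — were chosen
once as field-realistic and are config knobs, not tuning dials.

Every planted substitution is a real single-base change in a per-gene
random coding sequence (start codon, 300–500 sense codons, stop), so
extract c./p. pairs are internally consistent and the FASTA reference
proteins make the wrong-residue check self-contained. Each distinct pool
variant is anchored to at least one genotyped subject, so the distinct
sets the pipeline observes equal the planted pools exactly. Partner
alleles are drawn under constraints that make accidental in-trans (PM3)
evidence impossible for variants whose truth says PM3 is absent; family
history, predictor rows, and secondary-database rows are likewise written
only where the truth manifest plants the corresponding code. All diseases
are one-gene and autosomal recessive. Identical configs and seeds give
byte-identical outputs.

What the generator does **not** emulate: metabolite values and treatment
trajectories, multi-gene diseases, genomic (g.) coordinates, deep
intronic variation, population allele frequencies, and real-world
discordance between clinical records and genotype. Passing recovery tests
therefore demonstrates the pipeline's bookkeeping and decision rules are
exact under the stated study conditions — not robustness to every failure
mode of real registry data.

## Numerical and reporting choices

* Percentages are 100·count/denominator rounded half-up to one decimal
  (`decimal.Decimal`); the criteria/classification denominator is the
  distinct unpublished count. A zero denominator reports undefined
  (`None`), never 0.
* All randomness flows from one `numpy.random.Generator` seeded by the
  config; sub-seeds derived from it stay below 2³¹.
* Deduplication and all report files are sorted by canonical variant key,
  so outputs are independent of row order and byte-identical across
  regenerations.
* Degenerate inputs: empty registry tables produce empty partitions;
  unknown disease codes are quarantined and logged, never dropped;
  unparseable variant strings are counted and excluded from matching.

## Problem sizes

The test suite exercises an 8-disease/320-subject cohort for unit-level
checks and the full 1904-subject cohort for recovery and re-audit checks;
the rule-engine oracle sweep covers all 4,096 subsets of a 12-code
universe and the hypergeometric sweep all parameter tuples with universe
≤ 30. These sizes keep the whole suite in seconds on one CPU while
covering every decision rule exhaustively where enumeration is possible.

## Known limitations

* Frameshift and splice calls are notation-level; a mis-notated
  submission will be mis-classed.
* PM3 uses the assumption that two reported alleles are in trans; phase
  fields are carried as provenance but do not gate the criterion.
* The HGVS grammar subset excludes inversions, alleles-in-cis notation,
  genomic coordinates, and intronic offsets beyond ±2.
* Matching is extract-driven: variants published under a representation
  the registry never used (e.g. only genomic coordinates) would count as
  unpublished.
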