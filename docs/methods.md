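# Methods

## The scoring model

A taxonomic profile is a map from canonical taxon name to relative
abundance at one rank. Given a profile *j* and a reference community with
known composition *i* at the same rank, the four reporting measures are:

- **Sensitivity** = 100 · |TP| / *n*, where TP is the set of reference
  taxa matched by a profile entry with abundance strictly greater than the
  detection threshold and *n* is the number of reference taxa at that
  rank. Displayed rounded to an integer percent; stored unrounded.
- **FPRA** = 100 · A<sub>FP</sub> / (A<sub>TP</sub> + A<sub>FP</sub>),
  where A<sub>FP</sub> is the summed abundance of entries matching no
  reference taxon. The abundance split is computed over the full profile
  mass regardless of the detection threshold — the threshold gates which
  taxa *count* as detected, not where their mass is booked — so the
  invariant A<sub>TP</sub> + A<sub>FP</sub> = profile total always holds.
- **Diversity** = number of entries above the detection threshold
  (equivalently |TP| + |FP| at the same threshold).
- **Similarity** = 100 · 2·C<sub>ij</sub> / (S<sub>i</sub> + S<sub>j</sub>)
  with C<sub>ij</sub> = Σ<sub>t</sub> min(a<sub>it</sub>, a<sub>jt</sub>)
  over the taxon union and S the profile totals; identical to
  100 · (1 − Bray–Curtis dissimilarity). The formula is computed in full
  generality so un-normalised inputs remain valid; the scoring pipeline
  normalises profiles first, making S<sub>i</sub> = S<sub>j</sub> = 1.

Conventions for degenerate inputs: the similarity of two empty profiles is
0, not 100 (vacuous agreement should not score); FPRA of an empty profile
is 0 with a warning; threshold comparison is strictly greater-than, so a
threshold of 0 means "any positive abundance counts". Gram-stain recovery
renormalises over the matched abundance only — false positives carry no
gram label — and is undefined (NaN, with a warning) when nothing matches.

**Bias partition.** With a paired design — the same pipeline run on a
whole-cell reagent (WC) and on a DNA-only reagent of the same strains
(DNA) — similarity losses bound the contribution of each stage:
`bioinformatic_loss` = 100 − Sim(DNA, actual) (no extraction occurred, so
this loss is library/sequencing/classification), `extraction_loss` =
100 − Sim(WC, DNA), and `achievable_ceiling` = Sim(WC, DNA) is the best a
perfect classifier could recover given the extraction. These are bounds,
not an additive decomposition, so `total_loss` = 100 − Sim(WC, actual) is
reported independently rather than forced to equal their sum.

## The ground-truth registry

A community truth is a list of strain records: lineage
(phylum/family/genus/species), gram stain, genome size (bp), 16S rRNA gene
copy number, a relative cell weight and/or a DNA mass (ng). Expected
profiles are derived by weighting each strain, summing weights within each
taxon at the requested rank (strains of one species collapse into one
entry), and normalising:

| basis | weight per strain | emulates |
|---|---|---|
| `cells` | cell_weight | flow-cytometry cell fractions |
| `dna_mass` | cell_weight × genome_size | shotgun read fractions |
| `amplicon_16s` | cell_weight × copies_16s | 16S amplicon fractions |

For DNA-only reagent truths that record mass but no cell count,
`dna_mass` falls back to mass_ng directly and `amplicon_16s` to
(mass_ng / genome_size) × copies_16s.

The bundled `gut20` registry is a synthetic reconstruction of the
canonical 20-strain gut whole-cell reference community. The published
description fixes its cardinalities (20 strains, 19 species, 16 genera,
13 families, 5 phyla, 12 gram-positive / 8 gram-negative) and names three
species that drop out of shotgun profiles; the per-strain genome sizes and
copy numbers in the bundled table are literature-typical values for those
type strains chosen to satisfy every such constraint. They are **not**
certified values, so comparisons that depend on the exact genome-size- or
copy-number-adjusted percentages of the real reagent should load a
user-supplied truth file (same TSV/JSON schema). All strains carry
cell_weight = 1, reflecting equal-cell mixing.

## The synthetic-data generator

No generative model is published for this kind of experiment; the
generator is the simplest mechanism that reproduces each qualitative
finding independently, and each sub-model can be switched off.

1. **Extraction.** Strain efficiency e = 0 for species in `dropout_taxa`
   (hard-to-lyse organisms lost entirely), otherwise log-normal with
   median equal to the gram-class mean (`efficiency_mean_positive`,
   `efficiency_mean_negative`) and log-sd `efficiency_sd_log`. Strain
   basis-weights are multiplied by e, aggregated to species, normalised.
2. **Classification.** `n_false_taxa` names are drawn from a pool of gut
   taxa outside the community and given total abundance exactly
   `target_fpra_percent`/100, split by a symmetric Dirichlet; true taxa
   scale down by the complement. Fixing the false-positive mass (rather
   than drawing it) makes FPRA assertions on the output exact; randomness
   enters only through the identities and the split.
3. **Replication.** Each of `n` replicates is drawn from a Dirichlet with
   mean equal to the sample profile and concentration *c*
   (`dirichlet_concentration`; per-taxon variance p(1−p)/(c+1));
   `None` gives noise-free copies.

One integer seed drives a master `numpy` SeedSequence; the three stages
consume spawned substreams, so identical configs produce byte-identical
outputs and the stages stay independently reproducible.

`study_config()` packages the regime the benchmark observed: dropouts
{*Clostridium butyricum*, *Alistipes finegoldii*}, gram-positive
efficiency 0.6 vs gram-negative 1.0 with log-sd 0.2 (a clear but not
pathological lysis deficit), 6% FPRA over 2 false taxa (inside the
observed 3.5–8.2% range), 5 replicates at concentration 500. The
concentration is a free parameter — replicate dispersion is only
constrained to CV < 100% — and 500 puts per-taxon replicate CVs in the
few-percent range.

With unit efficiencies, no dropouts, zero FPRA and noise-free replicates,
the pipeline returns the expected profile exactly (identity limit, tested).

What the generator does **not** emulate: read-level sequencing error,
chimeras or PCR-cycle effects, reagent contamination, host DNA or
inhibitor matrix effects, and classifier rank-confusion (false positives
appear at the scored rank with fixed mass). Passing tests therefore
demonstrate correctness of the scoring arithmetic and recoverability of
planted extraction/classification bias — not performance of any real kit
or profiler on real specimens.

## Physicochemical QC

Per kit, replicate means of yield (ng), DIN and 260/280 ratio are scored
against configurable thresholds:

- **yield**: report-only (verdict `not_evaluable`) unless the user sets
  `min_yield_ng`, since acceptable yield depends on the downstream
  sequencing technology; then pass/fail on the mean.
- **DIN**: `not_evaluable` when the mean concentration is below the
  TapeStation limit of detection (default 1 ng/µl) or no DIN exists —
  never imputed; otherwise pass at mean ≥ `min_din` (default 4.0), warn
  below. The 4.0 default encodes the qualitative judgment that ~3.4 is
  notably degraded while 4.1–5.3 is unremarkable; it is a convention, not
  an instrument specification, and the report's metadata says so.
- **260/280**: pass at ≥ 1.8 (the conventional protein-free ratio), warn
  in [1.6, 1.8), fail below 1.6.

Each measure's replicate CV (single definition, shared with the scoring
module: 100·sd/mean, sample sd) warns above `max_cv_percent`
(default 100%, the published reproducibility bound — permissive, and
configurable).

## Parsing and name matching

Taxon names are canonicalised — lower-case, underscores to spaces, rank
prefixes (`s__`, `g__`, SILVA `D_6__`) stripped, brackets dropped,
whitespace collapsed — before any matching; the transform is idempotent.
MetaPhlAn-style clade tables are filtered to rows terminating exactly at
the requested rank (strain-level sub-rows are excluded), percentages are
divided by 100 and renormalised; rows at other ranks (including
unclassified fractions) are dropped rather than scored. Profiles that do
not sum to 1 are renormalised before scoring; `normalize=False` on the
generic reader preserves raw totals for FPRA-on-raw analyses. An optional
synonym map handles classifier/registry nomenclature drift (e.g. renamed
genera); there is no automatic taxonomy lookup — lineages come from the
truth file.

## Problem sizes and verification

All tests run on the 20-strain registry and random profiles over pools of
~12–22 taxa. Oracle checks compare the four measures against a
straight-from-the-equations reimplementation on 1,000 random profiles (to
1e-9) and Similarity against independent Bray–Curtis routines (scipy,
scikit-bio) on 100 random pairs. Parameter recovery uses 20 simulated
replicates; the Dirichlet mean-convergence check uses 1,000. The whole
suite completes in a few seconds on one core.

## Known limitations

- The bundled registry's numeric columns are reconstructions (see above);
  conclusions about the real reagent's adjusted compositions require the
  vendor/certified table.
- Gram recovery assumes each taxon at the scored rank has a single gram
  stain; mixed-gram groupings raise an error rather than splitting mass.
- The similarity-loss partition bounds, but cannot uniquely attribute,
  interaction effects between extraction and classification bias.
- No inferential statistics (PERMANOVA, ANOVA, FDR) are included; the
  exported dissimilarity matrices and score tables feed standard tools.
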