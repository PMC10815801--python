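# Methods

This note documents the models and procedures implemented in `aptapanel`,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the numerical details a user reproducing or
extending the analyses should know.

## SELEX read processing

Each selection round is a FASTQ file (Phred+33). Reads pass through:

1. **Sliding-window quality trimming.** Windows of `window` consecutive
   bases (default 4) are scanned left to right. At the first window whose
   mean Phred quality falls below `mean_quality_threshold` (default 20),
   the read is truncated immediately before that window's first base;
   trailing bases of the kept prefix with quality below the threshold are
   then dropped. Reads shorter than the window are kept whole when their
   overall mean quality meets the threshold and emptied otherwise. These
   semantics are fully specified here so results are reproducible without
   any external trimming tool; the output is always a prefix of the input,
   and raising the threshold never lengthens it (both property-tested).
   The 4:20 default matches the conventional Trimmomatic
   `SLIDINGWINDOW:4:20` option string; some protocol descriptions phrase
   the same step as a Q30 criterion, so the threshold is an explicit
   parameter rather than a constant.
2. **Length filter.** Reads shorter than `min_length` (default 74 nt, the
   minimum expected size for a 76-nt library) are discarded; input,
   surviving and discarded counts are reported.
3. **Frequency counting.** Surviving reads are counted by exact string
   identity per round and normalised to per-round frequencies. No
   clustering of near-identical sequences and no reverse-complement
   merging is performed: with a planted-truth simulation exact counting is
   the transparent choice, and collapsing rules would add parameters the
   analysis does not need.
4. **Candidate ranking.** The top-k sequences (default k = 5) present in
   the final round, ordered by final-round count with lexicographic
   tie-breaking, are nominated as candidates; each carries its full
   per-round frequency trajectory and round-over-round enrichment ratios
   (flagged undefined where the previous round had frequency zero).
   All reads surviving the length filter are counted, not only full-length
   ones; restricting to 76-nt reads is a caller-side filter if wanted.

FastQC-style summary statistics (read counts, length range, GC content,
mean quality) are reported for information only and impose no filtering.

## Saturation binding model

Total binding at aptamer concentration X (nM) is modelled as

    response(X) = Bmax · X / (X + Kd) + NS · X + Background

with Bmax ≥ 0 (maximal specific signal, response units), Kd > 0 (nM),
NS ≥ 0 (nonspecific slope, units/nM) and Background ≥ 0 (units). Fitting
is bounded nonlinear least squares (trust-region reflective) on all four
parameters, unweighted by default (per-point weights are an option).
Initialisation: Bmax₀ = response range; Kd₀ = median positive dose; NS₀ and
Background₀ from control rows (Background = mean zero-aptamer response;
NS prior = (library-control response − Background)/library dose when a
library control exists). Convergence uses `xtol = 1e-8` with a 10,000
evaluation cap; standard errors come from the Jacobian at the optimum
(σ² (JᵀJ)⁻¹ with the residual variance estimate). Flat or all-zero data
yield a converged degenerate fit with the Kd flagged unidentifiable rather
than an error. Replicate fits can be pooled with `pool_kd`, which reports
both the between-fit SD of Kd (the convention behind "Kd = 139 ± 14 nM"
style summaries) and each fit's asymptotic SE, labelled.

**Identifiability.** With the customary five-dose design (25–400 nM,
three replicates) and all four parameters free, Kd is only weakly
identified when the truth includes a nonzero nonspecific slope: the
asymptotic relative SE of Kd is ≈ 25% per 2% of Bmax of response noise, so
no tight recovery guarantee is possible in that regime (the nonnegativity
bounds help, but the median error remains well above what the
pure-saturation case achieves). The recovery properties asserted in the
test suite therefore use the pure-saturation truth (NS = 0,
Background = 0), where the median relative Kd error over 100 simulated
titrations is ~1e-15 without noise, ≲ 0.1 at 2% noise and ≲ 0.2 at 5%
noise. Practical advice encoded here: fix NS to a control-derived value
when doses barely exceed Kd.

## Diagnostic evaluation

A cohort table has one row per tissue sample — class (`adjacent`,
`primary_tumor`, `metastatic`), molecular subtype, stage, grade, TNM — and
one ordinal staining-intensity column per aptamer (0 none, 1 (+), 2 (++),
3 (+++)). A sample is positive for an aptamer (or for a panel, whose
combined intensity is the member-wise maximum — the union rule) when its
intensity reaches the positivity threshold. The default threshold is 1
(any staining) and the default tumor pooling is primary + metastatic
against adjacent tissue: this is the only reading that reproduces the
published per-aptamer index table from the recognition marginals, because
adjacent tissue stained (+) counts against specificity. Indices follow
the standard definitions (sensitivity TP/(TP+FN), specificity TN/(FP+TN),
accuracy (TP+TN)/N); integer-percent rendering rounds half away from zero
(e.g. 12/90 → 13%), and an index with a zero denominator is flagged
undefined, never fabricated. Stratified tables report recognized/total,
percent (decimals configurable, since published tables mix integer and
one-decimal percents) and the maximum intensity among recognized samples
per stratum; published subtype tables contain small internal percent
inconsistencies (e.g. 1/28 printed as 3.5), and this package always
recomputes percents from counts. Exhaustive panel search scores all
2ᵏ − 1 nonempty subsets and ranks by sensitivity then specificity; under
the union rule adding an aptamer can never lower sensitivity nor raise
specificity (property-tested over all subsets).

The bundled example dataset (`aptapanel.datasets`) carries only the
published per-class marginals of the 100-sample cohort, so expanded
per-sample tables support single-aptamer statistics exactly; multi-aptamer
panel values on that cohort would require the unpublished per-sample
staining matrix and are not reproduced.

## Target-shortlist cascade

Three sequential, independent filters over a protein table:

1. **Fold change:** keep proteins with
   (target + pc)/(control + pc) ≥ factor (default 2, inclusive — "at
   least" a 2-fold increase). The pseudocount pc defaults to the smallest
   positive abundance in the table, so zero-control proteins with real
   target signal survive instead of dividing by zero; the value used is a
   deliberate, logged choice, not a hidden constant.
2. **Membrane:** keep proteins with membrane-proteome evidence AND a
   plasma-membrane localization call. Requiring the conjunction mirrors
   the sequential use of a membrane-proteome dataset followed by
   localization predictors; it is one defensible reading of that
   procedure, and either line of evidence can be relaxed by editing the
   input columns.
3. **Phenotype:** keep proteins called `over` in every cell line the
   aptamer panel recognizes and `under` in every line it does not. The
   per-line calls are input columns (published expression calls are the
   intended source); `unknown` fails in strict mode (default) and is
   ignored in lenient mode. A helper derives calls from an abundance
   matrix at a user-set fold threshold when published calls are absent.

Because the filters are independent per-row predicates (given a fixed
pseudocount), reordering them never changes the final shortlist, though
stage counts change — both facts are tested. Electrostatic-surface
screening of shortlisted proteins requires external computation and is out
of scope; the report leaves room for such annotations downstream.

## Trajectory analytics

* **Superposition RMSD.** Kabsch's SVD algorithm with the determinant
  correction (proper rotations only); mass-unweighted over all supplied
  atoms, since no atom selection or weighting scheme is assumed. Requires
  ≥ 3 non-collinear atoms. Cross-checked in the tests against a
  rotation-grid search and an independent library implementation.
* **GROMOS clustering.** Pairwise superposed RMSD matrix (superposition
  per pair, not to a shared reference — the canonical formulation), then
  greedy extraction: the unassigned frame with the most unassigned
  neighbors within the cutoff (ties → lowest frame index) becomes the next
  cluster's representative, and it plus its neighbors are removed.
  Clusters are relabelled in descending size order, so cluster 0 is the
  dominant conformation. Default cutoff 2.5 Å. Every member lies within
  the cutoff of its representative by construction (asserted), and the
  implementation is verified against a brute-force reference on random
  trajectories.
* **Hydrogen-bond occupancy.** A frame satisfies a donor–hydrogen–acceptor
  spec when the donor–acceptor distance is ≤ 3.5 Å and the D–H···A angle
  at the hydrogen is ≥ 135°; both cutoffs are parameters and are recorded
  in the output tables, since no universal geometric criterion exists.
  Occupancy is the percentage of frames satisfying the spec, pooled across
  concatenated replicates (per-replicate breakdowns are also emitted —
  pooling matches the convention of quoting one percentage over repeats
  delimited in a timeline figure). The report lists specs above a 20%
  occupancy floor, sorted descending.
* RMSF is deliberately not implemented: it is occasionally named alongside
  these analyses but has no defined output here to validate against.

Trajectories are plain coordinate stacks with atom labels and replicate
boundaries; they read/write multi-model PDB (via biotite) and a plain
whitespace frame table. Metadata such as frame spacing is informational.

## Synthetic-data generators

All generators are bit-reproducible given their config and seed; one seed
feeds independent per-generator substreams (spawned by generator name) so
adding a generator never perturbs another's draws.

* **SELEX rounds.** A background pool of `background_diversity` distinct
  full-length sequences (constant flanks around a random region; flank
  sequences are configurable and randomly drawn by default, since primer
  sequences are generally proprietary) plus planted sequences whose
  relative weight multiplies by their enrichment factor each round; reads
  are multinomial draws per round. Per-base Phred scores are Gaussian
  (default mean 36, SD 3), truncated to [2, 41], with an optional linear
  3′ degradation over the second half of the read to exercise trimming.
  Defaults mirror the study design: 12 rounds, 76-nt library, 30-nt random
  region. Not modelled: PCR amplification bias, sequencing substitution
  errors, chimeras — so passing recovery tests demonstrates the counting
  and ranking logic, not robustness to amplification artifacts.
* **Binding curves.** The four-parameter model evaluated at the standard
  dose ladder {25, 50, 100, 200, 400} nM with additive Gaussian noise,
  three replicates, plus zero-aptamer control rows. Real MFI noise is
  heteroscedastic and the real dose ladder is sparse; recovery results on
  synthetic curves quantify estimator behaviour, not instrument error.
* **Recognition cohorts.** Default shape 10 adjacent / 50 primary / 40
  metastatic. Staining is Bernoulli per sample (true-positive rate on
  tumor, false-positive rate on adjacent; scalar or per-aptamer), with
  ordinal intensity drawn from a configurable distribution over {1, 2, 3};
  subtype/stage/grade/TNM metadata are drawn from fixed plausible
  frequency tables. Aptamers stain independently here, unlike real tissue
  where staining correlates across aptamers — so panel-level synthetic
  results exercise the union arithmetic, not biological co-staining.
* **Proteomic tables.** Planted targets pass all three filters by
  construction; each decoy fails exactly one designated filter (phenotype,
  membrane, or fold change). The default composition (4 planted + 36
  membrane decoys + 249 non-membrane decoys) makes the cascade's stage
  counts 289 → 40 → 4 fully determined. Abundances for fold-change
  survivors are drawn so that survival is robust to the data-derived
  pseudocount (target ≥ control · (2·factor − 1)).
* **Trajectories.** Cluster centers are independent Gaussian
  conformations (dispersion `center_separation`/2), so their pairwise
  *superposed* RMSD — the metric clustering actually sees — is of order
  `center_separation`; frames are jittered copies in blocks per replicate.
  If any realized center pair falls within twice the clustering cutoff,
  or the jitter itself spans the cutoff, the ground truth carries an
  overlap warning flag. Planted hydrogen bonds append a
  donor/hydrogen/acceptor atom triple placed at ideal geometry (2.9 Å,
  collinear) in a deterministic, evenly spaced set of frames of size
  round(occupancy × n_frames), and far away (8 Å) otherwise.

## Problem sizes in the test and acceptance runs

The default test suite and the acceptance script run simulations at
moderate sizes chosen to make the statistical assertions stable: 20
simulated selections of 5 rounds × 1500 reads against 800 background
sequences for candidate nomination; 100 simulated titrations per noise
level for Kd recovery; 100 random 15-frame trajectories for the
clustering oracle; 100 random cascade fixtures. These sizes are a
package-level choice balancing statistical resolution against quick
iteration; all are configurable upward.

## Known limitations

* Exact-match counting treats one-off sequencing errors as distinct
  sequences; heavily error-prone data would dilute planted counts.
* The binding fit assumes homoscedastic noise unless weights are given.
* The diagnostic module treats staining intensities as given inputs; no
  image quantification is performed.
* The shortlist cascade does not retrieve or parse the published
  proteomic datasets it is designed around; users supply the table.
* Trajectory operations are O(n²) in frames (pairwise superposition) and
  are intended for post-processed, strided trajectories, not raw
  million-frame runs.
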