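# Methods

## Data model

A quantified phosphopeptide table has one row per phosphopeptide form:
peptide sequence, leading protein accession, 1-based protein site positions
with residues (S/T/Y only), a site-localization probability per site, and an
intensity block of five time points (0, 5, 15, 30, 60 min) × three
biological replicates. Missing intensities are represented as absent (NaN),
never as zero; a zero is a measured value. Site positions are 1-based in all
external files and in memory, matching the field's `pS279` convention.
Intensity columns follow the `<time>min_rep<k>` naming scheme; a
column-mapping block in the run config adapts other export schemas without
code changes.

## Filtering

* **Class-I sites.** A peptide is kept only if *every* site has localization
  probability strictly greater than the threshold (default 0.75). The strict
  inequality is deliberate: 0.75 itself is dropped.
* **Reproducibility.** A peptide is kept only if it has at least
  `min_replicates` (default 2 of 3) non-missing intensities at *every* time
  point, including the 0-min baseline.

Both filters are idempotent and commute, which the test suite asserts.

## Normalization

`eigenms_normalize` removes systematic sample-level bias while preserving
the treatment (time-point) structure:

1. per-row available-case group means are fitted under the time-point
   grouping and subtracted (no imputation; all-missing rows pass through
   untouched and flagged);
2. the residual matrix (NaNs as zeros) is decomposed by SVD;
3. the number of significant bias trends is chosen by a permutation test:
   residuals are permuted independently within each row *and within each
   treatment group*, and trend *k* is retained while its singular value
   exceeds the (1 − α) quantile of the k-th permuted singular value
   (sequentially from the top). Within-group permutation matters: the
   group-mean fit constrains each row's residuals to sum to zero per group,
   and a permutation that breaks this constraint redistributes variance
   across singular values, making every residual dimension appear
   significant;
4. retained trends are projected out of the residuals and the group means
   are added back. The NaN pattern of the input is restored on output.

Defaults: 200 permutations, α = 0.05, seed from the run config; output is
bit-reproducible given the seed. The procedure is identifiability-limited by
design: a bias collinear with the treatment structure is absorbed into the
group means and cannot be distinguished from a real effect by any
fold-change-preserving normalization. Correspondingly, the synthetic
generator plants its optional rank-1 bias as a replicate-batch drift
(constant within a replicate across times), which is orthogonal to the
treatment structure and therefore detectable.

## Temporal analysis

Replicate-level log2 fold changes are computed against the mean of the
available 0-min replicates; per-time means average the available replicate
fold changes. K-means (k = 8, Euclidean, 50 restarts with k-means++
seeding, fixed seed) clusters the replicate-averaged mean-log2FC profiles.
Clustering operates on the unscaled log2FC vectors: per-profile unit-norm
scaling is available as an option but off by default, because scaling maps
near-zero (unresponsive) profiles to random directions on the unit sphere
and destroys the magnitude information that identifies them; the vector
transformation belongs to heatmap display, not to the clustering itself.

Cluster centroids (per-cluster means of the unscaled profiles) are labeled
with archetypes by shape rules with tolerance ε (default 0.3, roughly twice
the standard error of a centroid under the default noise): unresponsive (H)
if max |c| < ε; continuous dephosphorylation (F) if all entries ≤ −ε and
non-increasing within ε/4; fluctuating dephosphorylation (G) if all entries
≤ ε/4, some ≤ −ε, and not monotone; sustained phosphorylation (E) if all
entries ≥ ε/2; otherwise a transient peak A/B/C/D by argmax time. Sustained
(E) members are redistributed to early (peak at 5/15 min) or late (30/60
min) response by the argmax of their own mean profile, ties toward the
earlier time. The order of the rules matters and is fixed (H, F, G, E,
peaks).

DEP calling at each time point: *up* if ≥ 2 of 3 replicate log2FCs ≥ 1 and
t-test p < 0.05; *down* symmetric with ≤ −1. The decrease criterion is
interpreted as fold change ≤ 0.5 (log2FC ≤ −1), symmetric with the up
threshold; both thresholds are exposed in the config. The t-test is
Student's two-sample test on log2 intensities by default (Welch available
via `equal_var=False`); with three replicates per group the pooled-variance
test has substantially better power when missingness reduces a group to two
values, and it matches the analysis convention for this design. No
multiple-testing correction is applied to the per-peptide t-tests (raw
p < 0.05 is the calling criterion); a BH option exists but is off by
default.

## Enrichment

GO over-representation uses the one-sided (enrichment) Fisher exact test per
term, with the study set required to be a subset of the background; terms
with fewer than 5 study hits are not tested. Multiple testing is controlled
by Benjamini–Yekutieli (valid under the strong dependence of nested GO
terms), applied separately per aspect and per study set (early vs late).
Annotations with IEA or ND evidence are excluded at load time
(case-insensitive). The membrane-compartment split sends a protein to Group
A (the group of interest) on *any* annotation to a membrane/periphery
compartment (plasma membrane, ER, Golgi, vacuole, extracellular, cell wall,
apoplast, cytoskeleton, plasmodesmata); proteins annotated only to
cytosol/mitochondria/plastid/nucleus/complexes go to Group B, and
unannotated proteins default to B (configurable). Significance in the
pipeline means BY-adjusted p ≤ 0.05; raw-p selection is available via flag.

## Motif extraction

Windows are 13-mers (±6) around each phosphosite, X-padded at protein
termini; multiply phosphorylated peptides contribute one window per site,
each carrying the peptide's intensity profile. The background is every
S/T/Y-centered 13-mer of the supplied proteome (an option restricts it to
identified-peptide windows). motif-x proceeds greedily per central residue
(S, T, Y independently, minimum occurrences 30/20/20, step threshold
p < 1e-6): each step scores every unfixed (position, residue≠X) pair by the
binomial tail of the foreground count given the *current* background
frequency at that position (recomputed after every restriction; zero
background frequency is replaced by the 1/(bg+1) pseudo-frequency), fixes
the most significant pair (ties: larger fold enrichment, then smaller
|offset|, then upstream first), and restricts both window sets. A completed
motif's foreground matches are removed and extraction restarts; the
background always resets to the full set. Every reported motif satisfies
fg_matches ≥ min_occ and all step p-values < threshold, asserted by tests.

Motif-class grouping uses a rule table over the constraint set (checked in
order): LXR/KXX[pS/pT] and R/KXX[pS/pT] basic, [pS/pT]P proline-directed,
[pS/pT]XD/E and [pS/pT]XXD/E acidic, SX[pS], [pS/pT]F, [pS/pT]G, [pS]XP,
else "other".

Motif dynamics per (class, time): the abundance track is the fold change of
the mean normalized intensity of member peptides at time t vs 0 min; the
enrichment p is a two-sided Fisher test of [[a, b], [c, d]] with a/b the
time-t DEPs matching/not matching the class and c/d the matching/non-matching
peptides among DEPs pooled over all times. The exact 2×2 construction for
this statistic is not standardized; this time-vs-all-DEPs scheme is the
package's documented choice, with a DEP-vs-non-DEP alternative selectable in
the config.

## Kinase–substrate network

The curated interaction table becomes a deduplicated directed graph; node
roles (kinase/substrate/both) are inferred, kinase families come from the
table (curated input, not sequence analysis). The responsive subnetwork
keeps every edge with at least one endpoint in the DEP protein set — a
responsive substrate retains its upstream kinases even when those were not
identified — with a stricter both-endpoints mode available. Family
interaction counts group edges by the kinase endpoint's family ("other" when
unannotated) and conserve the edge total.

## Synthetic data generator

The generator emulates the *quantified table*, not spectra. Eight archetype
mean-log2FC shapes over (5, 15, 30, 60) min, scaled by the effect size e
(default 1.5):

| archetype | shape (×e) |
|---|---|
| A | (1, 0.25, 0.10, 0) |
| B | (0.10, 1, 0.25, 0.05) |
| C | (0, 0.10, 1, 0.25) |
| D | (0.05, 0.10, 0.25, 1) |
| E | (1, 0.60, 0.70, 0.90) |
| F | (−0.50, −0.70, −0.85, −1) |
| G | (−1, −0.25, −1, −0.50) |
| H | (0, 0, 0, 0) |

The transient shapes keep at least one entry below ε/2 so that the
sustained-response rule cannot capture them; E stays above e/2 everywhere;
G's rebound shape is a modeling choice (no functional form is standard for
fluctuating dephosphorylation). Baseline log2 intensities are N(20, 2);
cold-time intensities multiply the baseline by 2^(profile + N(0, noise_sd))
per replicate, with i.i.d. Gaussian log2 noise (default sd 0.25, the
simplest model consistent with a log-scale analysis). Cells go missing
independently with probability 0.05.

Sequence design: every planted site sits at the center of a 13-mer whose
other positions are drawn from the 17 non-S/T/Y letters, so each protein
contributes exactly one background window per planted site and planted-motif
prevalences are exact — a window either matches a planted pattern (with the
configured foreground/background probability) or is explicitly resampled not
to match it. Site residues follow the 85/12/3 S/T/Y convention; ~10% of
peptides are doubly phosphorylated (21-mers, two windows); ~10% of peptides
receive a sub-0.75 localization probability to exercise the class-I filter.
GO enrichment is planted by assigning a signal term to 50% of early-response
proteins vs 5% elsewhere. Default size is 100 peptides per archetype with
300 background proteins — large enough for stable K-means recovery and motif
counts above the 30-occurrence floor, small enough that a full pipeline run
takes seconds.

What the generator does *not* model: charge states, retention time, peptide
flyability, intensity-dependent missingness (missingness is MCAR),
correlated noise between co-eluting peptides, shared peptides across
proteins, and annotation incompleteness. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under the stated
generative model, not performance on real spectra-derived tables.

## Numerical choices and degenerate inputs

* Fisher p-values come from the exact hypergeometric distribution; the test
  suite checks them against an integer-arithmetic enumeration oracle to
  1e-12 over all 2×2 tables with margins ≤ 30.
* Benjamini–Yekutieli uses the step-up form with the harmonic factor,
  monotone-enforced and clipped at 1; checked against a direct formula
  oracle.
* t-tests with identical groups return p = 1; groups with fewer than two
  non-missing values return NaN and are flagged.
* K-means ties and restarts are resolved by best within-cluster sum of
  squares under a fixed seed; all stage seeds fan out from the single run
  seed via counter-based seed sequences (stable, below 2^31), so stages can
  be re-run in isolation.
* Empty results (no peptides after filtering, empty DEP set at a time point,
  empty subnetwork) produce warnings and well-typed empty outputs, not
  errors.

## Known limitations

* The archetype label of a peptide is the label of its cluster; if K-means
  merges two planted archetypes at very low effect/noise ratios, both
  receive one label. Recovery is validated at effect 1.5 / noise 0.25.
* The permutation test for bias trends assumes within-group exchangeability
  of residuals; heteroscedastic replicates would inflate the trend count.
* The Group A/B split is annotation-membership-based; it does not re-run a
  per-compartment enrichment before splitting.
* Protein-level abundance summaries use Tukey median polish; proteins with
  fewer than two peptides are excluded from the stability check.
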