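# Methods

## Model

The engine is a lazy local-regression scheme: no global model is ever fit.
For each query it collects training compounds above a Tanimoto similarity
threshold on MolPrint2D fingerprints, fits a similarity-weighted random
forest on their measurements, and predicts the query with a 95% interval.
The approach assumes (i) that structurally similar compounds tend to have
similar chronic toxicity (the read-across premise), and (ii) that the
spread of the local model's out-of-sample errors is a usable proxy for the
error on the query. Both assumptions degrade with distance from the
training data, which is why the applicability-domain tiers exist.

### Fingerprints and similarity

MolPrint2D describes each heavy atom by its own type plus the multisets of
types at bond distance 1 and 2. The atom type used here is the element
symbol with an aromaticity flag (lower-case for aromatic atoms, e.g. `C`
vs `c`); this is deliberately minimal and toolkit-independent, and is
swappable via the `atom_typer` argument. Richer type schemes (Sybyl types,
hybridization) would produce different absolute similarity values but the
same machinery. Hydrogens are excluded. Fingerprints are **sets** of
distinct environments — the Tanimoto index is defined on set cardinalities,
so repeated environments (symmetric atoms) do not count twice. A
consequence worth knowing: long unbranched alkanes beyond pentane share a
single identical fingerprint.

RDKit provides parsing, canonical SMILES (used for all duplicate detection
and leakage control; the dialect is recorded in dataset metadata as
`canonicalization`) and average molecular weights for the mg→mmol
conversion.

### Preprocessing

Doses are converted to mmol/kg bw/day and rounded to five significant
digits **once**, at conversion; all later equality tests compare the
rounded decimal representation, never floats within an epsilon, which makes
the duplicate rule (same canonical structure, same 5-digit value → same
study, keep one) deterministic. Analyses use −log10 of the molar dose. The
training set is the union of the two source databases; the test set is all
records of structures present in both. Rows with empty doses are dropped
and counted; unparsable SMILES go to a reject report instead of failing
the read.

### Local models

- Neighbors contribute one row per measurement (not a pre-aggregated
  median), so experimental variability propagates into the model and its
  interval; row weight = neighbor similarity, used in every fit.
- Environments constant across the neighbor set (present in all or in
  none) carry no signal and are removed before fitting. If nothing varies,
  the forest cannot be built and the weighted-mean fallback fires.
- The features-per-split hyperparameter (mtry) is tuned over the grid
  {√p, p/2, p} with 25 bootstrap resamples. Resampling is at the
  **compound** level: replicate rows of one compound never straddle the
  resample/held-out split, because the query is always an entirely unseen
  compound — row-level resampling lets replicates leak across the split
  and collapses the error estimate toward replicate noise (observed as
  under-covering intervals before the change).
- The prediction-interval RMSE is the pooled out-of-resample RMSE of the
  winning candidate; the interval is symmetric, value ± 1.96·RMSE. For the
  weighted-mean fallback, where no resampled model exists, the RMSE is the
  similarity-weighted RMS deviation of the neighbor measurements around
  the weighted mean; with a single measurement this degenerates to a
  zero-width interval, which is acceptable because such predictions are
  always flagged anyway.
- Forest sizes: 10 trees per tuning fit, 100 in the final fit. Tuning
  forests are deliberately small — at local-model sizes (typically 5–50
  rows) the fit cost is dominated by per-fit overhead, and 75 tuning fits
  per query add up; the slightly pessimistic error estimate of a small
  forest errs on the conservative side for the interval.
- A forest is attempted only with ≥ 2 distinct neighbor structures; below
  that the fallback fires.

### Tier procedure

Threshold 0.5 first; on *any* failure (no neighbors, too few distinct
neighbors, no informative features, fit error) the entire procedure repeats
at 0.2 with a warning; if the forest fails there too, the weighted mean
over the 0.2-neighbors is returned with a second warning; with no
neighbors at 0.2 a typed no-prediction result is produced. The
weighted-mean fallback therefore always carries threshold 0.2 — a failure
at the 0.5 tier falls through to the lower tier rather than to the mean of
the 0.5-neighbors. Warning-free predictions define the "ad-close" tier in
all validation summaries; warned ones "ad-distant".

### Validation

Test-set evaluation strips nothing explicitly: the engine's hardcoded
exclusion of the query's canonical structure already removes every one of
its records, which the evaluation layer re-asserts per prediction. Scores
compare predictions against the **median** of a compound's replicate
−log10 values. Cross-validation shuffles unique structures into k folds
(all measurements of a compound travel together) with independent shuffles
per repeat; summaries are aggregated as mean ± SD over repeats. Pearson
r², RMSE and the correlation-test p-value are reported; p-values are never
used as pass/fail logic. Prediction-interval coverage is counted per
measurement (every experimental value of a predicted compound against that
compound's interval).

## Variability analyses

Per-compound spread uses the sample (n−1) standard deviation; the
database-level figure is the unweighted mean over compounds with ≥ 2
measurements. For the between-database correlation, value pairs identical
at five significant digits in both databases are removed from both sides
first (they likely report the same experiment; matching is multiset-wise
per compound), and per-database medians of the remainder are correlated.
The SD comparison uses Welch's t-test. The small-compound comparison
(< 11 heavy atoms) uses the 2×2 chi-square test, reported both without
(headline) and with Yates continuity correction.

## Synthetic data generator

The generator emulates the statistical structure of real chronic-toxicity
collections at desk scale:

- **Clusters**: 12 scaffolds (fixed internal list of parseable ring/chain
  systems with one substitution slot), each decorated with 6 distinct
  small substituents. Within-cluster Tanimoto similarity is verified
  ≥ 0.5 at generation (minimum observed ≈ 0.56).
- **Activity**: cluster base ~ Uniform(0, 4) on the −log10 mmol/kg scale
  (spanning roughly the potency range of chronic oral studies), member
  offsets ~ N(0, 0.15) — a modest within-scaffold structure–activity
  signal.
- **Satellites**: 2 per cluster, the same scaffold with a bulky
  substituent, verified to sit in the similarity band [0.2, 0.5) to every
  regular member, with larger activity offsets (SD 0.35). These populate
  the ad-distant tier and encode the empirical pattern that structurally
  more distant analogs carry weaker structure–activity fidelity.
- **Singletons**: 8 compounds from a small-molecule pool, each verified
  < 0.2 similar to everything else generated; the engine must return
  no-prediction for them.
- **Replicates and noise**: measurements per compound per database are
  min(Geometric(0.6), 4) — mostly 1–2, occasionally more — and each
  measurement is the true value plus N(0, 0.3) on the −log10 scale
  (lognormal on the dose scale). SD 0.3 matches the magnitude of
  inter-study variability observed for replicate chronic LOAELs.
- **Overlap**: each compound appears in both databases with probability
  0.25 (roughly the overlap fraction of the real source databases),
  otherwise in one of them; the overlap defines the synthetic test set.
- Same seed → byte-identical CSVs.

What the generator does **not** emulate: real toxicophore chemistry,
correlated assay artifacts, dose-spacing effects, censoring, or the heavy
right tail of real structure distributions. Passing tests on this data
demonstrate the correctness and calibration of the machinery under its own
assumptions (noise recovery, tier ordering, leakage control), not
predictive validity on real chemicals — that is what the reproduction
tests against the published curated databases are for.

## Problem sizes

The bundled evaluations use the generator defaults (104 structures, ~190
records) for the test-set evaluation and 3 repeats of 10-fold
cross-validation; these sizes keep a full pipeline run in the
single-digit-minute range on one CPU while leaving every tier populated
with enough predictions for stable summaries.

## Known limitations

- Exact fingerprint-level equality with OpenBabel's MolPrint2D atom typing
  is not claimed; similarity values and hence neighbor sets can differ in
  borderline cases. Method-level behavior is equivalent.
- The original study's forest size, tuning grid and resample count were
  framework defaults and are not published; the values here are
  configuration, so numeric equality with the original predictions is not
  expected.
- The weighted-mean fallback weighs per measurement (a compound with more
  replicates pulls harder); per-compound weighting is equally defensible.
- Average (not monoisotopic) molecular weight is assumed for unit
  conversion.
- With fewer than ~5 neighbors the RMSE estimate is itself noisy; intervals
  for such predictions are unstable in both directions, which is one more
  reason warned predictions deserve manual inspection of the neighbor
  table.
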