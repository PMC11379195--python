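# Methods

## Problem and data model

The pipeline classifies tissue samples as cancer or normal from Illumina
450k methylation profiles. Each sample is a vector of beta values
β = M/(M+U) ∈ [0, 1], one per CpG probe; probes carry a chromosome and
position, with the sentinel position `*` marking probes that do not exist
on the genome build (these are systematically missing). The in-memory
container is `LabeledBetaMatrix`: a samples × sites float matrix (NaN =
missing) plus per-sample labels (`Cancer`/`Normal`), per-site coordinates
and a tissue tag. A boolean `is_test` flag implements the test-set
quarantine: fitting routines refuse a flagged matrix.

## Preprocessing

Stages run in a fixed order; the order is part of the method.

1. **Unmapped-probe removal.** All position-`*` columns are dropped.
2. **Missingness filters, sites then patients.** A site is dropped when
   its NA fraction is *strictly* greater than 0.15; patients are then
   filtered the same way on the reduced matrix. The order is not
   commutable — removing a bad site changes every patient's NA fraction —
   and is chosen because an array has ~400k sites but only hundreds of
   patients, so losing a site costs less than losing a patient. The
   exactly-15% boundary is retained ("more than 15%" is strict).
3. **Mean imputation.** Each remaining NA becomes the arithmetic mean of
   its site's observed values, pooled over all retained samples of the
   cohort (cancer and normal together, per tissue). This happens *before*
   the split, which faithfully reproduces the published procedure but is
   mild train/test leakage: test-sample values contribute to the imputation
   means. Callers wanting strict hygiene can split first and impute
   partitions separately; the default deliberately reproduces the
   procedure as stated.
4. **Binarization.** Call 1 (methylated) iff β ≥ 0.3, else 0. The 0.3
   threshold exploits the bimodality of the human methylome.
5. **Split.** Uniform random permutation into 70% train / 20% validation /
   10% test. Sizes: train and validation are round-to-nearest
   (⌊f·n + 0.5⌋), the remainder goes to test — the unique simple rule that
   reproduces all nine published cohort sizes (439 → 307/88/44,
   484 → 339/97/48, 542 → 379/108/55). Unstratified by default (the
   procedure says only "randomly divided"); stratification is available
   as an option.

**QC.** Two checks mirror the exploratory analyses: per-group first four
moments of the pooled beta values (population variance, standardized
skewness, excess kurtosis; a constant group reports NaN for the shape
moments), and a two-component PCA projection of the continuous
training + validation values (mean-centered SVD; deterministic sign
convention: each axis's largest-magnitude loading is positive). The test
partition is excluded from both.

## Panel selection

**Entropy.** Node impurity is binary entropy in bits,
H = −p_N log₂ p_N − p_C log₂ p_C, with 0·log 0 ≡ 0; base 2 is forced by
the convention that an evenly mixed node scores exactly 1.

**Depth-2 trees.** The root split maximizes information gain (parent
entropy minus child-size-weighted child entropy) over all non-masked
sites; each impure child is split once more the same way (the root's site
is additionally barred within the tree); pure or unimprovable children
become leaves predicting their majority class. Ties in gain break to the
lowest column index, with a 1e-12 tolerance so that mathematically tied
columns are not ordered by float rounding noise. Majority ties in a leaf
predict Cancer (the conservative direction for a diagnostic). If no site
has positive gain at the root the tree signals `NoInformativeSplit`.

**Iterative masked selection.** Trees are fitted repeatedly; after each
run, its split sites (root first, then second-level children
left-to-right) join the panel and the exclusion mask, so later runs must
find fresh primary and secondary separating sites. The loop stops at the
end of the first run that reaches `min_panel` (default 10) sites — since
a run adds at most three, panels land at 10–12 — or early, with a logged
warning, on `NoInformativeSplit` or after `max_runs` (default 50). There
is deliberately no hard cap at 10: the sites a tree picks can be useful
only jointly, so a run's sites are kept or dropped together. Selection
runs on the binarized *training* partition by default; a flag pools
training + validation.

**Separation score.** For each selected site, on the *continuous*
training + validation values:

    score = −((median_C − c)/SD_C) · ((median_N − c)/SD_N),  c = 0.3

SDs use the sample (n−1) convention. The score is positive iff the two
group medians straddle the cutoff, zero if a median sits exactly on it,
negative if both are on one side. Retention is strictly positive-score:
a zero score means the median-side rule cannot classify the site, and a
zero-SD group leaves the score undefined — both are excluded, with the
excluded rows and their scores recorded alongside the panel. If
refinement empties the panel (no informative signal in the cohort), the
pipeline warns and falls back to the unrefined panel so that a null
cohort still produces an end-to-end run with chance-level AUC rather
than an error.

## Classifier

A feed-forward network of logistic-sigmoid neurons, S(x) = 1/(1+e^(−x))
(computed branch-wise so ±1000 inputs neither overflow nor lose the
bound), with one output neuron scoring P(cancer). Preset hidden layers:
A = (7, 4), B = (10, 10), C = (5, 4, 3); input width equals the panel
size. Inputs are the binarized panel features (binarization precedes all
processing); a continuous-input mode simply means passing an unbinarized
feature frame.

Training is full-batch gradient descent on mean-squared error (binary
cross-entropy by flag) with learning rate lr(t) = lr₀/(1 + k·t) — a
schedule that decreases slowly over time — and seeded uniform(−0.5, 0.5)
weight/bias initialization. Defaults: lr₀ = 2.0, k = 0.01, up to 20 000
epochs, stopping early when the per-epoch loss improvement falls below
1e−9. The initial rate was chosen because smaller values (e.g. 0.5)
leave the deepest preset (5, 4, 3) stuck on the constant-output MSE
plateau (loss ≈ label variance): four stacked sigmoid layers attenuate
the error signal by factors of S′ ≤ 1/4 per layer, and with small
initial weights the early, largest steps of the decaying schedule are
the only chance to escape. At lr₀ = 2.0 all three presets reach held-out
AUC 1.0 on the default synthetic cohort for every initialization seed
tried (12/12); dataset sizes (hundreds of samples, ≤ 12 features) make
batching unnecessary. Backpropagation gradients are verified against
central finite differences to 1e−5 in the tests.

## Evaluation

ROC analysis sweeps a threshold over the distinct predicted scores in
descending order (ties grouped: one point per distinct score), anchored
at (0,0) and (1,1), positive class = Cancer; AUC is the trapezoidal
integral, which the tests verify equals the pairwise-concordance
definition (fraction of cancer/normal pairs ranked correctly, ties
half-credit) to 1e−9. Final numbers come from the test partition only,
touched exactly once per pipeline run.

## Synthetic cohort generator

The generator emulates the features of repository cohorts the pipeline
actually exercises:

- **Background methylome** — each uninformative site is assigned one
  component of a two-part beta mixture, Beta(1.5, 8) (mostly
  unmethylated) or Beta(8, 1.5) (mostly methylated), weight 0.5: bimodal
  across sites, identical between classes, and same-side by construction,
  so background sites that sneak into a panel get negative separation
  scores.
- **Planted informative sites** — class-specific beta distributions whose
  *theoretical* medians straddle 0.3 (validated with the beta quantile
  function at configuration time, not by sampling). Defaults Beta(8, 2)
  vs Beta(2, 8) (medians ≈ 0.820 / 0.180) give the strong separation
  regime in which the published method reports near-perfect AUC; the
  direction (hyper- vs hypomethylated in cancer) is configurable per
  site, defaulting to hypomethylated-in-cancer, the pattern seen in two
  of the three published tissues.
- **Imbalance** — 200 cancer vs 120 normal samples by default (tumor
  repositories hold more tumors than adjacent-normal samples; the real
  ratio per tissue is unpublished, so ~5:3 is an illustrative choice).
- **Missingness** — 25 unmapped (`*`) probes that are entirely NA, as in
  GDC files where most NAs are non-existent probes; 20 "bad" sites and 5
  "bad" patients given an exact NA count strictly above the 15% filter
  threshold (bad sites are drawn from background columns so the planted
  signal survives filtering and recovery remains measurable); and a 1%
  base rate of uniform independent NAs. Missingness is
  missing-completely-at-random; no MNAR mechanism is modeled.
- **Determinism** — all randomness derives from one integer seed via two
  independent streams (values, missingness); identical configs produce
  byte-identical cohorts, and the planted/unmapped site identities are
  recoverable from the config alone.

What the generator does *not* emulate: probe-level technical effects
(type I/II chemistry, batch), covariate structure (age, smoking, cell
composition), spatial correlation along the genome, and realistic
450k-scale dimensionality (desk-scale default is 2000 sites). A green
test therefore establishes that the algorithmic machinery is correct and
recovers planted signal under the stated noise model — not that the
pipeline's published biological findings generalize.

## Numerical and design choices

- Strict thresholds: NA filters drop at > 0.15; score retention at > 0;
  binarization methylated at ≥ 0.3.
- Entropy/gain tolerance 1e-12; gain ties and float-noise ties break to
  the lowest column index.
- Imputation pools labels within a tissue (the stated "mean for that CpG
  site in the relevant tissue"), rather than per label group.
- Positions are carried verbatim as strings; no coordinate arithmetic.
- The panel TSV stores scores to 6 decimals; round-trips are exact to
  well under the 3-decimal tolerance the format guarantees.
- Model JSON serializes architecture, weights, biases, feature order and
  seed, so a trained classifier is portable and reproducible.

## Known limitations

- Pre-split imputation (and selection statistics pooled over
  training + validation) leak information into validation; the quarantined
  test set is unaffected and is the only partition used for final AUC.
- With ~30 test samples, AUC 1.0 has a wide confidence interval; the
  generator's strong-separation default makes the task easy by design.
- The depth-2 tree scan is O(n·p) per run and fine to ~10⁵ sites; no
  sparse or out-of-core path is provided.
- `NoInformativeSplit` on noise-only cohorts is rare (finite samples
  almost always yield some positive spurious gain), so `max_runs` is the
  practical stop in degenerate settings.
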