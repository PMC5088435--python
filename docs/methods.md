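# Methods

## Model and procedure

dynaprof stratifies a longitudinal severe-TBI cohort in stages. Stage −1
clusters on the initial GCS score alone; stage 0 adds the
clinical/demographic variables; stage i ≥ 1 clusters on the GCS, the
clinical variables, the orthogonal-polynomial trends of each CSF mediator
series over reading rounds 1..i−1 (degree at most d), and the 13 raw
mediator readings of round i. Capping the trend degree bounds the
clustering dimension: however long a patient is observed, stages 2 and
above share one fixed feature dimension (stages −1, 0 and 1 are smaller
by construction, since no mediator history exists yet).

A cluster's weight is (red-flag count, mean GOS, GOS s.d.), where a red
flag is a member with GOS = 1; red flags / size is the cluster's
empirical death probability. The per-stage sequence of these
probabilities for the cluster containing a given patient is the patient's
risk curve. Outcome prediction for an incoming patient matches their risk
curve — built by nearest-centroid assignment into each stage's existing
clusters — against the curves of all database patients, by absolute
difference of trapezoidal areas under the curves (unit spacing on the
stage axis), restricted to the stages both curves share, up to the
incoming patient's last reading round. The predicted class is the
binarized GOS of the closest patient; exact ties vote by majority, and a
residual tie predicts the poor-outcome class.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `degree` (d) | 2 | maximum polynomial trend degree; series need ≥ d+1 points to enter the outcome-model pool (profiling zero-pads shorter histories instead) |
| `k` | 3 | clusters per stage; chosen for cohorts of a few dozen patients |
| `n_restarts` | 25 | k-means restarts; the best within-cluster sum of squares wins |
| `method` | kmeans | `spectral` embeds through a Gaussian-affinity graph (bandwidth = median pairwise distance), symmetric-normalized Laplacian, k eigenvectors, then k-means |
| `t_cut` | 1.5 | backward-elimination threshold on \|t\| = \|coefficient/SE\| in the outcome model |
| `gos_rule` | survival (LOO); low_high for the outcome model's favorable/poor split | GOS binarization: survival = GOS > 1; low_high = GOS ≥ 4 vs ≤ 3 |
| `BetaPrior(α, β)` | none (optional) | conjugate prior on a cluster's death probability; posterior = Beta(α + red flags, β + survivors) |

## Numerical choices

* **Basis construction.** QR factorization of the Vandermonde matrix over
  indices 1..n, signs fixed so each column correlates positively with its
  monomial; columns are orthonormal to 1e-10 for all supported sizes
  (n ≤ 20 verified exhaustively, d ≤ 4). Actual reading times are ignored
  in the basis — rounds are the time axis — and the optional smoother is a
  centered window-3 moving average with shrinking end windows (off by
  default).
* **Standardization.** Every stage feature column is z-scored; the moments
  are stored per partition so a new patient's row is standardized
  identically. Zero-variance columns standardize to zeros.
* **Missing data.** A patient with no readings in round i is excluded from
  stage i (their risk curve skips that stage). Missing individual mediator
  values within an included row are imputed at the column median (training)
  or the stored column mean (new-patient assignment). A carried-forward
  alternative was evaluated and did not improve leave-one-out accuracy.
* **Cluster labels** are canonicalized by ascending cluster mean GCS, so
  the label sequence is reproducible across runs and removals.
* **Tie-breaks.** Nearest-centroid ties go to the lower canonical label;
  nearest-curve ties vote by majority class, residual ties predict Low.
* **Separation.** Small cohorts with strong predictors can separate
  completely; the logistic/probit fit then flags it and refits under a
  small quadratic penalty (λ = 1e-4) so coefficients and standard errors
  stay finite, with the penalized observed information supplying the
  covariance.
* **k-means** is scikit-learn's Lloyd algorithm with k-means++ starts;
  the contract is best-of-restarts WCSS, verified against brute-force
  enumeration of all partitions on instances with n ≤ 9.

## Synthetic cohort generator

The generator emulates the data regime the method targets: default 27
patients, death fraction 7/27, admission GCS from class-specific truncated
normals (survivors 6.0, non-survivors 5.6, s.d. 1.0, range 3–8), ages
~34/38 ± 14, 90% male, 4–13 reading rounds roughly 24 h apart, and 5%
independently missing readings. Concentrations are log-normal
(right-skewed, non-negative, as cytokine panels are), with outcome effects
acting additively on the log scale: non-survivors receive per-mediator
linear/quadratic trends in the normalized round position u ∈ [0, 1],
concentrated in the canonical pro-inflammatory axis (TNF-α strongest at
+2.0 log units by the final round ≈ 7-fold, IL-6, IL-8, MIP-1α/β, IL-1β
weaker) and the anti-inflammatory IL-10 (+1.5u − 1.0u²); `effect_scale`
multiplies all of them, so 0 gives identical class dynamics by
construction. GOS among survivors is uniform on {2, 3, 4, 5}; clinical
flags are mildly class-informative Bernoullis. Reading-round indices are
emitted directly by the generator (ordinal re-indexing after missingness
would silently shift rounds).

What the generator does **not** emulate: inter-mediator correlation beyond
the shared class effect, assay detection limits and censoring, treatment
effects, and any mechanistic inflammation dynamics. Passing tests
therefore show that the pipeline recovers the structure it assumes — not
that real CSF panels contain that structure.

## Design choices where the design was open

* Trend polynomials are *discrete* orthogonal polynomials over equally
  spaced round indices (the classical orthogonal-contrast construction),
  not continuous Chebyshev-T polynomials: the data are short discrete
  series of unequal lengths, and orthonormality per series is what makes
  coefficients comparable across lengths.
* Rounds default to ordinal per-patient indexing (the j-th available
  reading is round j), with a time-binned alternative
  (round = ⌊t/bin⌋ + 1).
* The level (degree-0) trend term is included in the candidate pool — the
  13(d+1) predictor count only works out if it is.
* The outcome model's candidate pool (10 clinical + 13(d+1) trends)
  cannot be fit jointly on a few dozen patients; blocks (clinical; each
  mediator's trends) are screened marginally at |t| ≥ t_cut, survivors are
  pooled, and backward elimination prunes the pool.
* Leave-one-out evaluation reuses the same clustering seed for every
  holdout so that differences come only from patient removal; the
  held-out patient's final reading round sets the prediction horizon.
* Evaluation problem sizes: replicate cohorts of n = 40 and 20 (test) or
  5 (acceptance script) replicates for the leave-one-out studies, n = 200
  with 50 replicates for interval-coverage checks.

## Known limitations

* Areas are compared over the *common* stages of two curves; a patient
  observed for 4 rounds is compared with everyone over at most their own
  horizon. A span-normalized variant was evaluated and kept out (no
  accuracy gain, one more convention to document).
* Database risk curves include each member's own outcome in their cluster
  weights (a held-out patient's curve cannot); a jackknifed variant was
  evaluated and did not improve matching accuracy.
* With k = 3 and a few dozen patients, late stages can thin out to
  near-singleton clusters whose death probabilities saturate at 0 or 1;
  the Beta-prior posterior is the provided remedy when external expertise
  exists.
* The multinomial (5-level GOS) model is deliberately out of scope; the
  binary low/high and survival models are the deliverables.
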