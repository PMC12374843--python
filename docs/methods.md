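# Methods

This note documents the statistical model, the federated protocol, the
numerical choices and the simulator behind `fedabund`, including the design
decisions that were genuinely open and the limits of what the test suite
demonstrates.

## Model and estimation

Per protein group *p*, observed log-scale intensities follow the linear
model `Y_p = Xβ_p + ε_p`. The global design `X` contains, in this order:
the two target-class one-hot columns, optional covariates, and cohort
indicator columns for every cohort except the first (reference coding, as
in standard linear-model practice). Both class columns are kept and the
model has no intercept, so the class contrast `K = (+1, −1, 0, …)`
estimates the A-minus-B log₂ fold change directly.

**Missing data.** No imputation is ever performed. A protein's model uses
only its observed samples, reproducing pooled least-squares row-deletion.
Because dropping all samples of a cohort empties that cohort's indicator
column, a per-protein *design mask* removes:

* cohort columns of cohorts with zero observations for the protein;
* the indicator of the lowest-indexed observed cohort when the reference
  cohort itself has no observations (that cohort becomes the protein's
  reference — keeping the column would leave the reduced design collinear
  with the class columns);
* class/covariate columns none of whose supporting samples are observed.

Per-protein estimability beyond the mask is decided by Cholesky
factorization of the masked `XᵀX` with tolerance `1e-10 × max(diag)`;
rank-deficient proteins are flagged and excluded from moderation and from
the BH denominator. Residual df is `m_p − |v|_p` (observed samples minus
unmasked columns); proteins with df ≤ 0 are likewise excluded.

**Moderation.** The scaled-F prior for residual variances is fitted by the
method of moments on `z = log s²` using digamma/trigamma identities; the
prior df solves a trigamma equation by monotone Newton iteration
(tolerance 1e-8). When the spread of `z` does not exceed the sampling
spread implied by the residual df, the prior df is infinite and the prior
variance is the mean variance. Posterior variances are the df-weighted
average of residual and prior variance; moderated t uses
`df_residual + df_prior` degrees of freedom (we deliberately do not cap
this at the pooled df — the cap matters only in the near-infinite-prior
limit). Confidence intervals are `β′ ± t₀.₉₇₅ · st.dev′ · √σ²_post`.

The contrast standard deviation is the exact per-protein quadratic form
`√(Kᵀ(XᵀX)⁻¹K)`, evaluated through the correlation-matrix Cholesky route.
Note that the widely used R implementation of contrast fitting applies one
global coefficient-correlation matrix to all genes — a documented
approximation that is exact only for complete-case genes. We compute the
per-protein covariance on *both* the federated and the pooled side, so the
two pipelines remain bit-comparable; the R cross-validation test restricts
exact t-statistic agreement to complete-case proteins for this reason.

**B statistic.** The log posterior odds of differential abundance uses the
two-component mixture model with prior DE proportion `p_de` (default 0.01)
and a coefficient-variance scale estimated by matching the largest |t|
statistics to their expected mixture quantiles, clipped to
`(0.1², 4²)/σ²_prior`. B is reported for ranking only; DE calls always use
`|log₂FC|` and the BH-adjusted p value (count-adjusted when available).

**Peptide-count adjustment.** With minimal precursor-peptide counts
available, `log s²` is regressed on `log₂(count)` with a local quadratic
tricube-weighted smoother (span 0.75) when at least 10 distinct counts
exist, otherwise with per-count-bin means; the count-specific prior
variance is read off the trend (with the log-F bias correction) and the
count-specific prior df re-estimated from the residual spread around the
trend by the same moment method. If every protein shares one count the
trend carries no information and the count-free moderation is returned
unchanged. The smoother is our own implementation; its exact shape only
has to be *identical* between the federated and pooled pipelines, which it
is by construction since both call the same code on the same aggregates.

## Federated protocol

Seven steps; every cross-client numeric aggregate is a sum and travels
through additive secret sharing:

1. *Join/harmonize* — clients announce protein-group lists (identifiers
   normalized by sorting accessions within a group), sample counts and
   optional per-protein minimal peptide counts; the coordinator forms the
   feature union (absent features become all-missing rows), the variable
   list, and global minimal counts. A privacy guard aborts the study when
   clients outnumber the pooled samples (equality passes; with at least
   one sample per client the guard is a backstop for misconfiguration).
2. *Filters* — (i) client-side: any value that is the only observation
   among the samples of a design column is blanked (this subsumes the
   whole-cohort single-observation rule); (ii) global: a protein is kept
   when every target class is observed in at least `1 − f` of its samples
   (`f` = 0.8 by default, read as the maximum missing fraction; a
   `min_observed` switch implements the alternative reading "observed
   fraction ≥ f"); (iii) optional removal of proteins whose global minimal
   peptide count is 1.
3. *Normalization (optional)* — cross-client median normalization
   (`Y/Med_j × Med̄`, with `Med̄` the sample-count-weighted mean of client
   mean sample-medians) and, for multiplexed designs, internal reference
   scaling inside each client using in-silico references (per-plex
   per-protein means; scale factor = geometric mean across plexes divided
   by own reference). Proteins with undefined or non-positive references
   in any plex are left unscaled and reported, never silently rescaled.
   Both operate on non-log data; `log₂(x+1)` follows if configured.
4. *Design mask* from securely summed per-cohort observation counts and
   per-column support counts.
5. *Federated least squares* — secure sums of per-client `XᵀX`, `XᵀY`,
   then of local SSE computed from the broadcast coefficients.
6. *Contrast, moderation, BH* on the coordinator.
7. *Count adjustment* (skipped when any client lacks counts).

The coordinator sees: protein-group names, dimensions, share-sums and
global model parameters — never a per-sample value. A transcript of
coordinator-bound messages is recorded and audited in tests. Minimal
peptide counts are per-protein metadata (a minimum over samples), not
per-sample data, and are sent in plain form like the feature names.

### Secret sharing

Each client splits a block into `n` pieces over `Z_q`: `n − 1` uniform
noise masks and the encoded block minus their sum. Pieces are routed so no
party holds two pieces of one client; parties forward only their piece
sums. Encoding is **binary fixed point with scale 2¹⁰⁷⁵** and modulus the
Mersenne prime `2²²⁰³ − 1`. Every finite float64 is an integer multiple of
2⁻¹⁰⁷⁴, so encoding is lossless and the decoded aggregate equals the
correctly rounded exact sum of the client values — aggregation itself adds
zero error, which is what makes sub-picoscale federated-vs-pooled
agreement possible. (A decimal fixed-point scale such as 10¹⁰ would
quantize the plaintext and dominate the comparison.) The threat model is
honest-but-curious parties without collusion; real transport encryption
and relay infrastructure are out of scope — the in-process router
preserves only the share-distribution topology.

Remaining federated-vs-pooled differences stem solely from float
summation order (pooled matrix products vs exact sums of per-client
blocks), i.e. ~1 ulp per aggregate, observed end-to-end as ≤ ~10⁻¹³ in
−log₁₀(adjusted p).

## Simulator

The generator emulates multi-center label-free proteomics after
MaxLFQ-style quantification (hence no per-sample size effect and no
normalization step in the default analysis):

* per-protein means `μ_p ~ N(0, 2)` (the second parameter is a variance)
  and variances `σ²_p ~ InverseGamma(shape 2, scale 3)` with density
  `∝ x^(−shape−1) e^(−scale/x)`;
* intensities from a two-component mixture with outlier proportion
  `π_p ∈ [0, 0.5)` (0 by default);
* 600 samples, 300 per condition; a 200-protein DE block shifted by
  `Δμ = 1.25` in condition B, each protein realizing the shift with
  probability 0.8 and a random sign; a 150-protein confounder block
  shifted only in flagged class-B samples;
* cohort-aligned ComBat-style batch effects
  `y + γ_pi + δ_pi ε`, with `γ ~ N(0,1), N(0.2,0.5), N(−0.2,1.5)` and
  `δ ~ IG(3,2), IG(2.5,1), IG(4,0.5)` per batch (second normal parameters
  are variances);
* missingness at an exact overall rate (default 0.2), half of it
  intensity-dependent (MNAR: cells chosen by tricube-decaying weights on
  the within-protein intensity quantile via Gumbel top-k sampling) and
  half completely at random;
* three imbalance scenarios (cohort sizes / class-B counts / confounder
  frequencies among class-B): balanced `(200,200,200)/(100,100,100)/0.3`;
  mild `(150,200,250)/(60,100,140)/(0.1,0.3,0.5)`; strong
  `(100,200,300)/(20,100,180)/(0.0,0.2,0.8)`. The mild/strong frequency
  tables are this package's defaults, chosen to span a clearly graded
  confounding range; they are configuration, not estimates of any
  particular study.
* synthetic minimal peptide counts, when requested, are
  `1 + Poisson(3)` per protein, shared across cohorts. Count adjustment is
  off in the default simulation analysis since counts carry no signal
  there.

What the simulator does *not* emulate: protein-group overlap structure
across sites, spectrum-level noise, retention-time artifacts, or real
batch-correction workflows. Passing equivalence tests on simulated data
therefore demonstrates *numerical* equivalence of the two computation
routes under realistic dimensions, missingness and imbalance — not
biological validity of any particular DE call.

## Verification strategy

* secret sharing: exactness against `math.fsum` (0 ulp), uniformity of
  shares, subset non-recoverability (property tests);
* linear algebra: closed forms, brute-force least-squares oracles,
  re-partition invariance of moment aggregation;
* moderation: cross-validated against the reference R implementation
  (limma) on complete data to ~10⁻¹⁴ for t, p, priors and B, and on
  missing-data designs for coefficients, residual variances and df;
* prior fit: parameter recovery within 5% at n = 20,000 simulated
  variances; infinite-df degenerate cases; null type-I error calibration;
* end-to-end: federated vs pooled agreement ≤ 4×10⁻¹² worst case (observed
  ~10⁻¹³) on full-scale studies, identical DE calls in every scenario and
  seed, and meta-analysis baselines (Fisher/Stouffer) degrading with
  imbalance while the federated pipeline stays exact.

Full-scale runs use 6,000 proteins × 600 samples split into three cohorts,
5 seeded repetitions per scenario — ample to exercise every masked-design
and filtering path while keeping the whole verification suite at a few
minutes of CPU.

## Known limitations

* Honest-but-curious security only; no protection against colluding
  parties or a malicious coordinator, and no transport-layer encryption.
* Single two-class contrast; multi-contrast support is deferred.
* Protein groups are matched across clients purely by the normalized
  identifier string; overlapping-but-different accession sets are treated
  as distinct features.
* Fisher/Stouffer are the only built-in meta-analysis baselines; random
  effects and rank-product combination are external methods whose result
  tables can be compared with `fedabund evaluate` but are not
  reimplemented here.
* The B column depends on a heuristic coefficient-variance estimate and is
  excluded from equivalence guarantees (it is identical between the two
  pipelines by construction, but its absolute value is method-specific).
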