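# Methods

## Scientific setting

`eegconnectome` implements a resting-state functional-connectivity analysis
for high-density (256-channel geodesic net) EEG across four diagnostic
groups — healthy controls (HC), subjective cognitive decline (SCD), mild
cognitive impairment (MCI) and Alzheimer's dementia (AD), with cohort sizes
22/20/30/20.  Connectivity is the absolute Pearson correlation between
channel time series; networks are fully weighted and undirected; three graph
measures (weighted clustering coefficient, strength, betweenness centrality)
are evaluated at two scopes: the whole head (256 nodes) and a parietal
cluster.  Clinical EEG of this kind is not publicly deposited, so the
package ships a synthetic-cohort generator whose correlation structure is
known in closed form; every downstream stage is validated against that
oracle and against exhaustive brute-force enumeration.

## Synthetic cohort model

Channel `c` of a subject in group `g` is

    x_c(t) = signal_scale * ( a_c * s_P(t) + beta * s_G(t) + eps_c(t) )

with `s_P` a parietal cluster source, `s_G` a weaker whole-head common
source, and `eps_c` channel noise — all independent, unit-variance,
stationary AR(1) processes with coefficient `phi = 0.95`.  The loading `a_c`
equals `alpha_g` on parietal channels and 0 elsewhere.  Population values:

* parietal–parietal correlation: `(alpha_g^2 + beta^2) / (alpha_g^2 + beta^2 + noise_sd^2)`
* non-parietal pair: `beta^2 / (beta^2 + noise_sd^2)`

Defaults: `alpha = 1.9 / 1.5 / 1.4 / 1.2` for HC/SCD/MCI/AD, `beta = 0.6`,
`noise_sd = 1`, giving parietal correlations ≈ 0.80 / 0.72 / 0.70 / 0.64 — a
monotone weakening of parietal coupling with disease stage whose magnitude
matches the reported group means of the local clustering coefficient in this
literature.  AR(1) at `phi = 0.95` stands in for the 1/f-like spectrum of
resting EEG: it is the simplest process with realistic autocorrelation and a
tractable stationary variance.  `signal_scale = 10 µV` puts channel RMS near
20 µV, typical of scalp EEG.

Artifacts are 50-sample square pulses of ±150 µV written into a random
channel of each affected 500-sample window (window probability 0.05); square
pulses give unambiguous threshold crossings for the rejection rule.  Two
channels per subject are overwritten with white noise at 5× the subject RMS
and listed as bad.  Recordings default to 120 s at 250 Hz (60 windows); the
eyes-closed resting duration actually analyzed in such studies is of this
order, and the duration is configurable.

Subject streams are keyed by `(seed, group, index)`, so a cohort is
reproducible bit-for-bit and invariant to the ordering of the group map.
Full-size cohorts are streamed one subject at a time (`iter_cohort`); 92
recordings of 256 × 30000 doubles would otherwise need ~5.6 GB resident.

What the generator does *not* emulate: ocular/muscle artifact morphology,
spatially structured (distance-dependent) correlations outside the parietal
block, non-stationarity, volume-conduction geometry, and eyes-open segments.
Passing tests therefore certify the analysis machinery and its statistical
calibration on a known truth — not performance on clinical recordings.

## Preprocessing

Fixed stage order: bandpass filter → segmentation → artifact rejection →
bad-channel interpolation → average re-reference.

* **Filter**: 5th-order Butterworth bandpass, 0.3–75 Hz, applied zero-phase
  (forward–backward) as cascaded second-order sections.  SOS keeps the
  design stable with a 0.3 Hz edge at 250 Hz; zero-phase filtering avoids
  phase distortion of cross-correlations.
* **Segmentation**: non-overlapping 500-sample windows; trailing remainder
  dropped.
* **Rejection**: a window is dropped if any scanned channel exceeds 100 µV
  in absolute amplitude *after* filtering.  Channels already flagged bad are
  excluded from the scan — they are repaired in the next stage, and a
  saturated bad channel would otherwise veto every window.
* **Bad channels**: flagged upstream (manifest) or detected by variance
  exceeding 5× the median channel variance; each is replaced by the
  inverse-distance-weighted mean of its 6 nearest good neighbours on the
  montage sphere.  More than 20% bad channels is an error (interpolation
  deemed unreliable).
* **Re-reference**: subtract the instantaneous mean across channels.
  Continuous resting data has no pre-stimulus baseline; baseline handling is
  per-window channel-mean removal, which is exactly neutral for Pearson
  correlations (location invariance, asserted by a property test).

## Connectivity

Per retained window, the matrix of |Pearson r| between all channel pairs
(diagonal zero); per subject, the element-wise mean of the per-window
matrices, with the absolute value taken *before* averaging.  Averaging
per-window estimates rather than correlating concatenated data damps
non-stationarity.  The parietal ("local") network is the principal submatrix
over the parietal electrode labels.  The printed parietal electrode list in
the source literature has 29 entries of which two (E87, E63) are duplicates;
the default local scope uses the 27 unique electrodes, and the verbatim
29-entry list is kept in `montage.PARIETAL_LIST_RAW`.  The vertex reference
Cz is not among the analyzed channels.

## Graph metrics

All metrics operate on the raw |r| weights (no thresholding, no max-weight
normalization); graph-level values are node averages.

* **Strength** `S_i = Σ_j w_ij`.
* **Clustering** (Onnela geometric-mean form):
  `C_i = (1 / (k_i (k_i−1))) Σ_{j≠h} (w_ij w_ih w_jh)^{1/3}` with `k_i` the
  count of nonzero-weight neighbours; nodes with `k_i < 2` score 0 and are
  excluded from the graph average.  On a near-uniform correlation network
  this choice makes `C_i` track the mean neighbourhood weight (so the local
  clustering value is commensurate with the mean parietal correlation),
  which max-weight normalization would break.
* **Betweenness**: edge length `1/w` (zero weight = no edge), Brandes
  single-source dependency accumulation with fractional credit for tied
  shortest paths, normalized by `(N−1)(N−2)` ordered pairs so values lie in
  [0, 1].  Path-length ties use exact float equality: appropriate for
  continuous weights (ties have measure zero) and exact for the structured
  integer-length graphs used in tests.

Equivalence with exhaustive enumeration (all simple paths, triple loops) is
asserted to 1e-12 on hundreds of random graphs, and independently against
networkx.

## Group statistics and ROC

One-way ANOVA per metric and scope across the four groups; pairwise
independent-sample t-tests with pooled variance (df = n_a + n_b − 2) are run
only when the omnibus test is significant at 0.05, and interpreted against
the Bonferroni level 0.05/6 ≈ 0.008 for the six pairwise contrasts.
Metric–score associations use the Pearson correlation with the exact
`t = r √((n−2)/(1−r²))` null, uncorrected.

ROC analysis covers 4 one-vs-rest and 6 one-vs-one contrasts per metric and
scope.  AUC is the Mann–Whitney U probability (ties ½), identical to the
trapezoidal area under the empirical curve.  Score polarity is resolved
automatically (patients sit below controls on clustering/strength but above
on local betweenness): when the raw AUC is below 0.5 the scores are negated
and the flip is recorded, so reported AUCs are ≥ 0.5.  The operating
threshold maximizes the Youden index `J = sens + spec − 1`; ties break
toward higher specificity; thresholds are reported in original metric units,
midway between adjacent distinct scores.  A contrast is "acceptable" when
both sensitivity and specificity reach 0.65.

## Synthetic neuropsychological scores

Five battery-like scores (MMSE-, FUCAS-, FRSSD-sleep-, RBMT-, ROCFT-like)
are anchored at published-style group means and receive a component
proportional to the subject's z-scored local betweenness centrality with the
sign pattern reported for such batteries (negative for MMSE/RBMT/ROCFT,
positive for FUCAS and the sleep item), plus Gaussian noise.  The
coefficient `c = sd · r/√(1−r²)` makes the population score–metric
correlation equal the target `r`.  MMSE-like scores are clamped to [0, 30].

## Validation studies and problem sizes

`eegconnectome.experiments` drives three reproducible studies (shared by the
test suite and `scripts/acceptance.py`):

1. **Closed-form recovery** — full-size default cohort (256 channels, 120 s,
   92 subjects, artifacts on).  Windows failing the 100 µV rule are
   rejected; channels flagged bad are excluded from the parietal average
   (they are reconstructions, not observations of the latent model).  The
   pooled per-window parietal |r| is compared per group with the closed form
   at 3 SE across windows.  Note an intrinsic estimator property: on
   500-sample windows of AR(0.95) series, the sample correlation
   underestimates the population value by O(ρ(1−ρ²)/n_eff) ≈ 0.005–0.009
   (n_eff ≈ 26 after autocorrelation inflation, with a further loss from
   within-window demeaning).  With >1100 windows per group the Monte-Carlo
   SE (~0.0014) is smaller than this bias, so the 3 SE criterion fails even
   though the measured means agree with the closed form to ~1%.  A
   companion test shows the deviation collapses when the window length grows
   (500 → 4000 samples), identifying it as finite-window estimator bias
   rather than a pipeline defect.  The unit-level oracle tests therefore
   allow, in addition to 3 SE, an analytic bias bound `2ρ(1−ρ²)/n_eff`.
2. **Coupling-gradient recovery** — 100 end-to-end pipeline runs at the
   default gradient, reduced scale: 57 channels with 6 parietal (preserving
   the study's 27/256 ≈ 10.5% parietal fraction, which controls how strongly
   the parietal signal is diluted at whole-head scope), 30 s/subject, full
   group sizes.  Recorded: the rate at which the cohort-mean local
   clustering recovers the HC > SCD > MCI > AD ordering together with a
   significant local ANOVA, and the rate at which the local-scope HC-vs-rest
   AUC exceeds the global-scope AUC for clustering and strength.
3. **Null calibration** — 200 runs with all couplings equal (α = 1.5 for
   every group), 32 channels / 4 parietal / 20 s: the local ANOVA rejection
   rate at 0.05 must sit within 3 binomial SEs of 0.05.

On the scope contrast (study 2): in this factor model the parietal source
reaches every channel — through parietal/non-parietal pairs and, after
average re-referencing, through the common reference itself — so the
whole-head metrics are nearly affine images of the same underlying windowed
parietal correlation as the local metrics.  Their discrimination AUCs are
therefore close, and the local-beats-global event has only a modest edge
(~0.6 per run) rather than a wide margin.  Real whole-head EEG contains
heterogeneous structure that dilutes a focal effect far more strongly; the
synthetic model is conservative in this respect.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] before taking magnitudes; matrices are
  symmetrized and the diagonal forced to exact zero.
* Constant channels, zero-variance samples and single-class label vectors
  raise labelled errors (`DegenerateVarianceError`, `ConfigError`) rather
  than propagating NaN.  Two constant equal samples give t = 0 by
  convention; a constant metric yields NaN score correlations in the
  pipeline table rather than an abort.
* ANOVA with zero within-group variance and unequal means is an error; with
  equal means it returns F = 0, p = 1.
* Near-zero couplings: |r| of weakly correlated windows is positively biased
  (folded distribution); null tests compare against the folded-normal mean
  `√(2/π)·sd(r)` with the AR-aware null sd, not against zero.
* All randomness descends from a single integer seed; batch seeds are drawn
  through `SeedSequence` and kept below 2^31.

## Known limitations

* The synthetic montage is a Fibonacci-lattice sphere, not digitised sensor
  geometry; interpolation weights are therefore only structurally realistic.
* The generator's homogeneity makes whole-head metrics more informative
  about the parietal effect than they would be on real data (see above).
* Betweenness on correlation networks depends on the weight-to-length map;
  `1/w` is the standard convention adopted here, and no attempt is made to
  match absolute betweenness magnitudes reported elsewhere (the clustering
  inner formula and BC normalization of third-party toolboxes are not fully
  specified in the source literature).
* No spectral/band-limited connectivity, no thresholded or binary graphs, no
  small-world/efficiency measures, no dynamic networks, no EDF export.
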