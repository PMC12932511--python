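# Methods

`eztopo` implements a network-topology analysis for localizing the
epileptogenic zone (EZ) from electrophysiology: multichannel ictal and
interictal epochs are decomposed into seven frequency bands, turned into
binary functional networks by thresholding Pearson correlations, and
characterized node-by-node with four graph metrics.  Nodal metrics feed
a paired EZ-vs-NEZ statistical comparison, an EZ/NEZ sub-network density
analysis, and a patient-grouped machine-learning validation.  Scalp EEG
additionally passes through an electrical source imaging (ESI) stage so
that network nodes are cortical parcels rather than sensors.  A
synthetic cohort generator provides ground-truth-labeled inputs for
every stage.

## Signal conditioning

Epochs (default 10 s; 500 Hz scalp, 2,000 Hz SEEG) are band-pass
filtered 0.5–300 Hz with a 4th-order Butterworth filter and notch
filtered at 50 Hz and all harmonics below Nyquist (2 Hz stop bands).
All filters run forward–backward (`sosfiltfilt`), i.e. zero-phase with
an effective magnitude order of 8.  Zero-phase filtering is a deliberate
choice: a causal filter's group delay is frequency-dependent and would
systematically bias the zero-lag Pearson correlations computed next.
The seven analysis bands are full (0.5 Hz–upper edge), delta (0.5–4),
theta (4–8), alpha (8–13), beta (13–30), gamma (30–80) and HF
(> 80 Hz).  Band edges are capped at 0.45 × sampling rate, which puts
the HF and full-band upper edge at 225 Hz for 500 Hz scalp data and
300 Hz for SEEG.  Artifact rejection (ICA, visual bad-channel marking)
is out of scope — it is clinician- and toolbox-dependent and the
synthetic data are artifact-free; `eztopo.io.read_edf` is the hook where
cleaned real data enter.

## Source imaging (scalp path)

Scalp potentials follow the linear forward model `phi = K J + c 1`,
with `K` the lead field of a concentric-shell spherical conductor
(default three shells at relative radii 0.87/0.92/1.0 and conductivities
1/0.0125/1 — brain, skull, scalp).  The analytic model replaces a
boundary-element head model on purpose: it is dependency-free,
configurable, and preserves the structure of the inverse problem, at the
cost of anatomical realism (a limitation shared by any template-based
forward model).  Per Legendre degree the radial profile is obtained by
solving the interface conditions (continuity of potential and radial
current; zero current through the scalp) as a small linear system, so
the solver handles any number of shells; the series is truncated at 120
terms, ample for sources up to 0.85 of the brain radius.  The
implementation is validated against an independently coded
homogeneous-sphere closed-form solution and the free-medium dipole
formula.  Electrodes are the 16-channel clinical 10–20 montage at
idealized unit-sphere positions.

The inverse estimate minimizes `||phi − K J − c 1||² + alpha ||J||²`
jointly over `J` and the reference constant `c`; with the
average-reference projector `H` this gives
`J_hat = K^T (K K^T + alpha H)^+ H phi`.  sLORETA standardizes each
source's 3-vector by the corresponding 3×3 diagonal block of
`K^T (K K^T + alpha H)^+ K`.  This estimator has exactly zero
localization error for noiseless single dipoles at any `alpha >= 0` (a
Cauchy–Schwarz property of the resolution matrix), which the tests
exercise over random dipoles.  `alpha` defaults to
`1e-6 × mean(diag(K K^T))` — small enough to be numerically inert in
the noiseless checks, nonzero to keep the pseudoinverse stable;
anything in a wide range behaves identically for the analyses here.
Region time series are means of source magnitudes (square root of
standardized power) over the members of a generic k-means parcellation
(default 148 regions, standing in for an anatomical atlas of 74 regions
per hemisphere); magnitude averaging avoids the sign-flip ambiguity of
averaging raw dipole components across orientations.

## Networks and nodal metrics

Edges are zero-lag Pearson correlations per band.  Binary undirected
networks keep an edge where `|r| >= T` with `T = 0.7` (ties included);
a sensitivity sweep over {0.6, 0.7, 0.8} is built in.  The absolute
value is used because strong anticorrelations are genuine couplings; a
`signed` option restricts edges to `r >= T`.  Zero-variance channels
become isolated nodes rather than errors so node indexing keeps matching
clinical labels.

Per node, four metrics: degree, clustering coefficient
`2 e_i / (k_i (k_i − 1))`, local efficiency (mean inverse shortest-path
distance within the neighbor-induced subgraph), and betweenness
centrality (Brandes-style, unnormalized raw pair counts — only
within-sample EZ/NEZ contrasts are used, so normalization would cancel;
a `normalized` flag is available).  Disconnected pairs contribute zero
to efficiency and betweenness.  Metrics are always computed on the whole
network first and split by EZ/NEZ labels afterwards, so a node's value
never depends on its label.  7 bands × 4 metrics give the 28-column
nodal feature table.  The EZ/NEZ bipartition is additionally summarized
by internal densities `D_EZ`, `D_NEZ` (edges over `C(n,2)` within each
block) and the interaction density `D_EZ-NEZ` (edges over
`n_EZ × n_NEZ`); blocks with fewer than two nodes report an undefined
(NaN) density rather than zero.

## Statistics

Per sample (patient × state), nodal values are aggregated by the mean
over EZ nodes and over NEZ nodes (median available); the aggregate pair
enters a two-sided Wilcoxon signed-rank test.  Zero differences are
dropped (Wilcoxon's convention; Pratt handling was considered and not
needed).  For up to 25 informative pairs the null is enumerated exactly
by convolving the ±rank distribution (mid-ranks doubled to integers), so
tied magnitudes are handled exactly; above 25 the normal approximation
with continuity correction is used.  Families of tests are corrected
with Benjamini–Hochberg: the 28 band × metric tests of one
modality/state table form one family, and the 21 band × density
state-comparison tests another.  Undefined tests are flagged and
excluded from the family rather than imputed.

## Classification protocol

The node-level table is balanced 1:1 by seeded undersampling of the
majority class, allocated proportionally to each patient's share
(largest remainder), which preserves the group structure.  Five models
are supported (RBF SVM, random forest, gradient boosting, k-NN,
logistic regression).  Evaluation is a nested, patient-grouped
protocol: outer Group 5-fold by patient identifier; within each outer
training split an inner grouped 3-fold grid search selects
hyperparameters by AUC (SVM C ∈ {0.1, 1, 10}; RF 50/100/200 trees ×
depth None/10/20; k-NN k ∈ {3…11}; GBM 50/100/200 × learning rate
{0.05, 0.1} and LR C ∈ {0.1, 1, 10} — the last two grids are this
package's defaults, as only examples are standard for them).  Scaling —
plain Z or `log(1+x)` followed by Z — lives inside the pipeline so its
statistics come only from training folds; tree ensembles train on the
raw feature space.  `log1p` rather than `log` because degree and
betweenness are exactly zero on isolated nodes.  Metrics (AUC,
accuracy, sensitivity, specificity, precision, F1) are computed on the
pooled out-of-fold scores by default (per-fold averaging by flag); SVM
scores are the sigmoid-squashed decision function so the 0.5 threshold
coincides with the margin.  Significance uses label permutation across
the whole table (not within patient) with
`p = (1 + #{null >= observed}) / (1 + n_perm)`.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis
assumes, not waveform morphology (no spikes, HFOs or neural-mass
dynamics).

**SEEG.** Per band, two unit-variance band-limited latent sources exist:
one shared by NEZ contacts, one by EZ contacts.  A channel is
`g h_i (c_own S_own + c_cross S_other)` plus band-limited private noise
(sd 0.4).  `g` is a per-patient log-normal gain (mean 1, CV 0.4 for
SEEG, 0.16 for scalp) on all couplings — the inter-patient
heterogeneity that motivates log+Z preprocessing — and `h_i` a
per-channel log-normal jitter (CV 0.2) that keeps pairwise correlations
graded around the 0.7 threshold instead of collapsing into complete or
empty blocks.  The interictal defaults `c_intra_nez = 0.8`,
`c_intra_ez = 0.55`, `c_cross = 0.15` were chosen once from the closed
form `r = c_own² g² h² / (c_own² g² h² + c_cross² g² h² + sd²)`: they
put the expected NEZ–NEZ correlation (~0.78) above threshold, the
EZ–EZ correlation (~0.62) below it, and the cross correlation (~0.32)
far below — yielding the isolated-EZ phenotype (lower degree,
clustering, local efficiency) and the density ordering
`D_cross < D_EZ < D_NEZ`.  Channel counts are drawn at 113 ± 20 per
patient; EZ contacts uniform 8–30 (an assumption — clinical reports
give EZ extents in source space, not contact counts).

**Ictal state.** Beta/gamma/HF intra-couplings are multiplied by a
surge factor (default 2.0) and the cross coupling by a larger factor
(default 5.0); the EZ-internal delta coupling is boosted by 1.8.  The
separate cross factor is forced by the algebra: as couplings grow, the
cross-block correlation saturates at
`c_x (c_n + c_e) / sqrt((c_n² + c_x²)(c_e² + c_x²))` — about 0.40 under
a uniform surge — so no uniform multiplicative surge can push
interaction density over the threshold, and the between-module density
increase seen during seizures would be unreproducible.  With the
default factors the unit-gain cross correlation reaches ≈ 0.80, so all
three densities rise ictally in beta/gamma/HF while low-gain patients
tie; the delta boost selectively raises `D_EZ` (the pathological
slow-wave resonance pattern).  The patient structure stream (channel
count, EZ mask, gains) is seeded independently of the state stream, so
ictal/interictal cohorts from the same seed are matched
patient-for-patient — the paired design.

**Scalp.** A spatially clustered set of EZ parcels (5–31 regions)
hosts a coherent delta/theta driver at 5× the background amplitude;
NEZ sources carry independent broadband background.  All dipoles are
radially oriented (cortical generators are approximately
surface-normal, which in a spherical geometry means radial).  Sensor
data are the forward projection plus sensor noise; ground truth lives
at the region level.  After ESI, leakage of the dominant driver makes
the EZ appear as a high-degree hub — the opposite phenotype to SEEG,
as expected from source-space smearing of a strong coherent generator.

**Null generator.** For type-I calibration all three couplings are set
equal (0.45 with noise sd 0.4), which makes EZ and NEZ exchangeable
*and* puts the common correlation ≈ 0.72, near the threshold, so edges
remain stochastic; with couplings far from the threshold every network
is deterministically complete or empty, all paired differences are
zero, and the test is undefined rather than calibrated.

**What passing tests do and do not show.** The generator shares the
analysis' statistical skeleton (band-limited community coupling,
multiplicative heterogeneity), so green direction-recovery tests show
the pipeline detects the structure it is designed for — not that real
SEEG satisfies that structure.  Real recordings add artifacts,
nonstationarity, volume conduction within SEEG, and label noise that
the generator does not emulate.

## Problem sizes and numerical choices

Statistical and density acceptance checks run on the default
20-patient, both-state SEEG cohort.  Type-I calibration uses 200
reduced cohorts (10 patients, 20 contacts, 250 Hz, 4 s) — under the
null the p-value distribution does not depend on scale; the exact test
is conservative at this n because of its discreteness.  The permutation
check uses 200 permutations (the protocol's 1,000 scaled down; the
floor 1/(n+1) behaves identically).  The preprocessing comparison runs
ten 10-patient cohorts at the default channel scale.  The spherical
model uses 200–600 sources; sLORETA localization checks 50 random
dipoles.  Correlations are clipped to [−1, 1]; singular 3×3 sLORETA
blocks fall back to a pseudoinverse with a logged warning.

## Known limitations

* The log+Z-versus-raw SVM comparison is the one qualitative pattern
  the synthetic conditions do not reproduce: with this generator the
  raw-feature SVM is already strong (pooled AUC ≈ 0.86 across ten
  default cohorts vs ≈ 0.85 after log+Z), because an RBF kernel with
  variance-adaptive bandwidth is not crippled by unscaled features even
  at cross-patient metric CVs of 0.7–0.9, and because exactly-isolated
  EZ nodes give the raw space a strong zero signature.  The large
  raw-SEEG deficit reported on clinical data plausibly reflects
  heavier-tailed amplitude/implantation heterogeneity and different
  feature geometry than coupling-gain heterogeneity induces.  The
  directional test is kept at the stated conditions and currently
  fails; interpret it as a property of the generator, not of the
  pipeline.
* Spherical head model and generic parcellation; no individual anatomy.
* One epoch per patient and state; no dynamic (time-resolved) networks.
* A current dipole at the centre of a spherical conductor is *not*
  electrically silent (that property belongs to magnetic recordings);
  the forward-model tests therefore check the centre dipole's cosine
  surface pattern instead.
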