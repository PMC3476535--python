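# Methods

`erdica` reimplements a complete EEG analysis chain for discrete lower-limb
muscle contractions — channel quality control, adaptive mixture ICA,
equivalent-dipole source modelling and clustering, time-warped
significance-masked spectrograms with event-related desynchronization (ERD)
statistics, and 4-way single-trial decoding — and pairs it with a synthetic
EEG generator that emulates the study design the chain targets: 8 subjects
performing isometric and isotonic knee and ankle exercises at two effort
levels, two sets of 20 repetitions per exercise, ~3 s trials separated by
5 s pauses, with no isotonic knee flexion (the apparatus cannot produce it).
The real experiment's recordings are not publicly deposited, so every
quantitative claim here is a property of the chain demonstrated on
synthetic data with known ground truth, plus analytic calibrations.

## Head model

A single homogeneous conducting sphere (radius 85 mm, conductivity
0.33 S/m) provides both the simulator's forward projections and the inverse
dipole fits. The scalp potential of a current dipole is the classical
Legendre series for a dipole in a conducting sphere, evaluated with stable
recurrences, truncated when terms fall below 1e-10 of the accumulated
potential (cap 200 terms), and average-referenced. We chose a single
homogeneous sphere rather than a three-shell or boundary-element model
deliberately: the package needs exact internal consistency between
generator and inverse fit, not anatomical accuracy, and this choice is the
accuracy ceiling for any coordinate statement the pipeline makes.
Anatomical (MNI/Talairach) coordinates are out of scope.

Inverse fits scan a deterministic 5 mm grid over the brain volume (moment
solved linearly at each node, so a node costs one 3-column least squares),
then refine the best `n_restarts = 5` nodes with Nelder-Mead; ties break on
lowest residual variance (RV), then lexicographic location. Grid gain
matrices are cached per montage. Fits may place dipoles up to 0.99 R —
slightly outside the nominal brain sphere (0.95 R) — because the muscular
artifact rule classifies components by dipoles *beyond* the brain radius;
constraining fits to the brain sphere would make that rule unsatisfiable.

## Synthetic data generator

The generator aims to reproduce the statistical structure the analysis
assumes, not biophysics. Per subject:

* **Cortical sources** (medial premotor/SMA, left and right dorsal
  premotor, posterior parietal, visual) are band-limited Gaussian noise in
  the alpha (8–12 Hz) and beta (12–30 Hz) bands, amplitude-modulated by the
  task, over a pink background 10 dB below the alpha amplitude. Amplitudes
  are expressed in microvolts at the strongest electrode (each forward
  column is normalized to unit peak). Defaults are 3–7 uV per band — chosen
  (with the 3 uV diffuse background and 1 uV sensor noise below) so that
  the pipeline's recovery properties hold at realistic-looking SNR; the
  real study reports no amplitude or SNR figures, so these are generator
  conventions, exposed in the configuration.
* **ERD**: source amplitude is multiplied by `1 - d * m(t)`. For isometric
  trials `m(t)` is a pair of 600 ms raised-cosine bumps at trial onset and
  offset (transient profile); for isotonic trials a plateau across the
  trial with 300 ms cosine ramps (sustained). Because *amplitude* is
  modulated, the steady-state power ERD in dB is exactly `20 log10(1 - d)`,
  which the tests exploit (d = 0.5 gives -6.02 dB). Depths default to
  0.27–0.5 with high effort always at least as deep as low effort; each
  trial and source draws an independent 15% log-normal depth jitter
  (physiological variability; independence across sources is what makes
  combining clusters informative), and each subject a 10% log-normal
  depth factor plus 3 mm location jitter.
* **Two spatial regimes**: knee-trial samples mix through one matrix,
  ankle trials through another differing only in the medial premotor
  source, displaced 15 mm posteriorly (-Y) — the somatotopic-shift
  hypothesis the mixture ICA is meant to detect. Gaps between trials take
  the upcoming trial's regime.
* **Artifacts and sensors**: Poisson blinks (0.2/s, 300 ms biphasic,
  ~80 uV) from an anterior-inferior source; broadband 20–150 Hz bursts
  during trials from an extra-cranial source; 24 random deep dipoles with
  pink-noise time courses (3 uV) providing the spatially smooth ongoing
  background that makes neighbouring channels correlated; 1 uV white
  sensor noise; 60 Hz line noise (0.5 uV, per-channel amplitude jitter);
  per-channel random-walk drift. The default montage is a deterministic
  64-electrode Fibonacci layout on the upper sphere — desk-scale rather
  than the 264 channels of the original apparatus; the channel count is a
  configuration parameter.
* **Auxiliary channels** at 1000 Hz: a trapezoidal load-cell force per
  isometric trial (300 ms linear ramps; 400 N high effort, 100 N low,
  mirroring the "about 25%" low-effort instruction) and a triangular
  goniometer excursion per isotonic trial (50 deg knee, 25 deg ankle,
  signed by direction).

What the generator does **not** emulate: 1/f spectral detail of real EEG
beyond a single pink term, non-stationary artifact topographies, EMG
volume-conduction spectra, electrode impedance drift, or inter-subject
anatomical variability beyond location jitter. Passing tests therefore
demonstrate internal consistency and statistical correctness of the chain,
not performance on real recordings.

## Preprocessing

Zero-phase 4th-order Butterworth high-pass at 1 Hz (forward–backward, so
8th-order roll-off). Channel rejection applies three rules in the order
listed, each computed once on the survivors of the previous rule:
standard deviation >= 1000 uV; kurtosis more than 3 SD above the
across-channel mean kurtosis; and "uncorrelated with nearby channels too
often" — implemented as 1 s windows, a channel counting as uncorrelated in
a window when its maximum absolute Pearson correlation against its 4
nearest neighbours (3-D electrode distance) is <= 0.4, with rejection when
that happens in more than 0.1% of windows. Per-sample correlation is not
well defined, so the windowed reading is a design decision (window length
configurable); the neighbour count is likewise our choice. Survivors are
re-referenced to the common average.

Trial bounds are refined from the mechanical channels (force for
isometric, absolute angular deviation for isotonic): baseline is the
median of the second before the nominal onset, the threshold sits at
baseline + 10% of the peak-to-baseline range with 2% hysteresis, and the
first/last crossings (converted to EEG samples) replace the nominal
bounds; trials without a crossing keep nominal bounds with a logged
warning. The 10% threshold is our choice; the original work does not state
one.

## Mixture ICA

`MixtureICA` fits M complete ICA models by maximum likelihood. Model h has
unmixing matrix W_h, bias c_h, and one generalized-Gaussian density per
source, `log q(s) = log(rho/(2 beta Gamma(1/rho))) - |s/beta|^rho` with
shape rho in [0.5, 4] and scale beta. Per-sample responsibilities are the
softmax over models of `log pi_h + L_h(x_t)` with
`L_h = log|det W_h| + sum_i log q_i(s_i)`. Updates per iteration:
responsibility-weighted natural gradient `dW = (I - E[phi(s) s^T]) W` with
the generalized-Gaussian score; bias as the responsibility-weighted mean;
shape by a 14-step golden-section search of the per-source profile
likelihood (the optimal scale is closed-form for fixed shape, and the
search runs on a <= 20k-sample stride subsample — the shape needs far fewer
samples than the unmixing matrix); scale in closed form
(`beta^rho = rho E[|s|^rho]`, after any shape update); priors as mean
responsibilities. The learning rate starts at 0.2, grows 5% per accepted
step (cap 0.5) and halves whenever total log-likelihood decreases, with
the step reverted; ten consecutive rejected steps abort with diagnostics.
The accepted-step likelihood trace is non-decreasing to 1e-8 per sample.
Shape bounds [0.5, 4] keep the score integrable and cover Laplacian
through sub-Gaussian sources. One generalized Gaussian per source (not a
per-source mixture) is the default — sufficient for the synthetic sources
and far cheaper.

After the annealed soft phase, a classification-EM refinement runs by
default (`refine_iter`): samples are hard-assigned to their
argmax-responsibility model once, and each model is polished on its own
samples by the same single-model annealed loop. Once the mixture has
specialised, the hard partition is essentially pure, and the refinement
removes the residual cross-regime leakage that fractional
responsibilities leave in the unmixing matrices — on two-regime fixtures
this is the difference between per-model Amari indices of ~0.2 and ~0.01.

Data are PCA-whitened and reduced to `n_components` (default 16 on the
64-channel synthetic montage) before fitting; the paper-scale channel
counts make some reduction unavoidable and the original work does not
state one. Scalp maps are mixing columns mapped back through the PCA.
Long recordings are fitted on a stride subsample (default cap 100k
samples); inference (responsibilities, model probabilities) always runs on
the full data. In the pipeline the mixture is fitted on concatenated
*trial* samples rather than the full continuous record: with a single
generalized Gaussian per source, the muscular artifact's on/off
bimodality would otherwise reward a trial-versus-pause split of the data
as much as the spatial-regime split the analysis is after (the
full-AMICA remedy, a mixture of Gaussians per source density, is exactly
what makes continuous-data fitting safe there). Inference and trial
classification still use the whole recording.

A whole segment's model probability is
`softmax_h(log pi_h + sum_t L_h(x_t))` computed with max subtraction.
Trial classification assigns each trial its argmax model and chooses the
model-to-joint mapping (among the M! permutations) that maximises
agreement with the joint factor; overall, isometric-only and
isotonic-only accuracies are reported. A one-way fixed-effects ANOVA
compares per-subject model probabilities between the knee-trial and
ankle-trial data subsets.

## Source space

Components with dipole RV > 0.15 are rejected (the dipole explains less
than 85% of scalp-map variance). Ocular components have anterior-inferior
dipoles (y > 0.8 R, z < 0) and a (1–4 Hz)/(4–40 Hz) power ratio above 2;
muscular components have dipoles outside the brain sphere and rising
log-power over 40–100 Hz. Everything else is cortical.

Cortical components from all subjects are clustered with k-means (k
configurable, default 10; 20 seeded restarts, best inertia) on the
concatenation of z-scored dipole coordinates weighted 3 and z-scored
10-dimensional PCA scores of the scalp maps weighted 1. Because subjects
retain different channel subsets, maps are first interpolated
(thin-plate-spline RBF) onto a shared 64-point spherical grid — a
necessity the source description leaves open. Records are canonically
sorted before clustering so the partition is invariant to input order.
Clusters with components from at least 75% of subjects (6 of 8 at the
reference study size) are retained; subject count uses distinct subjects,
and several components of one subject may share a cluster.

## Spectrograms and ERD statistics

Morlet spectrograms use a fixed-duration Gaussian envelope: full width
(+-3 sigma) equal to the 500 ms analysis window at every frequency, so
cycles grow proportionally to frequency. This matches a fixed "500 ms
sliding window" description; the alternative (EEGLAB-style expanding
cycles) is not implemented. The 25 ms figure is read as the slide between
windows — a 475 ms slide would give ~6 columns per 3 s trial, too coarse
for the smooth maps the method produces. Wavelets are L2-normalized
(white noise is flat across bins in expectation) and power is in dB.
The frequency grid is 220 log-spaced bins from 3 to 150 Hz.

Single-trial maps are normalized by subtracting the mean baseline log
spectrum (-1000 to -500 ms before onset), linearly time-warped so the
trial spans the dataset-median duration (pre-onset and post-offset columns
pass through unstretched), and regridded onto a canonical latency axis so
all trials share a shape. Significance versus baseline uses a surrogate
bootstrap: per frequency, the null of the trial-mean dB is built by
drawing one random null column per trial (single columns, not blocks) and
averaging, n_boot = 200 times; values outside the two-tailed empirical
alpha = 0.05 band are significant and the rest are displayed as 0 dB.

The null column pool deserves care. Drawing from the normalization
baseline itself is anti-conservative at this geometry: with a 500 ms
analysis window the -1000..-500 ms baseline holds only ~2 independent
spectral estimates, mutually correlated and anti-correlated with the
subtracted baseline mean, so the surrogate under-estimates the null
spread (measured pointwise type-I error ~0.15 at alpha = 0.05 on
stationary nulls). The pool therefore consists of pre-trial *pause*
columns whose windows are disjoint from the baseline and spaced by half
a window (near-independent estimates); drawn deviations from the pool
mean are scaled by sqrt(m/(m-1)) to undo the finite-pool variance
deficit, and the acceptance band uses outward-rounded order statistics.
Trial spectrograms carry a 3.5 s pre-onset span so the pool exists — the
protocol's 5 s inter-trial pauses accommodate it. This calibration
(measured type-I ~0.06) is a package design choice; no
multiple-comparison correction is applied beyond it — the masks are
pointwise by design, and the type-I calibration of the mask is itself a
tested property. Band ERD statistics are means of the significant
alpha/beta points inside the (warped) trial interval; effort levels are
compared with a paired two-sided t-test across subjects (a zero-variance
difference is handled as its analytic limit), and condition pairs with a
pointwise label-permutation test that switches to exact enumeration when
feasible.

## Decoding

Normalized trial spectrograms are reduced by non-overlapping 10 x 10
block means (trailing partial blocks average the available cells).
Per condition, bootstrap-significant points on the *reduced* grid are
selected, and the union over the four conditions across the included
component clusters forms the feature set; features are the dB values at
those points. The classifier is Gaussian naive Bayes with per-feature
variance pooled across classes — the construction that is simultaneously
naive-Bayes and linear (quadratic terms cancel in the log-odds);
per-class variances are available behind a flag. Ten-fold stratified
cross-validation (seeded) is used; by default the feature mask is
recomputed within each training fold so the test fold never informs
selection, while `paper_mode=True` reproduces the simpler
select-once-per-subject protocol for comparison. Per-fold confusion
counts are summed and then normalized so all 16 cells total 100%
(counts-then-normalize; the alternative order is a one-line change).
Row sums reflect class prevalence — the protocol has a 4:3
isometric:isotonic trial ratio. The visual-cortex cluster is excluded
from the all-clusters decoder as a gaze-confound control, mirroring the
original design.

## Numerical and testing choices

* Sample indices are 0-based, intervals half-open `[onset, offset)`.
* EDF files are written by the package's own 16-bit writer (1 s records,
  last record padded, exact sample counts in a JSON sidecar) and read back
  through MNE's EDF reader, which doubles as an independent check of the
  writer. EEG and the 1000 Hz auxiliary channels live in separate EDF
  files so each rate group round-trips exactly (mixed-rate EDFs are
  resampled by the available reader).
* The pipeline is a pure function of (config, seed): every stochastic
  step derives its seed from the master seed and a stage tag.
* Test problem sizes: the two-regime ICA check uses 16 dimensions, 8
  regime-specific columns, 100k samples and 10 draws; trial
  classification uses one full default subject; ERD and decoding checks
  run the 8-subject study at source level (the generator's ground-truth
  activations stand in for recovered components there — mixture ICA
  recovery is validated separately, and chaining both would only blur
  attribution of a failure). The acceptance script reruns the same
  analyses at reduced counts (3 ICA draws, 20 dipoles, 4 subjects).
* Known limitations: the spherical head model's coordinates are
  self-consistent but not anatomical; near-surface sources (beyond
  ~0.95 R) lose forward-model accuracy at the 200-term series cap; the
  generator's sources are Gaussian-within-band (identifiable by the
  mixture only through amplitude modulation and band structure), which is
  kinder than real EEG in some respects (stationary mixing within regime)
  and harsher in others (weak non-Gaussianity).
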