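# Methods

This note documents the models and numerical choices behind `cordmap`,
in the order the pipeline runs them, together with what the synthetic
phantom does and does not emulate.

## The synthetic phantom

`synth.generate_phantom` builds one subject of paired brain/cord 4D
data on the acquisition geometry of a simultaneous cerebro-spinal
protocol: TR = 1.55 s, 230 volumes. The cord grid is 6 × 6 × 42 voxels
(1 × 1 × 3 mm): a 4 × 4 gray-matter core ringed by CSF, with seven
equal-thickness segments (C1–C7) stacked rostro-caudally. The cortex
grid is 42 × 14 × 3 (2 mm): a sensorimotor strip of 10 rows flanked by
CSF, tiled into seven patches along its long axis.

Each segment *s* carries a latent spike train — Bernoulli events at
`event_rate = 0.05` per volume per segment, unit amplitude — convolved
with the canonical double-gamma HRF into a "neural" signal
*n<sub>s</sub>(t)*. Cord voxels of segment *s* receive *n<sub>s</sub>*;
cortical voxels of patch *p* receive Σ<sub>s</sub> 0.3^|p−s| ·
*n<sub>s</sub>*, a geometric falloff that creates the graded
"preferential" connectivity a winner-take-all analysis must resolve.
White voxel noise is scaled so that std(shared)/std(noise) =
`coupling_snr` (default 0.8 — moderate per-voxel SNR of the kind left
after denoising resting-state data; the default keeps single-voxel
correlations well below 1 while seed means are nearly clean).

Structured noise: cardiac (1.0 Hz) and respiratory (0.3 Hz) cosines
generated at 100 Hz (so phase estimation sees realistic high-rate
traces) and sampled at volume times — at this TR they alias to
≈ 0.29 Hz and 0.30 Hz; a slow cosine drift; bounded-random-walk motion
traces (6 brain, 2 cord parameters); and a motion intensity artifact
added as a modulation proportional to the framewise-displacement trace,
common to all voxels of an organ. CSF compartments carry only
physiological signal (with per-voxel gain jitter, so CompCor sees a
low-rank field), drift, and small measurement noise — no neural signal.

What the phantom does **not** emulate: MR physics (k-space, distortion,
slice timing), spatial autocorrelation of the noise, true subject
motion (no resampling — the intensity modulation keeps the phantom
analytic), hemodynamic variability across voxels, and non-Poisson
spontaneous-event statistics. Passing recovery tests therefore
demonstrates the *analysis chain* is correct and well-conditioned, not
that real cerebro-spinal data will yield these effect sizes.

## QC

Framewise displacement for the brain follows Power's convention:
FD<sub>t</sub> = Σ|Δtranslation| + r·Σ|Δrotation| with r = 50 mm.
For the cord, realignment provides two in-plane translations and
FD<sub>t</sub> = mean(|Δx|, |Δy|). The first volume's FD is 0, and mean
FD > 0.3 mm raises the excess-motion flag. tSNR is mean/std over time
(population std); constant voxels are reported as 0 with a count.

## Nuisance model and denoising

* **RETROICOR** — cardiac phase is linear in time between pulse peaks
  (detected with a 0.25 s refractory period, or supplied); respiratory
  phase is Glover's histogram-equalized amplitude transfer signed by
  the belt derivative, in (−π, π]. The design holds sin/cos of 3
  cardiac and 4 respiratory harmonics plus sin/cos of (φ<sub>c</sub> ±
  φ<sub>r</sub>) for one interaction order — 18 columns. Degenerate
  (constant) columns are kept but flagged; the projection step drops
  them.
* **CompCor** — CSF voxel series are demeaned and variance-normalized
  (tCompCor-style) before a temporal PCA; components are unit-norm,
  ordered by explained variance (eigenvalues of the normalized voxel
  covariance), with a deterministic sign (largest-magnitude loading
  positive). Defaults: 12 components for the brain, 5 for the cord.
* **DCT** — the 5 lowest-frequency non-constant DCT-II vectors,
  orthonormal.
* **Projection with band-pass** — the voxel series and the (demeaned)
  regressors are filtered with the same zero-phase frequency mask
  (passband 0.01–0.17 Hz inclusive, realized as an FFT mask) and the
  data are then projected onto the orthogonal complement of the
  filtered regressor span. Filtering and regression commute by
  construction, so neither step can reintroduce what the other removed;
  residual correlation with every regressor is zero to numerical
  precision. Rank-deficient designs proceed with a warning (least
  squares ignores dependent directions). Order of operations: demean,
  filter, project, demean, then standardize to unit variance. The
  unfiltered variant (projection only) feeds the deconvolution, which
  needs the full spectrum.
* **Smoothing** — separable Gaussian per volume, FWHM in mm converted
  through the affine (defaults 3 × 3 × 6 mm cord, 6 × 6 × 6 mm brain),
  zero-padded boundaries; FWHM 0 is an exact identity.

## iCAPs

**Deconvolution.** Per voxel we solve min<sub>a</sub> ½‖y − Ha‖² +
λ·TV(a), H being causal convolution with the double-gamma HRF (peak
parameter 6, undershoot 16, ratio 1:6; unit scale puts the mode at 5 s;
kernel sampled at the TR over 32 s, max-normalized). H uses a
steady-state left boundary — activity before the first sample is taken
equal to the first sample — so constant activity maps to a constant
signal and a flat series deconvolves to a flat activity with exactly
zero innovations. The solver is monotone FISTA: an accelerated proximal
gradient whose candidate is accepted only if the objective does not
increase, with per-voxel momentum restart on rejection; the TV prox is
computed exactly by Condat's taut-string algorithm (numba-compiled,
with a pure-Python fallback). The objective is therefore non-increasing
by construction, which the tests assert. Convergence: relative
objective change < 1e−6 (sticky per voxel) or 500 iterations, with
per-voxel convergence flags returned.

λ defaults to a per-voxel robust noise estimate — MAD of the first
difference, scaled to σ — times `lambda_scale · √(2 log T)`. The
default `lambda_scale = 0.25` (a quarter of the universal threshold) is
deliberately mild: full universal-threshold shrinkage merges closely
spaced transients and suppresses weak events, while the surrogate test
downstream absorbs the extra false innovations this leniency admits.

**Frame selection.** Innovations are Δa. Per voxel, a two-sided
threshold at the α/2 and 1 − α/2 quantiles (α = 0.05) of innovation
amplitudes from 100 phase-randomized surrogates of that voxel's
innovation series; a frame is kept when ≥ 5% of voxels are
suprathreshold. Events at the very end of a run (inside the HRF rise
time of the last volume) are physically unrecoverable — the phantom
recovery tests reflect that as the few percent of misses.

**Clustering.** Polarity-folded cosine K-means: a frame and its
negation are the same transition, so assignment maximizes |cos| to the
centroid and each member contributes with its matching sign. Best of 20
restarts by within-cluster dispersion Σ(1 − |cos|); empty clusters are
re-seeded from the worst-fit frame (at most 10 repairs). Each map is
the z-scored mean of sign-aligned member frames, with canonical
polarity (largest-|z| voxel positive) so the maps are invariant to
wholesale negation of the input. Plain Euclidean K-means is available
behind `metric="euclidean"`.

**Consensus.** Monti-style: 50 subsamples of 80% of frames are
reclustered; consensus(i, j) is the co-assignment frequency among
subsamples containing both; the per-cluster score is the mean pairwise
consensus within each final cluster (singletons score 1; a single
subsample is flagged uninformative).

## Seed FC and winner-take-all

Seed series are unweighted means over segment gray matter on
*unsmoothed* denoised, band-passed data. FC is Pearson r per target
voxel (constant voxels → r = 0, flagged), Fisher z = atanh(r) with the
clamp |r| ≤ 1 − 1e−7, averaged voxelwise across subjects. The
winner-take-all label is the argmax over seeds of signed z — negative
maxima are assigned by default, with a `positive_only` option that
leaves them unlabelled — ties going to the lowest seed index with a
count (ties have measure zero on real data; the rule makes synthetic
integer inputs deterministic). The reproducibility table counts, inside
each group-level winner mask, the voxels each subject assigns to every
level; it is exported as TSV for external mixed-model analysis, which
is out of scope here.

## Parcellation

Z[i, j] = atanh(r) between cord voxel i and cortical voxel j.
"Similarity as the cross-correlation of Z" is implemented as row-wise
Pearson correlation (each cortical profile centered and scaled), which
makes it invariant to common affine rescalings of the profiles; a raw
inner-product variant exists behind `method="inner"`. Per-subject
matrices are averaged elementwise; the group matrix is clustered by
average linkage on D = 1 − S̄ (scipy's implementation, validated
merge-for-merge against an O(n³) agglomeration oracle in the tests),
and the dendrogram is cut at K = 5…9. Cluster-to-atlas matching is a
maximum-weight bipartite assignment (Hungarian algorithm, validated
against exhaustive 7! search) with Dice weights by default (voxel
overlap optional); Dice of two empty masks is defined as 0.

Stability has two views: (i) for every voxel, the mean over subject
pairs of the correlation between their similarity-matrix rows (diagonal
excluded); (ii) per-subject clusterings aligned to the group solution
through a contingency matrix normalized by group-cluster size (so small
clusters are not swamped) and a maximum-weight injective assignment,
then summed into per-label heatmaps. Cluster fingerprints are the mean
of member-voxel FC profiles — the mean of maps, not the FC of the mean
series; the two differ after Fisher z and the former is the definition
used throughout — averaged across subjects and resolved by
winner-take-all into a brain map per cluster.

## Pipeline, determinism, and problem sizes

`pipeline.run_pipeline` wires the stages with the correct data
variants: the deconvolution consumes smoothed, *unfiltered* denoised
data; seed extraction and the feature matrix consume unsmoothed,
filtered data. Every random operation receives a seed derived from the
run config; reruns with identical config produce identical hashes,
which the manifest records along with per-stage wall-clock and summary
quantities. Unknown config keys are rejected.

Default validation sizes — 8 subjects, 230 volumes, 672 cord GM voxels,
1260 strip voxels — were chosen so the complete suite and the
acceptance script each run in about a minute on one CPU while keeping
every statistical check comfortably powered; the SNR-degradation grid
(0.8, 0.1, 0.03, 0.01) spans the default condition down to near-chance
labelling.

## Known limitations

* The deconvolution is per-voxel 1-D: no spatial regularization across
  voxels, unlike full structured total-activation variants; it sits
  behind the `ActivitySignals` contract so a richer solver can be
  swapped in.
* The frame-selection criterion (surrogate quantiles + active-voxel
  fraction) is one reasonable formalization of "significant
  transitioning activity"; all three knobs are exposed.
* The phantom's motion artifact is an intensity modulation, not a
  resampling, so motion correction itself cannot be exercised.
* Group iCAPs pool frames across subjects before clustering
  (config-switchable); per-subject back-projection of iCAP time courses
  is not implemented.
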