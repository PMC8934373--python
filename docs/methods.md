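# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `chromarch`. The package quantifies chromatin architecture and
dynamics at four scales — Hi-C contact structure, lamina association, single
locus motion, and nuclear geometry — and ships synthetic-data generators with
planted ground truth so every stage can be validated end to end.

## Hi-C metrics

**Matrix model.** Contact matrices are symmetric, non-negative, genome-wide,
binned at a fixed resolution with per-chromosome concatenated bin indexing.
Coordinates are 0-based half-open everywhere. Bins whose raw coverage falls
below the 2nd percentile of nonzero coverages (configurable) are masked: the
data give no handle on their visibility.

**ICE balancing** assumes equal visibility of all loci. The matrix is divided
iteratively by the outer product of relative row sums until the coefficient of
variation of unmasked row sums falls below `tol` (default 1e-5) or `max_iter`
is reached; per-bin biases are returned, NaN for masked bins. Depth
normalization divides by the total valid interaction count (upper triangle,
diagonal once) so matrices from different sequencing depths are comparable.

**A/B compartments.** Per chromosome at 500-kb resolution: the cis matrix is
converted to observed/expected using per-diagonal means, then to a Pearson
correlation matrix, whose first principal component is extracted (leading
eigenvector of the column-centered cross-product). Computing PC1 on the O/E
correlation rather than the raw correlation is the package default
(`use_oe=True`); the raw variant is one flag away because practice varies.
The sign of PC1 is arbitrary, so it is oriented by gene density: the A
compartment (PC1 > 0) is the side with the higher mean gene density.
Chromosomes with fewer than 10 valid bins are skipped; chromosomes whose
leading eigenvalue explains no more variance than a null are flagged
low-confidence. Compartment switching between two conditions is reported as
the A→B, B→A and stable fractions over bins valid in both tracks (they sum
to 1).

**Insulation and TADs.** At 40-kb resolution, the insulation score of bin *i*
is the mean contact in the *w*×*w* square pairing the *w* bins upstream with
the *w* bins downstream of *i* (the diagonal never enters), normalized by the
chromosome mean and log2-transformed. The window defaults to 500 kb and is
floored to whole bins (12 bins = 480 kb effective at 40-kb resolution) so the
default window and bin size can be used together. Boundary candidates are
upward zero crossings of the delta vector (right-minus-left mean of the score
over a 100-kb span); boundary strength is the delta swing across the
crossing, thresholded at 0.1 by default. These three parameters (window,
delta span, strength threshold) are package choices — the insulation-script
parameters used in the source analyses of this field are rarely printed —
and are all configurable. Consecutive retained boundaries delimit TADs;
domains shorter than 200 kb are filtered out. The TAD score of a domain is
the sum of contacts with both ends inside it divided by the total cis
contacts of its chromosome, so scores lie in [0,1] and disjoint domains sum
to at most 1.

**Ratio statistics.** The trans-interaction ratio of a chromosome is
trans/(cis+trans) with the diagonal counted once. The AB/(AA+BB) ratio uses
cis pairs only, discards pairs separated by less than 2 Mb (they are
dominated by intra-TAD contacts), and can exclude chromosomes (e.g. X) by
flag. Boundary pairing matches every boundary of one TAD set to the nearest
boundary of the other on the same chromosome (ties resolve to the leftmost)
and reports the fractions within 1 bin and within 2 bins.

## LAD calling

Lamin ChIP/input log-ratio tracks are re-binned to 11 kb. Each unmasked bin
scores +1 if above the enrichment threshold (track median by default; a
fixed 0 for calibrated log-ratios is a flag) and −5 (the gap penalty)
otherwise. Domains are the maximal scoring segments of this sequence,
computed with the linear-time Ruzzo–Tompa algorithm and verified in tests
against an independent exhaustive best-segment-extraction oracle. Masked
bins are score-neutral, so segments merge across assembly gaps; domains
shorter than 10 bins are dropped to keep the broad-domain character. This
±1/−penalty scheme deliberately simplifies the enriched-domain-detector
approach it emulates (whose Poisson bin scoring and FDR segment selection
operate on read counts we do not model); what it preserves is the
gap-penalty-controlled merging behavior that gives LADs their megabase
scale.

Four-way classification against LAD sets of four cell types labels each bin:
cLAD (in all four), ciLAD (in none), fLAD (query cell type only), fiLAD
(absent from the query, present in ≥1 other). Bins in the query set and in
some but not all others fit none of those definitions; they go into an
explicit fifth "other" bucket rather than being silently folded into a
class. The partition is exhaustive and mutually exclusive by construction.

## Locus dynamics

**Detection and linking.** Puncta are localized per frame by a Gaussian
low-pass filter in Fourier space, robust SNR thresholding of local maxima,
and least-squares 2D Gaussian refinement on the raw image (sub-pixel).
Linking is greedy mutual nearest neighbour against each open track's last
position, capped at 5 camera pixels (800 nm at the default 160 nm/px); a
track may resume after up to 10 missing frames, and a longer disappearance
closes it — any later reappearance is a new particle. This is deliberately
simpler than global LAP tracking; at the sparse spot densities of
locus-labeling experiments greedy mutual-NN linking is near-optimal.

**MSD.** For a trajectory spanning N frames, the time-averaged MSD at lag
n·δt sums squared displacements over pair origins j = 1 … N−1−n with
prefactor 1/(N−1−n), and lags are capped at n < N/10 to keep long-lag
estimates precise. Note the sum's origin at j = 1: the first frame is never
used as a pair origin. This convention is reproduced exactly (it is what
the MSD oracle transcribes); the conventional j = 0 variant sits behind
`include_j0=True` and agrees asymptotically. Pairs spanning missing frames
are skipped and the prefactor reduced to the pairs actually used.
Trajectories shorter than 20 frames are rejected.

**Anomalous-diffusion fit.** MSD = D·t^α is fitted by linear least squares
of log MSD on log t (zero lags excluded; ≥3 usable lags required). D is the
generalized diffusion coefficient in µm²/s^α; α < 1 indicates subdiffusion.
A nonlinear original-space fit is available behind `log_space=False`; the
log-space default weights the decades evenly, which suits power-law data.
Fits with α below 0.1 are flagged confined. Both per-trajectory fitting and
ensemble-curve fitting are provided; ensemble MSD curves are per-lag means ±
SE across trajectories sharing a subnuclear label, dropping lags covered by
fewer than 3 trajectories.

## Nuclear geometry

Shells: the envelope-distance transform of the nucleus mask (anisotropic
voxel spacing supported, e.g. 400-nm z-steps) is split at equal-count
quantiles into 5 zones — equal area in 2D, equal volume in 3D — and each
shell's summed intensity is divided by the whole-nucleus total. Locus
positions are classified by their distance-transform value: ≤ 640 nm (4
pixels) from the envelope is periphery, otherwise nucleoplasm (nucleoli
included); the boundary case is periphery by convention. Territory metrics:
voxel volume relative to the nucleus, center-to-center distance normalized
by the cube root of nuclear volume (square root of area in 2D, keeping the
statistic dimensionless), and pairwise overlap as any shared voxel.
Territory segmentation is Otsu per channel by default with an absolute
threshold option. Diameter profiles are cropped between the two outermost
DAPI peaks, resampled to a common length, normalized to their own mean and
averaged.

## Synthetic-data generators

The generators define the study conditions the validation runs under.

*Hi-C*: expected cis count ∝ |i−j|^−γ (γ = 1 by default, the generic
interphase scaling) × c_comp for same-compartment pairs × c_tad for
same-TAD pairs; trans pairs get β × mean cis × the compartment factor;
counts are Poisson around the depth-scaled expectation. Compartments
alternate in 2-Mb blocks by default; a gene-density track correlated with
the A class is returned for orientation. *fBm*: each coordinate is an exact
fractional Brownian motion (Davies–Harte circulant embedding, Cholesky on
the exact covariance as fallback for short series) with Hurst index α/2,
scaled so the ensemble 2D MSD is D·t^α before i.i.d. Gaussian localization
noise; frames drop independently at the stated probability. Exact
covariance construction was chosen over spectral approximation so exponent
recovery tests measure the estimator, not simulator bias. *Lamin tracks*:
baseline (−0.5) plus shift (+1.0) inside planted domains plus Gaussian
noise (SD 0.3) at 11-kb bins. *Nuclei*: ellipsoidal masks with DAPI filled
per planted shell weights, spherical territories and point loci (rejected
if outside the nucleus), optional Poisson photon noise. *Spot movies*: 2D
Gaussian puncta of fixed photon budget over Poisson background.

Noise models are Poisson for counts/photons and Gaussian for log-ratios and
localization error throughout. All generators are bit-reproducible from
their seed.

What the generators do not emulate: locus-dependent visibility biases and
restriction-fragment structure in Hi-C, copy-number and mappability
artifacts in ChIP tracks, motion blur and PSF anisotropy in imaging, and
correlated (non-fractional-Gaussian) motion such as directed transport.
Passing the synthetic validations therefore demonstrates correctness of the
estimators under their stated model, not robustness to every artifact of
real data.

## Problem sizes and numerics

Validation runs use desk-scale problems chosen to make Monte-Carlo error
comfortably smaller than the tested tolerances: 100 trajectories × 600
frames for exponent recovery (bias ≲ 0.02 observed, tolerance 0.05),
~400–1000-bin chromosomes for TAD/compartment recovery at full planted
signal strength (c = 3), 910-bin tracks for LAD recovery. ICE iterates to a
row-sum CV of 1e-5 by default. Degenerate inputs follow explicit rules:
all-depleted tracks give an empty domain set (not an error), chromosomes
smaller than the insulation window are skipped with a warning, flat frames
yield no detections, empty classes report NaN means.

## Known limitations

- The LAD caller is a behavioral, not statistical, re-creation of
  enriched-domain detection: no FDR control, no read-count model.
- Compartment PC1 on short chromosomes or weak signal can be unstable; the
  low-confidence flag is a heuristic (eigenvalue vs 2/n), not a test.
- The greedy linker can mis-assign identities when spot density approaches
  one spot per linking radius.
- Boundary-strength units are delta-swing log2 units; the 0.1 default was
  chosen to separate planted boundaries (≈1.5) from Poisson noise (≈0.02)
  with two orders of margin, but real data may need tuning.
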