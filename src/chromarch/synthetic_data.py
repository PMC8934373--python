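"""Synthetic-data generators with planted ground truth.

Every input the analysis pipeline consumes can be simulated here with known
truth, matching the statistical structure the downstream methods assume:

* contact matrices with power-law distance decay, planted checkerboard A/B
  compartments, TAD blocks and a trans-contact background (Poisson counts);
* fractional-Brownian-motion locus trajectories with exact covariance
  (Davies-Harte circulant embedding, Cholesky fallback), localization noise
  and missing frames;
* log2(ChIP/input)-style tracks with planted broad enriched domains
  (Gaussian noise);
* ellipsoidal nuclei with radially structured DAPI intensity, spherical
  chromosome territories and point loci;
* spot movies rendering trajectories as 2D Gaussian puncta over Poisson
  background.

All generators take an explicit RNG seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hic_metrics import ContactMatrix, n_bins
from .lad_domains import DomainSet, GenomicTrack
from .loci_dynamics import Trajectory, TrajectoryEnsemble
from .nuclear_geometry import NucleusModel, PERIPHERY_THRESHOLD_NM

__all__ = [
    "HiCSimConfig",
    "FbmSimConfig",
    "NucleusSimConfig",
    "LaminTrackSimConfig",
    "gen_contact_matrix",
    "gen_fbm_trajectories",
    "gen_nucleus_image",
    "gen_lamin_track",
    "gen_spot_movie",
    "fbm_path",
]


# ---------------------------------------------------------------------------
# Hi-C contact matrices
# ---------------------------------------------------------------------------

@dataclass
class HiCSimConfig:
    """Planted-structure Hi-C simulation.

    Expected cis count for bins i, j on one chromosome:
    ``depth-scaled |i-j|^-gamma * c_comp^[same A/B class] * c_tad^[same TAD]``;
    trans pairs get ``beta x (mean cis level) x c_comp^[same class]``.
    Counts are Poisson.
    """

    chrom_lengths: dict                 # name -> bp
    bin_size: int = 500_000
    comp_block_bp: int = 2_000_000      # alternating A/B block length
    comp_labels: dict = None            # optional explicit per-chrom labels
    c_comp: float = 3.0
    tad_boundaries: dict = field(default_factory=dict)  # chrom -> bp list
    c_tad: float = 3.0
    gamma: float = 1.0
    beta: float = 0.0                   # trans background vs mean cis
    depth: float = 5e6
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if self.c_comp < 1 or self.c_tad < 1:
            raise ValueError("contact multipliers must be >= 1")
        if self.gamma <= 0:
            raise ValueError("distance-decay exponent must be positive")
        if self.beta < 0:
            raise ValueError("trans background must be non-negative")
        for c, l in self.chrom_lengths.items():
            if l % self.bin_size != 0:
                raise ValueError(
                    f"{c}: bin size must divide the chromosome length")


def _class_labels(cfg: HiCSimConfig) -> dict:
    if cfg.comp_labels is not None:
        return {c: np.asarray(v) for c, v in cfg.comp_labels.items()}
    out = {}
    block_bins = max(1, cfg.comp_block_bp // cfg.bin_size)
    for c, l in cfg.chrom_lengths.items():
        nb = n_bins(l, cfg.bin_size)
        out[c] = np.where((np.arange(nb) // block_bins) % 2 == 0, "A", "B")
    return out


def _tad_ids(cfg: HiCSimConfig) -> dict:
    out = {}
    for c, l in cfg.chrom_lengths.items():
        nb = n_bins(l, cfg.bin_size)
        cuts = sorted(b // cfg.bin_size for b in cfg.tad_boundaries.get(c, []))
        tid = np.zeros(nb, dtype=int)
        for k, cut in enumerate(cuts):
            tid[cut:] = k + 1
        out[c] = tid
    return out


def expected_contact_matrix(cfg: HiCSimConfig) -> np.ndarray:
    """Closed-form expected count matrix (the Poisson means)."""
    labels = _class_labels(cfg)
    tads = _tad_ids(cfg)
    chroms = list(cfg.chrom_lengths)
    nb = {c: n_bins(l, cfg.bin_size) for c, l in cfg.chrom_lengths.items()}
    total = sum(nb.values())
    off, pos = {}, 0
    for c in chroms:
        off[c] = pos
        pos += nb[c]
    exp = np.zeros((total, total))
    cis_vals = []
    for c in chroms:
        n = nb[c]
        idx = np.arange(n)
        d = np.abs(idx[:, None] - idx[None, :]).astype(float)
        decay = np.maximum(d, 1.0) ** (-cfg.gamma)
        same_class = np.equal.outer(labels[c], labels[c])
        same_tad = np.equal.outer(tads[c], tads[c])
        block = decay * np.where(same_class, cfg.c_comp, 1.0) \
                      * np.where(same_tad, cfg.c_tad, 1.0)
        s = slice(off[c], off[c] + n)
        exp[s, s] = block
        cis_vals.append(block[np.triu_indices(n)])
    mean_cis = float(np.concatenate(cis_vals).mean())
    if cfg.beta > 0:
        for i, ca in enumerate(chroms):
            for cb in chroms[i + 1:]:
                same_class = np.equal.outer(labels[ca], labels[cb])
                tblock = cfg.beta * mean_cis * np.where(same_class,
                                                        cfg.c_comp, 1.0)
                sa = slice(off[ca], off[ca] + nb[ca])
                sb = slice(off[cb], off[cb] + nb[cb])
                exp[sa, sb] = tblock
                exp[sb, sa] = tblock.T
    scale = cfg.depth / np.triu(exp).sum()
    return exp * scale


def gen_contact_matrix(cfg: HiCSimConfig) -> tuple:
    """Draw a Poisson contact matrix around the planted expectation.

    Returns ``(ContactMatrix, truth)`` where ``truth`` holds the per-bin A/B
    class labels, the planted TAD boundary bins, the expectation matrix, and
    a gene-density track correlated with the A class (for compartment
    orientation downstream).
    """
    rng = np.random.default_rng(cfg.seed)
    exp = expected_contact_matrix(cfg)
    upper = np.triu(rng.poisson(exp))
    counts = upper + np.triu(upper, k=1).T
    m = ContactMatrix(dict(cfg.chrom_lengths), cfg.bin_size,
                      counts.astype(float))
    labels = _class_labels(cfg)
    density = {
        c: np.where(lab == "A", 1.0, 0.2) + rng.normal(0, 0.01, lab.size)
        for c, lab in labels.items()
    }
    gene_density = GenomicTrack(dict(cfg.chrom_lengths), cfg.bin_size, density)
    truth = {
        "class_labels": labels,
        "tad_boundaries": {c: sorted(b // cfg.bin_size
                                     for b in cfg.tad_boundaries.get(c, []))
                           for c in cfg.chrom_lengths},
        "expected": exp,
        "gene_density": gene_density,
    }
    return m, truth


# ---------------------------------------------------------------------------
# Fractional Brownian motion
# ---------------------------------------------------------------------------

@dataclass
class FbmSimConfig:
    """Ensemble of 2D fBm locus trajectories with MSD(t) = D t^alpha."""

    n_trajectories: int = 100
    n_frames: int = 600
    dt: float = 0.1                     # s; 10 Hz acquisition
    alpha: float = 0.5
    D: float = 0.01                     # um^2 / s^alpha
    noise_sd: float = 0.0               # um localization noise
    missing_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 2.0:
            raise ValueError("alpha must lie in the open interval (0, 2)")
        if self.n_frames < 20:
            raise ValueError("need at least 20 frames")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError("missing-frame probability must be in [0, 1)")


def _fgn_davies_harte(n: int, hurst: float, rng) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant embedding.

    Returns ``n`` unit-scale fGn increments, or None when the circulant
    eigenvalues go negative (then the caller falls back to Cholesky).
    """
    k = np.arange(n)
    r = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst)
               + np.abs(k - 1) ** (2 * hurst))
    circ = np.concatenate([r, r[-2:0:-1]])
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-10:
        return None
    lam = np.clip(lam, 0, None)
    m = circ.size
    w = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    f = np.fft.fft(np.sqrt(lam / (2 * m)) * w)
    return f.real[:n] * np.sqrt(2.0)


def _fbm_cholesky(n: int, hurst: float, rng) -> np.ndarray:
    """fBm positions B_H(1..n) from the exact covariance (short series)."""
    t = np.arange(1, n + 1, dtype=float)
    cov = 0.5 * (t[:, None] ** (2 * hurst) + t[None, :] ** (2 * hurst)
                 - np.abs(t[:, None] - t[None, :]) ** (2 * hurst))
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return L @ rng.standard_normal(n)


def fbm_path(n_steps: int, hurst: float, rng) -> np.ndarray:
    """Unit-scale fBm positions B_H(0), B_H(1), ..., B_H(n_steps)."""
    incr = _fgn_davies_harte(n_steps, hurst, rng)
    if incr is not None:
        path = np.concatenate([[0.0], np.cumsum(incr)])
    else:
        path = np.concatenate([[0.0], _fbm_cholesky(n_steps, hurst, rng)])
    return path


def gen_fbm_trajectories(cfg: FbmSimConfig) -> tuple:
    """Simulate 2D fBm trajectories scaled so ensemble MSD(t) = D t^alpha.

    Each coordinate is an independent fBm with Hurst index alpha/2, scaled so
    the per-coordinate MSD is (D/2) t^alpha before localization noise; i.i.d.
    Gaussian noise of ``noise_sd`` is then added and frames are dropped
    independently with ``missing_prob`` (first frame always kept).

    Returns ``(TrajectoryEnsemble, {"D": D, "alpha": alpha})``.
    """
    rng = np.random.default_rng(cfg.seed)
    hurst = cfg.alpha / 2.0
    scale = np.sqrt(cfg.D / 2.0) * cfg.dt ** hurst
    trajs = []
    for i in range(cfg.n_trajectories):
        x = fbm_path(cfg.n_frames - 1, hurst, rng) * scale
        y = fbm_path(cfg.n_frames - 1, hurst, rng) * scale
        xy = np.column_stack([x, y])
        if cfg.noise_sd > 0:
            xy = xy + rng.normal(0, cfg.noise_sd, xy.shape)
        frames = np.arange(cfg.n_frames)
        if cfg.missing_prob > 0:
            keep = rng.random(cfg.n_frames) >= cfg.missing_prob
            keep[0] = True
            frames, xy = frames[keep], xy[keep]
        trajs.append(Trajectory(i, frames, xy, dt=cfg.dt))
    ens = TrajectoryEnsemble(trajs, dt=cfg.dt)
    return ens, {"D": cfg.D, "alpha": cfg.alpha}


# ---------------------------------------------------------------------------
# Nucleus images
# ---------------------------------------------------------------------------

@dataclass
class NucleusSimConfig:
    """Ellipsoidal nucleus with shell-structured DAPI, spherical territories
    and point loci.

    ``shell_weights`` are intensity fractions outermost -> innermost over 5
    equal-area (2D) or equal-volume (3D) shells.  ``territories`` is a list of
    ``(center_px, radius_px, channel)``; ``loci`` a list of
    ``(position_px, channel)``.  Positions use array axis order.
    """

    shape: tuple = (256, 256)
    voxel_nm: tuple = 160.0
    semi_axes_px: tuple = (100, 80)
    center_px: tuple = None
    shell_weights: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    territories: list = field(default_factory=list)
    loci: list = field(default_factory=list)
    background: float = 10.0
    total_photons: float = 1e6
    photon_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.shell_weights, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("shell weights must be non-negative and sum to 1")
        if self.center_px is None:
            self.center_px = tuple(s / 2.0 for s in self.shape)
        if len(self.semi_axes_px) != len(self.shape):
            raise ValueError("semi-axes must match image dimensionality")


def _ellipsoid_mask(shape, center, semi_axes):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / a) ** 2
              for g, c, a in zip(grids, center, semi_axes))
    return acc <= 1.0


def gen_nucleus_image(cfg: NucleusSimConfig) -> tuple:
    """Render a multi-channel nucleus image with planted geometry.

    Channel 0 is DAPI filled according to the shell weights over equal-
    area/volume concentric zones; each territory/locus channel holds its
    Gaussian-blurred solid or spot.  Territories or loci extending outside
    the nucleus are rejected.

    Returns ``(image [c, ...], truth)`` with the nucleus mask and model,
    per-territory masks/centers/volumes and per-locus periphery labels under
    the 640-nm threshold.
    """
    rng = np.random.default_rng(cfg.seed)
    mask = _ellipsoid_mask(cfg.shape, cfg.center_px, cfg.semi_axes_px)
    nucleus = NucleusModel(mask, cfg.voxel_nm)
    nd = mask.ndim

    n_shells = len(cfg.shell_weights)
    dist_nm = nucleus.boundary_distance_nm()
    inside = dist_nm[mask]
    edges = np.quantile(inside, np.linspace(0, 1, n_shells + 1))
    shell_idx = np.clip(np.searchsorted(edges[1:-1], inside, side="right"),
                        0, n_shells - 1)
    dapi = np.full(cfg.shape, float(cfg.background))
    vals = np.zeros(inside.size)
    for k in range(n_shells):
        sel = shell_idx == k
        if sel.any():
            vals[sel] = cfg.total_photons * cfg.shell_weights[k] / sel.sum()
    dapi[mask] += vals

    channels = [dapi]
    terr_truth = []
    for center, radius, _chan in cfg.territories:
        tmask = _ellipsoid_mask(cfg.shape, center, (radius,) * nd)
        if (tmask & ~mask).any():
            raise ValueError("territory extends outside the nucleus")
        img = np.full(cfg.shape, float(cfg.background))
        img += ndimage.gaussian_filter(tmask * 1000.0, sigma=1.0)
        channels.append(img)
        terr_truth.append({
            "mask": tmask,
            "center_px": tuple(float(c) for c in center),
            "volume_vox": int(tmask.sum()),
        })
    loci_truth = []
    for pos, _chan in cfg.loci:
        idx = tuple(int(round(p)) for p in pos)
        if not mask[idx]:
            raise ValueError("locus outside the nucleus")
        img = np.full(cfg.shape, float(cfg.background))
        spot = np.zeros(cfg.shape)
        spot[idx] = 5000.0
        img += ndimage.gaussian_filter(spot, sigma=1.5)
        channels.append(img)
        d = float(dist_nm[idx])
        loci_truth.append({
            "position_px": tuple(float(p) for p in pos),
            "envelope_distance_nm": d,
            "label": "periphery" if d <= PERIPHERY_THRESHOLD_NM
                     else "nucleoplasm",
        })
    image = np.stack(channels)
    if cfg.photon_noise:
        image = rng.poisson(image).astype(float)
    truth = {
        "nucleus_mask": mask,
        "nucleus": nucleus,
        "shell_weights": np.asarray(cfg.shell_weights, dtype=float),
        "territories": terr_truth,
        "loci": loci_truth,
    }
    return image, truth


# ---------------------------------------------------------------------------
# Lamin ChIP-style tracks
# ---------------------------------------------------------------------------

@dataclass
class LaminTrackSimConfig:
    """log2(ChIP/input)-style track with planted broad enriched domains."""

    chrom_length: int = 11_000_000
    bin_size: int = 11_000
    domains: list = field(default_factory=list)   # (start_bp, end_bp) list
    shift: float = 1.0                            # enrichment over baseline
    baseline: float = -0.5
    noise_sd: float = 0.3
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        if self.shift <= 0:
            raise ValueError("domain shift must be positive")
        if self.baseline > 0:
            raise ValueError("baseline mean must be <= 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        doms = sorted(self.domains)
        for (s1, e1), (s2, e2) in zip(doms, doms[1:]):
            if s2 < e1:
                raise ValueError("planted domains must not overlap")
        for s, e in doms:
            if s < 0 or e > self.chrom_length or e <= s:
                raise ValueError("domain outside the chromosome")


def gen_lamin_track(cfg: LaminTrackSimConfig) -> tuple:
    """Per-bin value = baseline + shift x [bin in domain] + Gaussian noise.

    Returns ``(GenomicTrack, DomainSet truth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    nb = n_bins(cfg.chrom_length, cfg.bin_size)
    v = np.full(nb, cfg.baseline)
    for s, e in cfg.domains:
        v[s // cfg.bin_size: -(-e // cfg.bin_size)] += cfg.shift
    if cfg.noise_sd > 0:
        v = v + rng.normal(0, cfg.noise_sd, nb)
    track = GenomicTrack({cfg.chrom: cfg.chrom_length}, cfg.bin_size,
                         {cfg.chrom: v})
    truth = DomainSet([(cfg.chrom, int(s), int(e)) for s, e in cfg.domains]) \
        if cfg.domains else DomainSet([])
    return track, truth


# ---------------------------------------------------------------------------
# Spot movies
# ---------------------------------------------------------------------------

def gen_spot_movie(
    ens: TrajectoryEnsemble,
    shape: tuple = (64, 64),
    psf_sigma: float = 1.5,
    photons: float = 2000.0,
    background: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a trajectory ensemble as a movie of Gaussian puncta.

    Positions (um) are converted to pixels via the ensemble's pixel size;
    each visible spot contributes ``photons`` distributed as an isotropic 2D
    Gaussian of ``psf_sigma`` px, on a uniform ``background``; the frame is
    Poisson sampled.  Spots are centered on the frame grid so trajectories
    should start near the field center.
    """
    rng = np.random.default_rng(seed)
    n_frames = 1 + max((int(t.frames[-1]) for t in ens), default=0)
    um_per_px = ens.pixel_nm / 1000.0
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    movie = np.zeros((n_frames,) + tuple(shape))
    peak = photons / (2 * np.pi * psf_sigma ** 2)
    for t in ens:
        px = t.xy / um_per_px
        for f, (x, y) in zip(t.frames, px):
            if not (0 <= x < shape[1] and 0 <= y < shape[0]):
                continue
            movie[f] += peak * np.exp(-((yy - y) ** 2 + (xx - x) ** 2)
                                      / (2 * psf_sigma ** 2))
    movie += background
    return rng.poisson(movie).astype(float)
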