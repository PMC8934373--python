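"""Nuclear geometry: radial shell analysis, periphery/nucleoplasm locus
classification, and chromosome-territory metrics.

The nucleus is segmented from the DAPI channel; its mask drives three
quantifications used throughout lamina biology:

* shell profiles — the nucleus is divided into 5 concentric shells of equal
  area (2D equatorial sections; equal volume in 3D) from periphery to
  interior, and the fraction of a marker's fluorescence falling in each shell
  is reported;
* locus position — a locus within 640 nm (4 camera pixels) of the nuclear
  envelope is classified "periphery", otherwise "nucleoplasm" (nucleoli count
  as nucleoplasm);
* territory metrics — per chromosome territory, the volume relative to the
  nucleus and the center-to-center distance normalized by the cube root of
  the nuclear volume, plus pairwise territory overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "NucleusModel",
    "ShellProfile",
    "TerritoryMetrics",
    "shell_profile",
    "align_diameter_profile",
    "classify_locus_position",
    "territory_metrics",
    "overlap_frequency",
    "segment_territories",
]

PERIPHERY_THRESHOLD_NM = 640.0       # 4 px at 160 nm/px


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class NucleusModel:
    """Binary nucleus mask with physical calibration.

    ``voxel_nm`` is a scalar (isotropic) or a per-axis sequence, e.g.
    ``(400, 160, 160)`` for z-stacks with a 400-nm step.
    """

    mask: np.ndarray
    voxel_nm: tuple
    equatorial: bool = True       # 2D masks: equatorial plane section

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.isscalar(self.voxel_nm):
            self.voxel_nm = (float(self.voxel_nm),) * self.mask.ndim
        self.voxel_nm = tuple(float(v) for v in self.voxel_nm)
        if len(self.voxel_nm) != self.mask.ndim:
            raise ValueError("voxel_nm length must match mask dimensionality")
        if not self.mask.any():
            raise ValueError("empty nucleus mask")
        lab, n = ndimage.label(self.mask)
        if n > 1:
            # keep the largest connected component
            sizes = ndimage.sum(self.mask, lab, range(1, n + 1))
            self.mask = lab == (1 + int(np.argmax(sizes)))

    @property
    def ndim(self) -> int:
        return self.mask.ndim

    @property
    def center(self) -> np.ndarray:
        return np.array(ndimage.center_of_mass(self.mask))

    @property
    def voxel_um(self) -> np.ndarray:
        return np.array(self.voxel_nm) / 1000.0

    @property
    def volume_um(self) -> float:
        """Area (um^2, 2D) or volume (um^3, 3D) of the mask."""
        return float(self.mask.sum() * np.prod(self.voxel_um))

    def boundary_distance_nm(self) -> np.ndarray:
        """Euclidean distance (nm) of each voxel to the nuclear envelope."""
        return ndimage.distance_transform_edt(
            self.mask, sampling=self.voxel_nm)


@dataclass
class ShellProfile:
    """Normalized intensity fractions per shell, outermost to innermost."""

    fractions: np.ndarray
    shell_edges_nm: np.ndarray    # distance-to-envelope quantile edges

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if (self.fractions < 0).any():
            raise ValueError("shell fractions must be non-negative")
        if not np.isclose(self.fractions.sum(), 1.0):
            raise ValueError("shell fractions must sum to 1")


@dataclass
class TerritoryMetrics:
    labels: list                  # territory ids
    relative_volume: np.ndarray   # territory / nucleus, in (0, 1]
    norm_center_distance: np.ndarray   # dist / V_nucleus^(1/3), dimensionless
    overlap_pairs: dict           # (id_a, id_b) -> bool (any shared voxel)


# ---------------------------------------------------------------------------
# Shell analysis
# ---------------------------------------------------------------------------

def shell_profile(intensity: np.ndarray, nucleus: NucleusModel,
                  n_shells: int = 5) -> ShellProfile:
    """Fraction of total nuclear fluorescence in each concentric shell.

    Shells are built by splitting the envelope-distance transform of the mask
    at its equal-count quantiles, so each shell holds the same number of
    pixels (equal area in 2D, equal volume in 3D), from the nuclear periphery
    (shell 1) to the interior (shell ``n_shells``).  Each shell's summed
    intensity is divided by the whole-nucleus sum.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != nucleus.mask.shape:
        raise ValueError("intensity and mask shapes differ")
    npx = int(nucleus.mask.sum())
    if npx < n_shells:
        raise ValueError("mask smaller than one pixel per shell")
    dist = nucleus.boundary_distance_nm()[nucleus.mask]
    edges = np.quantile(dist, np.linspace(0, 1, n_shells + 1))
    shell_idx = np.clip(np.searchsorted(edges[1:-1], dist, side="right"),
                        0, n_shells - 1)
    vals = intensity[nucleus.mask]
    total = vals.sum()
    if total <= 0:
        raise ValueError("no fluorescence inside the nucleus")
    fractions = np.array([vals[shell_idx == k].sum() / total
                          for k in range(n_shells)])
    return ShellProfile(fractions, edges)


def align_diameter_profile(intensity_profiles: list, dapi_profiles: list,
                           n_points: int = 100) -> np.ndarray:
    """Average diameter line profiles across nuclei.

    Each profile is delimited by the two outermost peaks of its DAPI profile
    (the envelope signal), resampled to ``n_points``, normalized to its own
    mean intensity, and the normalized profiles are averaged.  Profiles whose
    DAPI trace shows fewer than two peaks are rejected with a warning.
    """
    from scipy.signal import find_peaks

    aligned = []
    for prof, dapi in zip(intensity_profiles, dapi_profiles):
        prof = np.asarray(prof, dtype=float)
        dapi = np.asarray(dapi, dtype=float)
        peaks, _ = find_peaks(dapi, prominence=0.05 * np.ptp(dapi))
        if peaks.size < 2:
            warnings.warn("profile with fewer than two DAPI peaks rejected")
            continue
        a, b = int(peaks[0]), int(peaks[-1])
        seg = prof[a:b + 1]
        if seg.mean() == 0:
            continue
        x = np.linspace(0, 1, seg.size)
        xi = np.linspace(0, 1, n_points)
        aligned.append(np.interp(xi, x, seg / seg.mean()))
    if not aligned:
        raise ValueError("no usable profiles")
    return np.mean(aligned, axis=0)


# ---------------------------------------------------------------------------
# Locus classification
# ---------------------------------------------------------------------------

def classify_locus_position(locus: tuple, nucleus: NucleusModel,
                            threshold_nm: float = PERIPHERY_THRESHOLD_NM) -> str:
    """Classify a locus as nuclear periphery or nucleoplasm.

    ``locus`` is a voxel coordinate (same axis order as the mask).  The
    Euclidean distance from the locus to the nuclear envelope is read off the
    distance transform; distances <= ``threshold_nm`` (640 nm, i.e. 4 camera
    pixels) classify as ``"periphery"``, larger ones as ``"nucleoplasm"``
    (which includes nucleoli).  The boundary case is periphery by convention.
    """
    idx = tuple(int(round(c)) for c in locus)
    if any(i < 0 or i >= s for i, s in zip(idx, nucleus.mask.shape)) \
            or not nucleus.mask[idx]:
        raise ValueError("locus outside the nucleus mask")
    d = nucleus.boundary_distance_nm()[idx]
    return "periphery" if d <= threshold_nm else "nucleoplasm"


# ---------------------------------------------------------------------------
# Chromosome territories
# ---------------------------------------------------------------------------

def segment_territories(channel: np.ndarray, nucleus: NucleusModel,
                        threshold: float = None) -> np.ndarray:
    """Label chromosome-territory voxels in one FISH channel.

    Thresholding is Otsu by default (configurable absolute ``threshold``),
    restricted to the nucleus; connected components are labeled.
    """
    from skimage.filters import threshold_otsu

    channel = np.asarray(channel, dtype=float)
    inside = channel[nucleus.mask]
    thr = threshold if threshold is not None else threshold_otsu(inside)
    binary = (channel > thr) & nucleus.mask
    lab, _ = ndimage.label(binary)
    return lab


def territory_metrics(nucleus: NucleusModel, territories: dict) -> TerritoryMetrics:
    """Relative volume, normalized radial position and pairwise overlap.

    ``territories`` maps a territory id to its binary mask (same shape as the
    nucleus mask).  For each territory: voxel volume / nuclear volume; the
    distance between the nuclear and territory centers of mass divided by the
    cube root (square root in 2D) of the nuclear volume; overlap between two
    territories is any shared voxel.
    """
    vox = nucleus.voxel_um
    vol_n = nucleus.volume_um
    center_n = nucleus.center * vox
    norm = vol_n ** (1.0 / nucleus.ndim)
    labels, rel, dist = [], [], []
    masks = {}
    for tid, m in territories.items():
        m = np.asarray(m, dtype=bool)
        if m.shape != nucleus.mask.shape:
            raise ValueError(f"territory {tid}: shape mismatch")
        if not m.any():
            raise ValueError(f"territory {tid}: empty mask")
        masks[tid] = m
        labels.append(tid)
        rel.append(m.sum() * np.prod(vox) / vol_n)
        c = np.array(ndimage.center_of_mass(m)) * vox
        dist.append(np.linalg.norm(c - center_n) / norm)
    overlap = {}
    ids = list(labels)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            overlap[(a, b)] = bool((masks[a] & masks[b]).any())
    return TerritoryMetrics(labels, np.array(rel), np.array(dist), overlap)


def overlap_frequency(flags: list, other_flags: list = None) -> dict:
    """Fraction of cells showing territory overlap, with an optional
    Fisher-exact comparison against a second condition.

    Returns ``{"fraction": f, "n": n}`` plus ``odds_ratio`` and ``p_value``
    when ``other_flags`` is given (two-sided Fisher exact test on the 2x2
    overlap-by-condition table).
    """
    flags = np.asarray(flags, dtype=bool)
    out = {"fraction": float(flags.mean()) if flags.size else float("nan"),
           "n": int(flags.size)}
    if other_flags is not None:
        other = np.asarray(other_flags, dtype=bool)
        table = [[int(flags.sum()), int((~flags).sum())],
                 [int(other.sum()), int((~other).sum())]]
        oddsratio, p = stats.fisher_exact(table, alternative="two-sided")
        out["odds_ratio"] = float(oddsratio)
        out["p_value"] = float(p)
        out["other_fraction"] = float(other.mean()) if other.size else float("nan")
    return out
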