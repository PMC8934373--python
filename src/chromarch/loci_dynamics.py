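"""Single-locus tracking and anomalous-diffusion analysis.

The workflow mirrors live-cell 2D tracking of fluorescently labeled genomic
loci: puncta are localized per frame by 2D Gaussian fitting after Fourier
low-pass filtering, linked frame-to-frame to their nearest neighbour within a
5-camera-pixel (800 nm) radius, and split into separate particles when a
trajectory gap exceeds 10 consecutive frames.

For a trajectory of N frames the time-averaged mean square displacement is

    MSD(n dt) = 1/(N-1-n) * sum_{j=1}^{N-1-n}
                [x(j dt + n dt) - x(j dt)]^2 + [y(j dt + n dt) - y(j dt)]^2

with lags restricted to n < N/10 to keep long-lag estimates precise.  Note
the sum starts at j = 1 (the first frame is not used as a pair origin); a
conventional j = 0 variant is available behind a flag and the two agree
asymptotically.  Each MSD curve is fitted by least squares to the anomalous
diffusion law MSD = D t^alpha, where D is the generalized diffusion
coefficient (um^2/s^alpha) and alpha the scaling exponent (alpha < 1:
subdiffusion; alpha = 1: Brownian).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "Trajectory",
    "TrajectoryEnsemble",
    "MSDCurve",
    "DiffusionFit",
    "detect_spots",
    "link_spots",
    "split_on_gaps",
    "compute_msd",
    "fit_power_law",
    "ensemble_msd",
]

DEFAULT_PIXEL_NM = 160.0     # implied by the 5 px == 800 nm linking radius
MAX_LINK_PX = 5.0
MAX_GAP_FRAMES = 10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-indexed 2D positions of one locus (um), possibly with gaps."""

    locus_id: int
    frames: np.ndarray            # strictly increasing frame indices
    xy: np.ndarray                # shape (n, 2), um
    dt: float                     # frame interval, s
    pixel_nm: float = DEFAULT_PIXEL_NM
    label: str = "unassigned"     # periphery | nucleoplasm | unassigned

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.ndim != 1 or self.xy.shape != (self.frames.size, 2):
            raise ValueError("frames and xy shapes inconsistent")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not np.isfinite(self.xy).all():
            raise ValueError("positions must be finite")

    @property
    def n_frames(self) -> int:
        """Span N of the trajectory in frames (first to last, inclusive)."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def gap_exceeded(self) -> bool:
        """True when an internal gap exceeds the 10-frame limit, in which
        case the trajectory must be split before MSD analysis."""
        return bool(np.any(np.diff(self.frames) > MAX_GAP_FRAMES + 1))


@dataclass
class TrajectoryEnsemble:
    trajectories: list
    dt: float
    pixel_nm: float = DEFAULT_PIXEL_NM

    def __len__(self):
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)


@dataclass
class MSDCurve:
    """Time-averaged MSD at lags n*dt, n = 1 .. < N/10."""

    lags: np.ndarray              # seconds
    msd: np.ndarray               # um^2
    counts: np.ndarray            # displacement pairs per lag
    n_frames: int

    def __post_init__(self):
        if (np.asarray(self.msd) < 0).any():
            raise ValueError("MSD must be non-negative")


@dataclass
class DiffusionFit:
    D: float                      # um^2 / s^alpha
    alpha: float
    residual: float               # RMS residual in log space
    ensemble: bool = False
    confined: bool = False        # alpha ~ 0 (flat MSD)


# ---------------------------------------------------------------------------
# Spot detection
# ---------------------------------------------------------------------------

def _fourier_lowpass(frame: np.ndarray, cutoff_px: float) -> np.ndarray:
    """Gaussian low-pass in Fourier space with real-space sigma cutoff_px."""
    f = np.fft.rfft2(frame)
    ny, nx = frame.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.rfftfreq(nx)[None, :]
    h = np.exp(-2.0 * (np.pi * cutoff_px) ** 2 * (fy ** 2 + fx ** 2))
    return np.fft.irfft2(f * h, s=frame.shape)


def _gauss2d(params, yy, xx):
    amp, y0, x0, sigma, off = params
    return off + amp * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2)
                              / (2.0 * sigma ** 2))


def detect_spots(
    frame: np.ndarray,
    lowpass_cutoff: float = 1.0,
    min_snr: float = 5.0,
    fit_radius: int = 4,
) -> list:
    """Localize fluorescent puncta in one frame.

    The frame is Fourier low-pass filtered, local maxima exceeding
    ``background + min_snr * noise_sd`` (robust estimates from the filtered
    image) are refined by least-squares 2D Gaussian fits on the raw image, and
    sub-pixel centers are returned as ``(x, y, amplitude, sigma)`` tuples.

    A flat or saturated frame yields an empty list with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        warnings.warn("flat frame: no spots detectable")
        return []
    sm = _fourier_lowpass(frame, lowpass_cutoff)
    bg = np.median(sm)
    noise = 1.4826 * np.median(np.abs(sm - bg))
    if noise == 0:
        noise = sm.std() or 1.0
    thr = bg + min_snr * noise
    maxima = (sm == ndimage.maximum_filter(sm, size=5)) & (sm > thr)
    ys, xs = np.nonzero(maxima)
    spots = []
    ny, nx = frame.shape
    for y0, x0 in zip(ys, xs):
        y1, y2 = max(0, y0 - fit_radius), min(ny, y0 + fit_radius + 1)
        x1, x2 = max(0, x0 - fit_radius), min(nx, x0 + fit_radius + 1)
        win = frame[y1:y2, x1:x2]
        yy, xx = np.mgrid[y1:y2, x1:x2]
        p0 = (float(win.max() - win.min()), float(y0), float(x0), 1.5,
              float(win.min()))
        try:
            res = optimize.least_squares(
                lambda p: (_gauss2d(p, yy, xx) - win).ravel(), p0,
                bounds=([0, y1 - 1, x1 - 1, 0.3, -np.inf],
                        [np.inf, y2, x2, fit_radius * 2.0, np.inf]))
        except ValueError:
            continue
        amp, yc, xc, sigma, _ = res.x
        if amp <= 0:
            continue
        spots.append((float(xc), float(yc), float(amp), float(sigma)))
    return spots


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def link_spots(
    detections: list,
    max_disp: float = MAX_LINK_PX,
    max_gap: int = MAX_GAP_FRAMES,
    dt: float = 0.1,
    pixel_nm: float = DEFAULT_PIXEL_NM,
) -> TrajectoryEnsemble:
    """Link per-frame detections into trajectories.

    ``detections`` is a list over frames; each element is a sequence of
    ``(x, y, ...)`` positions in pixels.  Linking is greedy mutual nearest
    neighbour against the last known position of each open track, capped at
    ``max_disp`` pixels per step.  A track unseen for up to ``max_gap`` frames
    may resume; a longer disappearance closes it and any later reappearance
    becomes a new particle.  Positions are converted to um in the output.
    """
    open_tracks = []          # dicts: id, frames, xy (px), last_frame
    closed = []
    next_id = 0
    for f, dets in enumerate(detections):
        pts = np.array([(d[0], d[1]) for d in dets], dtype=float).reshape(-1, 2)
        # retire tracks whose gap already exceeds max_gap
        still = []
        for tr in open_tracks:
            if f - tr["last_frame"] - 1 > max_gap:   # > max_gap missing frames
                closed.append(tr)
            else:
                still.append(tr)
        open_tracks = still
        if pts.shape[0] == 0:
            continue
        assigned = np.full(pts.shape[0], False)
        if open_tracks:
            last = np.array([tr["xy"][-1] for tr in open_tracks])
            dist = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            dist[dist > max_disp] = np.inf
            # mutual nearest neighbour pairs, greedy by distance
            while np.isfinite(dist).any():
                ti, pi = np.unravel_index(np.argmin(dist), dist.shape)
                if not np.isfinite(dist[ti, pi]):
                    break
                tr = open_tracks[ti]
                tr["frames"].append(f)
                tr["xy"].append(pts[pi])
                tr["last_frame"] = f
                assigned[pi] = True
                dist[ti, :] = np.inf
                dist[:, pi] = np.inf
        for pi in np.nonzero(~assigned)[0]:
            open_tracks.append({"id": next_id, "frames": [f],
                                "xy": [pts[pi]], "last_frame": f})
            next_id += 1
    closed.extend(open_tracks)
    closed.sort(key=lambda tr: tr["id"])
    um = pixel_nm / 1000.0
    trajs = [
        Trajectory(tr["id"], np.array(tr["frames"]),
                   np.array(tr["xy"]) * um, dt=dt, pixel_nm=pixel_nm)
        for tr in closed
    ]
    return TrajectoryEnsemble(trajs, dt=dt, pixel_nm=pixel_nm)


def split_on_gaps(t: Trajectory, max_gap: int = MAX_GAP_FRAMES) -> list:
    """Split a trajectory at internal gaps longer than ``max_gap`` frames.

    Mirrors the linking rule: a particle unseen for more than ``max_gap``
    consecutive frames is treated as two particles.
    """
    cuts = np.nonzero(np.diff(t.frames) > max_gap + 1)[0] + 1
    pieces = np.split(np.arange(t.frames.size), cuts)
    return [
        Trajectory(t.locus_id, t.frames[p], t.xy[p], t.dt, t.pixel_nm, t.label)
        for p in pieces if p.size > 0
    ]


# ---------------------------------------------------------------------------
# MSD and fitting
# ---------------------------------------------------------------------------

def max_lag(n_frames: int) -> int:
    """Largest lag n with n < N/10 (at least 1)."""
    return max(1, int(np.ceil(n_frames / 10.0)) - 1)


def compute_msd(t: Trajectory, min_frames: int = 20,
                include_j0: bool = False) -> MSDCurve:
    """Time-averaged MSD of one trajectory at lags n*dt, n < N/10.

    The pair origins run j = 1 .. N-1-n (frames indexed 0 .. N-1 relative to
    the trajectory start); with ``include_j0=True`` the conventional j = 0
    origin is added and the prefactor becomes N-n.  Pairs spanning a missing
    frame are skipped and the prefactor reduced to the number of pairs
    actually used.
    """
    N = t.n_frames
    if N < min_frames:
        raise ValueError("trajectory too short")
    if t.gap_exceeded:
        raise ValueError("trajectory gap exceeds the split limit; "
                         "split it into separate particles first")
    # scatter observed positions onto the full frame grid
    full = np.full((N, 2), np.nan)
    full[t.frames - t.frames[0]] = t.xy
    nmax = min(max_lag(N), N - 2)
    j0 = 0 if include_j0 else 1
    lags, msd, counts = [], [], []
    for n in range(1, nmax + 1):
        d = full[j0 + n: N] - full[j0: N - n]
        sq = np.einsum("ij,ij->i", d, d)
        ok = np.isfinite(sq)
        lags.append(n * t.dt)
        counts.append(int(ok.sum()))
        msd.append(float(sq[ok].mean()) if ok.any() else np.nan)
    return MSDCurve(np.array(lags), np.array(msd), np.array(counts), N)


def fit_power_law(c: MSDCurve, min_lags: int = 3,
                  log_space: bool = True, ensemble: bool = False,
                  confined_alpha: float = 0.1) -> DiffusionFit:
    """Least-squares fit of MSD = D t^alpha.

    By default the fit is linear regression of log MSD on log t (zero or
    missing MSD values excluded); ``log_space=False`` switches to nonlinear
    least squares in the original space, seeded by the log-space solution.
    Curves with fewer than ``min_lags`` usable lags are refused.  A fitted
    alpha below ``confined_alpha`` flags the locus as confined.
    """
    ok = np.isfinite(c.msd) & (c.msd > 0) & (c.lags > 0)
    if ok.sum() < min_lags:
        raise ValueError("fewer than %d usable lags; fit refused" % min_lags)
    lt, lm = np.log(c.lags[ok]), np.log(c.msd[ok])
    alpha, logD = np.polyfit(lt, lm, 1)
    D = float(np.exp(logD))
    resid = float(np.sqrt(np.mean((lm - (alpha * lt + logD)) ** 2)))
    if not log_space:
        def f(p):
            return p[0] * c.lags[ok] ** p[1] - c.msd[ok]
        sol = optimize.least_squares(f, [D, alpha])
        D, alpha = float(sol.x[0]), float(sol.x[1])
        pred = D * c.lags[ok] ** alpha
        resid = float(np.sqrt(np.mean((pred - c.msd[ok]) ** 2)))
    return DiffusionFit(D=float(D), alpha=float(alpha), residual=resid,
                        ensemble=ensemble, confined=bool(alpha < confined_alpha))


def ensemble_msd(e: TrajectoryEnsemble, group_by: str = "label",
                 min_trajectories: int = 3, min_frames: int = 20) -> dict:
    """Per-group ensemble-averaged MSD curves (mean +/- SE across loci).

    Trajectories are grouped by their subnuclear ``label``; at each lag the
    mean and standard error across trajectories are taken, and lags covered
    by fewer than ``min_trajectories`` trajectories are dropped.  Groups with
    fewer than 2 usable trajectories are dropped with a warning.

    Returns ``{group: (lags, mean, se, n_per_lag)}``.
    """
    groups = {}
    for tr in e:
        key = getattr(tr, group_by) if group_by != "all" else "all"
        groups.setdefault(key, []).append(tr)
    out = {}
    for key, trs in groups.items():
        curves = []
        for tr in trs:
            try:
                curves.append(compute_msd(tr, min_frames=min_frames))
            except ValueError:
                continue
        if len(curves) < 2:
            warnings.warn(f"group {key!r}: fewer than 2 usable trajectories; "
                          "dropped")
            continue
        all_lags = sorted({float(l) for c in curves for l in c.lags})
        lags, mean, se, nn = [], [], [], []
        for l in all_lags:
            vals = [c.msd[np.isclose(c.lags, l)][0]
                    for c in curves if np.isclose(c.lags, l).any()]
            vals = [v for v in vals if np.isfinite(v)]
            if len(vals) < min_trajectories:
                continue
            v = np.array(vals)
            lags.append(l)
            mean.append(v.mean())
            se.append(v.std(ddof=1) / np.sqrt(v.size))
            nn.append(v.size)
        if lags:
            out[key] = (np.array(lags), np.array(mean), np.array(se),
                        np.array(nn))
    return out
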