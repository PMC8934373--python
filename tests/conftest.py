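import numpy as np
import pytest

import chromarch as ca


@pytest.fixture
def toy_matrix():
    """Small two-chromosome raw contact matrix with known structure."""
    cfg = ca.HiCSimConfig(
        chrom_lengths={"chr1": 5_000_000, "chr2": 4_000_000},
        bin_size=500_000, c_comp=1.0, c_tad=1.0, beta=0.05,
        depth=2e5, seed=42)
    m, truth = ca.gen_contact_matrix(cfg)
    return m, truth


@pytest.fixture
def planted_lamin_track():
    cfg = ca.LaminTrackSimConfig(
        chrom_length=10_010_000, bin_size=11_000,
        domains=[(2_002_000, 3_509_000)], shift=1.0, noise_sd=0.3, seed=7)
    return ca.gen_lamin_track(cfg) + (cfg,)


@pytest.fixture
def disk_nucleus():
    cfg = ca.NucleusSimConfig(shape=(200, 200), semi_axes_px=(80, 80),
                              background=0.0, seed=1)
    image, truth = ca.gen_nucleus_image(cfg)
    return image, truth


def brute_force_msd(frames, xy, dt, include_j0=False):
    """Literal transcription of the time-averaged MSD sum.

    MSD(n dt) = 1/(N-1-n) sum_{j=1}^{N-1-n} [x(j+n)-x(j)]^2 + [y(j+n)-y(j)]^2
    with lags n < N/10; pairs spanning missing frames are skipped and the
    prefactor reduced accordingly.
    """
    frames = np.asarray(frames)
    f0 = frames[0]
    N = int(frames[-1] - f0 + 1)
    pos = {int(f - f0): p for f, p in zip(frames, xy)}
    nmax = min(max(1, int(np.ceil(N / 10.0)) - 1), N - 2)
    j_start = 0 if include_j0 else 1
    lags, msds = [], []
    for n in range(1, nmax + 1):
        total, cnt = 0.0, 0
        for j in range(j_start, N - n):
            if j in pos and (j + n) in pos:
                dx = pos[j + n][0] - pos[j][0]
                dy = pos[j + n][1] - pos[j][1]
                total += dx * dx + dy * dy
                cnt += 1
        lags.append(n * dt)
        msds.append(total / cnt if cnt else np.nan)
    return np.array(lags), np.array(msds)


def brute_force_maximal_segments(scores):
    """Maximal scoring segments by repeated best-segment extraction.

    Independent of the linear-time caller: exhaustively scan all O(n^2)
    segments for the best score (ties: shortest, then leftmost), remove it,
    and recurse on both flanks.
    """
    scores = np.asarray(scores, dtype=float)

    def best(lo, hi):
        out = None
        for i in range(lo, hi):
            acc = 0.0
            for j in range(i, hi):
                acc += scores[j]
                cand = (acc, -(j + 1 - i), -i)
                if acc > 0 and (out is None or cand > out[0]):
                    out = (cand, i, j + 1)
        return out

    def recurse(lo, hi):
        if hi <= lo:
            return []
        b = best(lo, hi)
        if b is None:
            return []
        _, i, j = b
        return recurse(lo, i) + [(i, j, float(scores[i:j].sum()))] \
            + recurse(j, hi)

    return recurse(0, len(scores))


def brute_force_ice(matrix, mask, n_iter):
    """Naive per-element ICE iteration used as an independent oracle."""
    mat = matrix.astype(float).copy()
    n = mat.shape[0]
    mat[~mask, :] = 0.0
    mat[:, ~mask] = 0.0
    for _ in range(n_iter):
        s = mat.sum(axis=1)
        mean = s[mask].mean()
        rel = np.ones(n)
        for i in range(n):
            if mask[i]:
                rel[i] = s[i] / mean
        for i in range(n):
            for j in range(n):
                mat[i, j] = mat[i, j] / (rel[i] * rel[j])
    return mat
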