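"""Hi-C contact-matrix metrics: ICE balancing, A/B compartments, insulation-score
TAD calling, and chromosome-architecture ratio statistics.

The module operates on genome-wide binned contact matrices held densely in
memory (desk-scale genomes).  Coordinates are 0-based half-open throughout;
bins are indexed per chromosome and concatenated in chromosome order.

Conventions
-----------
* A/B compartments: sign of the first principal component of the Pearson
  correlation of the per-chromosome observed/expected matrix, oriented so that
  PC1 > 0 bins have the higher mean gene density (compartment A).
* Insulation: mean contact frequency in a ``window x window`` square straddling
  each bin, normalized to the chromosome mean and log2-transformed; boundaries
  are valleys of this curve.
* TADs smaller than 200 kb are filtered out by default.
* trans-interaction ratio: per chromosome, trans contacts / (cis + trans).
* AB/(AA+BB) ratio: inter- over intra-compartment cis contacts, with pairs
  separated by less than 2 Mb excluded (they are dominated by intra-TAD
  contacts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactMatrix",
    "CompartmentTrack",
    "InsulationProfile",
    "TADSet",
    "ice_normalize",
    "depth_normalize",
    "coarsen",
    "compartment_pc1",
    "compartment_switch",
    "insulation_profile",
    "call_tads",
    "tad_score",
    "pair_boundaries",
    "trans_ratio",
    "ab_ratio",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def n_bins(length: int, bin_size: int) -> int:
    return -(-int(length) // int(bin_size))


@dataclass
class ContactMatrix:
    """Symmetric genome-wide binned contact matrix.

    Parameters
    ----------
    chroms : dict[str, int]
        Ordered mapping of chromosome name to length in bp.
    bin_size : int
        Bin width in bp; the last bin of each chromosome may be partial.
    matrix : ndarray, shape (nbins, nbins)
        Symmetric non-negative contact counts or balanced weights.
    mask : ndarray of bool, shape (nbins,)
        True for valid (analysable) bins.  Masked bins carry zero contacts.
    norm : str
        One of ``"raw"``, ``"ICE"``, ``"depth"``.
    """

    chroms: dict
    bin_size: int
    matrix: np.ndarray
    mask: np.ndarray = None
    norm: str = "raw"

    def __post_init__(self):
        total = sum(n_bins(l, self.bin_size) for l in self.chroms.values())
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (total, total):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match genome "
                f"bin count {total}"
            )
        if self.mask is None:
            self.mask = np.ones(total, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")
        if (self.matrix < 0).any():
            raise ValueError("contact matrix must be non-negative")

    # -- bin bookkeeping ---------------------------------------------------
    @property
    def chrom_names(self):
        return list(self.chroms)

    @property
    def bins_per_chrom(self):
        return {c: n_bins(l, self.bin_size) for c, l in self.chroms.items()}

    @property
    def offsets(self):
        off, pos = {}, 0
        for c, l in self.chroms.items():
            off[c] = pos
            pos += n_bins(l, self.bin_size)
        return off

    @property
    def n_total_bins(self) -> int:
        return self.matrix.shape[0]

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offsets[chrom]
        return slice(off, off + n_bins(self.chroms[chrom], self.bin_size))

    def cis(self, chrom: str) -> np.ndarray:
        s = self.chrom_slice(chrom)
        return self.matrix[s, s]

    def apply_mask(self) -> None:
        """Zero out contacts of masked bins in place."""
        bad = ~self.mask
        self.matrix[bad, :] = 0.0
        self.matrix[:, bad] = 0.0


@dataclass
class CompartmentTrack:
    """Per-bin PC1 values and A/B labels at a fixed evaluation bin size."""

    chroms: dict
    bin_size: int
    pc1: np.ndarray               # NaN on masked/skipped bins
    labels: np.ndarray            # "A" / "B" / "" per bin
    variance_explained: dict      # per chromosome
    orientation_r: dict           # per-chromosome corr(PC1, gene density)
    low_confidence: set = field(default_factory=set)

    def valid(self) -> np.ndarray:
        return ~np.isnan(self.pc1)


@dataclass
class InsulationProfile:
    """Log2 chromosome-mean-normalized insulation scores with boundary calls."""

    chroms: dict
    bin_size: int
    window: int
    scores: np.ndarray            # NaN where the window does not fit
    delta: np.ndarray
    boundaries: list              # (chrom, bin_index_in_chrom, strength)


@dataclass
class TADSet:
    """Non-overlapping domains, 0-based half-open bp coordinates."""

    intervals: list               # (chrom, start, end)
    scores: list = None           # optional per-TAD score

    def __post_init__(self):
        by_chrom = {}
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping TADs on {chrom}")

    def __len__(self):
        return len(self.intervals)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def ice_normalize(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mask_quantile: float = 0.02,
) -> tuple:
    """Iterative correction (ICE) balancing of a raw contact matrix.

    Assumes equal visibility of all loci and iteratively divides the matrix by
    outer products of relative row sums until the coefficient of variation of
    unmasked row sums drops below ``tol`` (or ``max_iter`` is reached).

    Bins whose raw coverage falls below the ``mask_quantile`` quantile of
    nonzero coverages (or is zero) are masked and excluded from balancing.

    Returns ``(balanced ContactMatrix, per-bin bias vector)``; biases of
    masked bins are NaN.
    """
    if m.norm != "raw":
        raise ValueError("ICE expects a raw count matrix")
    mat = m.matrix.copy()
    coverage = mat.sum(axis=1)
    mask = m.mask & (coverage > 0)
    nz = coverage[mask]
    if nz.size == 0:
        raise ValueError("all bins masked: matrix has no coverage")
    cutoff = np.quantile(nz, mask_quantile, method="lower")
    mask = mask & (coverage >= cutoff)
    if not mask.any():
        raise ValueError("all bins masked by the coverage filter")

    mat[~mask, :] = 0.0
    mat[:, ~mask] = 0.0
    biases = np.ones(mat.shape[0])
    for _ in range(max_iter):
        s = mat.sum(axis=1)
        sm = s[mask]
        rel = np.ones_like(s)
        rel[mask] = sm / sm.mean()
        mat /= np.outer(rel, rel)
        biases *= rel
        sm = mat.sum(axis=1)[mask]
        cv = sm.std() / sm.mean()
        if cv <= tol:
            break
    biases_out = np.where(mask, biases, np.nan)
    out = ContactMatrix(dict(m.chroms), m.bin_size, mat, mask, norm="ICE")
    return out, biases_out


def depth_normalize(m: ContactMatrix) -> ContactMatrix:
    """Scale the matrix by the total number of valid interactions.

    The total is the sum over the upper triangle (diagonal included) of
    unmasked bins; after scaling, that total equals 1, making matrices from
    samples of different sequencing depth directly comparable.
    """
    mat = m.matrix.copy()
    mat[~m.mask, :] = 0.0
    mat[:, ~m.mask] = 0.0
    total = np.triu(mat).sum()
    if total <= 0:
        raise ValueError("empty contact matrix: nothing to normalize")
    return ContactMatrix(dict(m.chroms), m.bin_size, mat / total, m.mask.copy(),
                         norm="depth")


def coarsen(m: ContactMatrix, new_bin_size: int) -> ContactMatrix:
    """Aggregate a matrix to a coarser bin size (per-chromosome block sums)."""
    if new_bin_size % m.bin_size != 0:
        raise ValueError("new bin size must be a multiple of the current one")
    f = new_bin_size // m.bin_size
    if f == 1:
        return m
    # per-chromosome fine-bin -> coarse-bin assignment
    fine2coarse = np.empty(m.n_total_bins, dtype=int)
    pos = 0
    for c, l in m.chroms.items():
        nf = n_bins(l, m.bin_size)
        nc = n_bins(l, new_bin_size)
        fine2coarse[m.offsets[c]:m.offsets[c] + nf] = pos + np.arange(nf) // f
        pos += nc
    ncoarse = pos
    agg = np.zeros((ncoarse, m.n_total_bins))
    np.add.at(agg, fine2coarse, m.matrix)
    out = np.zeros((ncoarse, ncoarse))
    np.add.at(out.T, fine2coarse, agg.T)
    # a coarse bin is valid if any constituent fine bin is valid
    mask = np.zeros(ncoarse, dtype=bool)
    np.logical_or.at(mask, fine2coarse, m.mask)
    return ContactMatrix(dict(m.chroms), new_bin_size, out, mask, norm=m.norm)


# ---------------------------------------------------------------------------
# A/B compartments
# ---------------------------------------------------------------------------

def _observed_over_expected(cis: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """O/E matrix using the per-diagonal mean over valid bin pairs."""
    n = cis.shape[0]
    oe = np.zeros_like(cis)
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    vv = np.outer(valid, valid)
    for d in range(n):
        sel = (dist == d) & vv
        if not sel.any():
            continue
        mu = cis[sel].mean()
        if mu > 0:
            oe[sel] = cis[sel] / mu
    return oe


def compartment_pc1(
    m: ContactMatrix,
    gene_density,
    bin_size_eval: int = 500_000,
    use_oe: bool = True,
    min_valid_bins: int = 10,
) -> CompartmentTrack:
    """A/B compartment calling from the first principal component.

    Per chromosome: the cis matrix (coarsened to ``bin_size_eval``) is turned
    into an observed/expected matrix (per-distance means), then into a Pearson
    correlation matrix, whose first principal component is extracted.  The sign
    is chosen so that the mean gene density of PC1 > 0 bins exceeds that of
    PC1 < 0 bins; PC1 > 0 bins are labeled A, PC1 < 0 labeled B.

    ``gene_density`` is a :class:`~chromarch.lad_domains.GenomicTrack` binned
    at (or refinable to) ``bin_size_eval``.

    Chromosomes with fewer than ``min_valid_bins`` valid bins are skipped with
    a warning; their PC1 is NaN.  Chromosomes where PC1 explains barely more
    variance than a null are flagged low-confidence.
    """
    mc = coarsen(m, bin_size_eval) if m.bin_size != bin_size_eval else m
    gd = gene_density.rebin(bin_size_eval)
    ntot = mc.n_total_bins
    pc1 = np.full(ntot, np.nan)
    labels = np.array([""] * ntot, dtype=object)
    varexp, orient_r, lowconf = {}, {}, set()

    for chrom in mc.chrom_names:
        s = mc.chrom_slice(chrom)
        cis = mc.matrix[s, s]
        valid = mc.mask[s] & (cis.sum(axis=1) > 0)
        if valid.sum() < min_valid_bins:
            warnings.warn(f"{chrom}: fewer than {min_valid_bins} valid bins; "
                          "compartments skipped")
            continue
        work = _observed_over_expected(cis, valid) if use_oe else cis
        sub = work[np.ix_(valid, valid)]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr)
        # PCA of the correlation matrix: leading eigenvector of its
        # column-centered covariance
        centered = corr - corr.mean(axis=0, keepdims=True)
        cov = centered.T @ centered
        evals, evecs = np.linalg.eigh(cov)
        v = evecs[:, -1]
        ve = float(evals[-1] / evals.sum()) if evals.sum() > 0 else 0.0
        varexp[chrom] = ve
        vec = np.full(valid.size, np.nan)
        vec[valid] = v

        dens = gd.values_for(chrom)[: valid.size]
        dmask = np.isfinite(dens) & valid
        hi = dens[dmask & (vec > 0)]
        lo = dens[dmask & (vec < 0)]
        if hi.size and lo.size and hi.mean() < lo.mean():
            vec = -vec
        r = np.nan
        if dmask.sum() > 2 and np.nanstd(vec[dmask]) > 0 and dens[dmask].std() > 0:
            r = float(np.corrcoef(vec[dmask], dens[dmask])[0, 1])
        orient_r[chrom] = r
        if ve < 2.0 / max(valid.sum(), 1):
            lowconf.add(chrom)

        pc1[s] = vec
        lab = np.where(vec > 0, "A", np.where(vec < 0, "B", ""))
        lab[~np.isfinite(vec)] = ""
        labels[s] = lab

    return CompartmentTrack(dict(mc.chroms), bin_size_eval, pc1, labels,
                            varexp, orient_r, lowconf)


def compartment_switch(a: CompartmentTrack, b: CompartmentTrack) -> dict:
    """Fractions of bins switching compartment between two tracks.

    Returns ``{"A_to_B": f1, "B_to_A": f2, "stable": f3}`` over bins valid in
    both tracks; the three fractions sum to 1.
    """
    if a.bin_size != b.bin_size or a.pc1.size != b.pc1.size:
        raise ValueError("tracks must share binning")
    both = a.valid() & b.valid()
    n = both.sum()
    if n == 0:
        raise ValueError("no bins valid in both tracks")
    la, lb = a.labels[both], b.labels[both]
    ab = np.sum((la == "A") & (lb == "B")) / n
    ba = np.sum((la == "B") & (lb == "A")) / n
    return {"A_to_B": float(ab), "B_to_A": float(ba),
            "stable": float(1.0 - ab - ba)}


# ---------------------------------------------------------------------------
# Insulation and TADs
# ---------------------------------------------------------------------------

def insulation_profile(
    m: ContactMatrix,
    window: int = 500_000,
    delta_span: int = 100_000,
) -> InsulationProfile:
    """Sliding-square insulation score and boundary candidates.

    For bin ``i`` the score is the mean contact in the ``w x w`` square with
    upstream bins ``[i-w, i)`` against downstream bins ``(i, i+w]`` (the
    diagonal is excluded by construction).  Scores are divided by their
    chromosome mean and log2-transformed.  The delta vector at bin ``i`` is
    the mean score over the ``delta_span`` to the right minus the left; an
    upward zero crossing of delta marks an insulation valley.  Boundary
    strength is the delta swing across the crossing.
    """
    w = window // m.bin_size        # window floored to whole bins
    if w < 1:
        raise ValueError("window smaller than one bin")
    ds = max(1, delta_span // m.bin_size)
    ntot = m.n_total_bins
    scores = np.full(ntot, np.nan)
    delta = np.full(ntot, np.nan)
    boundaries = []

    for chrom in m.chrom_names:
        s = m.chrom_slice(chrom)
        cis = m.matrix[s, s]
        n = cis.shape[0]
        if n <= 2 * w:
            warnings.warn(f"{chrom}: window larger than chromosome; skipped")
            continue
        raw = np.full(n, np.nan)
        for i in range(w, n - w):
            raw[i] = cis[i - w:i, i + 1:i + 1 + w].mean()
        ok = np.isfinite(raw) & (raw > 0) & m.mask[s][: n]
        if ok.sum() == 0:
            continue
        mu = raw[ok].mean()
        sc = np.full(n, np.nan)
        sc[ok] = np.log2(raw[ok] / mu)
        scores[s] = sc

        dl = np.full(n, np.nan)
        for i in range(n):
            right = sc[i + 1:i + 1 + ds]
            left = sc[max(0, i - ds):i]
            if np.isfinite(right).any() and np.isfinite(left).any():
                dl[i] = np.nanmean(right) - np.nanmean(left)
        delta[s] = dl

        for i in range(n - 1):
            if not (np.isfinite(dl[i]) and np.isfinite(dl[i + 1])):
                continue
            if dl[i] < 0 <= dl[i + 1]:
                lo = np.nanmin(dl[max(0, i - ds):i + 1])
                hi = np.nanmax(dl[i + 1:i + 1 + ds])
                strength = float(hi - lo)
                # boundary at the local score minimum nearest the crossing
                j = i if (np.isfinite(sc[i]) and
                          (not np.isfinite(sc[i + 1]) or sc[i] <= sc[i + 1])) \
                    else i + 1
                boundaries.append((chrom, int(j), strength))

    return InsulationProfile(dict(m.chroms), m.bin_size, window, scores,
                             delta, boundaries)


def call_tads(
    p: InsulationProfile,
    min_size: int = 200_000,
    strength_min: float = 0.1,
) -> TADSet:
    """Segment chromosomes into TADs at strong insulation valleys.

    Boundaries weaker than ``strength_min`` are discarded; consecutive
    boundaries (with chromosome ends as implicit boundaries) delimit TADs;
    TADs shorter than ``min_size`` (200 kb by default) are filtered out.
    A chromosome with no retained boundary yields one TAD spanning it.
    """
    by_chrom = {}
    for chrom, idx, strength in p.boundaries:
        if strength >= strength_min:
            by_chrom.setdefault(chrom, []).append(idx)
    intervals = []
    for chrom, length in p.chroms.items():
        cuts = sorted(set(by_chrom.get(chrom, [])))
        edges_bp = [0] + [(c + 1) * p.bin_size for c in cuts] + [length]
        for a, b in zip(edges_bp, edges_bp[1:]):
            if b - a >= min_size and b > a:
                intervals.append((chrom, int(a), int(b)))
    return TADSet(intervals)


def tad_score(m: ContactMatrix, tads: TADSet) -> np.ndarray:
    """Per-TAD ratio of intra-TAD contacts to total cis contacts of its
    chromosome.

    Both contact ends must fall inside the TAD; the denominator is the total
    cis contact sum of the chromosome (upper triangle, diagonal counted once).
    Scores lie in [0, 1] and, for disjoint TADs of one chromosome, sum to <= 1.
    """
    chrom_tot = {}
    for chrom in m.chrom_names:
        cis = m.cis(chrom)
        chrom_tot[chrom] = np.triu(cis).sum()
    out = []
    for chrom, start, end in tads.intervals:
        s = m.chrom_slice(chrom)
        cis = m.matrix[s, s]
        b0 = start // m.bin_size
        b1 = n_bins(end, m.bin_size)
        sub = cis[b0:b1, b0:b1]
        tot = chrom_tot[chrom]
        out.append(np.triu(sub).sum() / tot if tot > 0 else np.nan)
    return np.asarray(out)


def pair_boundaries(a: TADSet, b: TADSet, bin_size: int, k: int = 1) -> dict:
    """Distance from each boundary of ``a`` to its nearest boundary in ``b``.

    Boundaries are the internal edges between consecutive TADs (interval start
    and end points).  Equidistant neighbours resolve to the leftmost.  Returns
    the distance list (bp) plus the fractions at distance <= ``k`` bins and
    strictly < 2 bins.
    """
    def edges(ts):
        by = {}
        for chrom, start, end in ts.intervals:
            by.setdefault(chrom, set()).update((start, end))
        return {c: np.array(sorted(v)) for c, v in by.items()}

    ea, eb = edges(a), edges(b)
    dists = []
    for chrom, pts in ea.items():
        if chrom not in eb or eb[chrom].size == 0:
            continue
        other = eb[chrom]
        for p in pts:
            d = np.abs(other - p)
            j = int(np.argmin(d))          # argmin takes the leftmost tie
            dists.append(int(d[j]))
    dists = np.array(dists, dtype=float)
    if dists.size == 0:
        return {"distances": dists, "frac_within_k_bins": np.nan,
                "frac_within_2_bins": np.nan}
    return {
        "distances": dists,
        "frac_within_k_bins": float(np.mean(dists <= k * bin_size)),
        "frac_within_2_bins": float(np.mean(dists < 2 * bin_size)),
    }


# ---------------------------------------------------------------------------
# Ratio statistics
# ---------------------------------------------------------------------------

def trans_ratio(m: ContactMatrix) -> dict:
    """Per-chromosome fraction of trans contacts in its total contacts.

    cis = both bins on the chromosome (diagonal counted once); trans = one bin
    on the chromosome, the other elsewhere.  Each ratio lies in [0, 1].
    """
    out = {}
    for chrom in m.chrom_names:
        s = m.chrom_slice(chrom)
        cis = np.triu(m.matrix[s, s]).sum()
        row_tot = m.matrix[s, :].sum()
        trans = row_tot - m.matrix[s, s].sum()
        denom = cis + trans
        out[chrom] = float(trans / denom) if denom > 0 else np.nan
    return out


def ab_ratio(
    m: ContactMatrix,
    c: CompartmentTrack,
    exclusion: int = 2_000_000,
    exclude_chroms: tuple = (),
) -> dict:
    """Per-chromosome AB / (AA + BB) cis contact ratio.

    Only cis pairs separated by at least ``exclusion`` bp enter either sum
    (closer pairs are dominated by intra-TAD contacts).  Chromosomes listed in
    ``exclude_chroms`` (e.g. the X chromosome) are omitted from the output.
    """
    if c.bin_size != m.bin_size:
        raise ValueError("compartment track binning must match the matrix")
    excl_bins = exclusion // m.bin_size
    out = {}
    for chrom in m.chrom_names:
        if chrom in exclude_chroms:
            continue
        s = m.chrom_slice(chrom)
        cis = m.matrix[s, s]
        lab = c.labels[s]
        n = cis.shape[0]
        idx = np.arange(n)
        far = np.abs(idx[:, None] - idx[None, :]) * m.bin_size >= exclusion
        has = (lab == "A") | (lab == "B")
        pair_ok = np.triu(far, k=max(1, excl_bins)) & np.outer(has, has)
        same = np.equal.outer(lab, lab)
        inter = cis[pair_ok & ~same].sum()
        intra = cis[pair_ok & same].sum()
        out[chrom] = float(inter / intra) if intra > 0 else np.nan
    return out
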