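"""Lamina-associated-domain (LAD) calling and classification.

LADs are broad regions of enrichment in lamin ChIP/input log-ratio tracks.
The caller scores each bin +1 (enriched, above a robust center) or
``-gap_penalty`` (depleted) and reports maximal-scoring segments, a
simplification of the enriched-domain-detector approach that keeps its
broad-domain character fully testable (11-kb bins and gap penalty 5 by
default).  A 4-way classification against reference LAD sets of several cell
types distinguishes constitutive LADs (cLAD: in all sets), constitutive
inter-LADs (ciLAD: in none), facultative LADs (fLAD: query cell type only)
and facultative inter-LADs (fiLAD: absent from the query but present in at
least one other).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GenomicTrack",
    "DomainSet",
    "call_lads",
    "maximal_scoring_segments",
    "lad_stats",
    "classify_lads",
    "mean_signal_by_class",
    "jaccard",
]

LAD_CLASSES = ("cLAD", "ciLAD", "fLAD", "fiLAD", "other")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomicTrack:
    """Per-bin genomic signal (log2 ChIP/input, PC1, gene density, ...).

    ``values`` is a dict chromosome -> 1-D array tiling the chromosome at
    ``bin_size`` (last bin may be partial).  Masked bins are NaN.
    """

    chroms: dict
    bin_size: int
    values: dict

    def __post_init__(self):
        for chrom, length in self.chroms.items():
            need = -(-int(length) // int(self.bin_size))
            v = np.asarray(self.values[chrom], dtype=float)
            if v.size != need:
                raise ValueError(
                    f"{chrom}: {v.size} bins given, {need} expected")
            self.values[chrom] = v

    def values_for(self, chrom: str) -> np.ndarray:
        return self.values[chrom]

    def concat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.chroms])

    def rebin(self, new_bin_size: int) -> "GenomicTrack":
        """Average values into coarser bins (NaN-aware)."""
        if new_bin_size == self.bin_size:
            return self
        if new_bin_size % self.bin_size != 0:
            raise ValueError("new bin size must be a multiple of current")
        f = new_bin_size // self.bin_size
        out = {}
        for chrom, v in self.values.items():
            nc = -(-v.size // f)
            pad = np.full(nc * f, np.nan)
            pad[: v.size] = v
            with np.errstate(invalid="ignore"):
                out[chrom] = np.nanmean(pad.reshape(nc, f), axis=1)
        return GenomicTrack(dict(self.chroms), new_bin_size, out)


@dataclass
class DomainSet:
    """Sorted non-overlapping intervals (0-based half-open bp) with optional
    scores and class labels."""

    intervals: list                       # (chrom, start, end)
    scores: list = None
    labels: list = None                   # class label per interval

    def __post_init__(self):
        order = sorted(range(len(self.intervals)),
                       key=lambda i: (self.intervals[i][0],
                                      self.intervals[i][1]))
        self.intervals = [self.intervals[i] for i in order]
        if self.scores is not None:
            self.scores = [self.scores[i] for i in order]
        if self.labels is not None:
            self.labels = [self.labels[i] for i in order]
        prev = {}
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            if chrom in prev and start < prev[chrom]:
                raise ValueError(f"overlapping domains on {chrom}")
            prev[chrom] = end

    def __len__(self):
        return len(self.intervals)

    def lengths(self) -> np.ndarray:
        return np.array([e - s for _, s, e in self.intervals], dtype=float)

    def covers(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e
                   for c, s, e in self.intervals)


# ---------------------------------------------------------------------------
# Maximal-scoring-segment machinery
# ---------------------------------------------------------------------------

def maximal_scoring_segments(scores: np.ndarray) -> list:
    """All maximal scoring segments of a real-valued sequence (Ruzzo–Tompa).

    Returns ``[(start, end, score), ...]`` (half-open, ascending), the unique
    disjoint set of positive-scoring segments that cannot be lengthened or
    shortened without lowering their score, equivalently the result of
    repeatedly extracting the best-scoring segment.
    """
    # stack entries: [start, end, L, R] with L/R cumulative scores just before
    # start / at end
    cum = 0.0
    stack = []
    for i, x in enumerate(np.asarray(scores, dtype=float)):
        cum_prev = cum
        cum += x
        if x <= 0:
            continue
        seg = [i, i + 1, cum_prev, cum]
        while True:
            # rightmost j with L_j < L_new (searched from the top)
            j = len(stack) - 1
            while j >= 0 and stack[j][2] >= seg[2]:
                j -= 1
            if j < 0 or stack[j][3] >= seg[3]:
                stack.append(seg)
                break
            # extend the new segment left over I_j..top and retry
            seg = [stack[j][0], seg[1], stack[j][2], seg[3]]
            del stack[j:]
    return [(int(s), int(e), float(r - l)) for s, e, l, r in stack]


def call_lads(
    t: GenomicTrack,
    bin_size: int = 11_000,
    gap_penalty: float = 5.0,
    threshold: str = "median",
    min_bins: int = 10,
) -> DomainSet:
    """Call broad enriched domains (LADs) on a log-ratio track.

    The track is re-binned to ``bin_size``; each unmasked bin scores +1 if its
    value exceeds the enrichment threshold (the track median by default, or a
    fixed 0 with ``threshold="zero"``) and ``-gap_penalty`` otherwise.
    Maximal-scoring segments of this score sequence are the domains; adjacent
    domains separated only by masked (NaN) bins are merged, and domains
    shorter than ``min_bins`` bins are dropped (broad-domain character).

    An all-depleted track yields an empty :class:`DomainSet`.
    """
    tt = t.rebin(bin_size) if bin_size != t.bin_size else t
    intervals, seg_scores = [], []
    for chrom in tt.chroms:
        v = tt.values_for(chrom)
        if v.size < 2:
            raise ValueError(f"{chrom}: track shorter than 2 bins")
        finite = np.isfinite(v)
        if not finite.any():
            continue
        center = (np.median(v[finite]) if threshold == "median" else 0.0)
        sc = np.where(v > center, 1.0, -float(gap_penalty))
        sc[~finite] = 0.0                    # masked bins are score-neutral
        segs = maximal_scoring_segments(sc)
        # merge segments separated only by masked bins
        merged = []
        for s, e, r in segs:
            if merged and np.all(~finite[merged[-1][1]: s]):
                ps, pe, pr = merged[-1]
                merged[-1] = (ps, e, pr + r)
            else:
                merged.append((s, e, r))
        for s, e, r in merged:
            if e - s >= min_bins:
                intervals.append((chrom, int(s * bin_size),
                                  int(min(e * bin_size, tt.chroms[chrom]))))
                seg_scores.append(r)
    return DomainSet(intervals, scores=seg_scores)


# ---------------------------------------------------------------------------
# Statistics and classification
# ---------------------------------------------------------------------------

def lad_stats(d: DomainSet, genome_size: int) -> dict:
    """Domain count, median length (bp) and genome coverage fraction."""
    lengths = d.lengths()
    return {
        "count": len(d),
        "median_length": float(np.median(lengths)) if len(d) else float("nan"),
        "coverage": float(lengths.sum() / genome_size),
    }


def classify_lads(
    reference_sets: list,
    chroms: dict,
    bin_size: int,
    query_cell_index: int = 0,
) -> GenomicTrack:
    """Partition the genome into LAD classes from several cell types' LAD sets.

    Each bin is labeled by membership across the reference sets: in all ->
    cLAD; in none -> ciLAD; in the query set only -> fLAD; absent from the
    query but present in >= 1 other -> fiLAD.  Bins in the query set and in
    some but not all of the others fit none of those definitions and go into
    an explicit "other" bucket rather than being silently folded in.

    Returns a :class:`GenomicTrack` whose values are indices into
    :data:`LAD_CLASSES`; the partition is exhaustive and mutually exclusive.
    """
    nsets = len(reference_sets)
    if not 0 <= query_cell_index < nsets:
        raise ValueError("query_cell_index out of range")
    values = {}
    for chrom, length in chroms.items():
        nb = -(-int(length) // int(bin_size))
        member = np.zeros((nsets, nb), dtype=bool)
        for k, ds in enumerate(reference_sets):
            for c, s, e in ds.intervals:
                if c != chrom:
                    continue
                b0 = s // bin_size
                b1 = -(-e // bin_size)
                member[k, b0:b1] = True
        total = member.sum(axis=0)
        in_q = member[query_cell_index]
        lab = np.full(nb, LAD_CLASSES.index("other"), dtype=float)
        lab[total == nsets] = LAD_CLASSES.index("cLAD")
        lab[total == 0] = LAD_CLASSES.index("ciLAD")
        lab[in_q & (total == 1)] = LAD_CLASSES.index("fLAD")
        lab[~in_q & (total >= 1)] = LAD_CLASSES.index("fiLAD")
        values[chrom] = lab
    return GenomicTrack(dict(chroms), bin_size, values)


def mean_signal_by_class(t: GenomicTrack, classes: GenomicTrack,
                         other: GenomicTrack = None) -> dict:
    """Per-class mean +/- SD of a track over a LAD-class partition.

    If a second track ``other`` is supplied, a Welch two-sample t statistic
    and p-value comparing the two tracks within each class is included.
    Empty classes report NaN means and are excluded from tests.
    """
    if classes.bin_size != t.bin_size:
        t = t.rebin(classes.bin_size)
        if other is not None:
            other = other.rebin(classes.bin_size)
    lab = classes.concat()
    v = t.concat()
    out = {}
    for ci, cname in enumerate(LAD_CLASSES):
        sel = (lab == ci) & np.isfinite(v)
        entry = {"n": int(sel.sum())}
        if sel.any():
            entry["mean"] = float(v[sel].mean())
            entry["sd"] = float(v[sel].std(ddof=1)) if sel.sum() > 1 else 0.0
        else:
            entry["mean"] = float("nan")
            entry["sd"] = float("nan")
        if other is not None:
            w = other.concat()
            sel2 = (lab == ci) & np.isfinite(w)
            if sel.sum() > 1 and sel2.sum() > 1:
                tstat, p = stats.ttest_ind(v[sel], w[sel2], equal_var=False)
                entry["welch_t"] = float(tstat)
                entry["welch_p"] = float(p)
        out[cname] = entry
    return out


def jaccard(a: DomainSet, b: DomainSet, chroms: dict) -> float:
    """Base-pair Jaccard index between two interval sets."""
    inter = union = 0
    for chrom, length in chroms.items():
        cov_a = np.zeros(int(length), dtype=bool)
        cov_b = np.zeros(int(length), dtype=bool)
        for c, s, e in a.intervals:
            if c == chrom:
                cov_a[s:e] = True
        for c, s, e in b.intervals:
            if c == chrom:
                cov_b[s:e] = True
        inter += int((cov_a & cov_b).sum())
        union += int((cov_a | cov_b).sum())
    return inter / union if union else float("nan")
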