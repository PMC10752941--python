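"""Sliding-window detection of runs of homozygosity (ROH) and F_ROH.

The scanner reproduces the classic PLINK ``--homozyg`` dialect. Per animal
and chromosome:

1. a window of ``window_snps`` consecutive SNPs slides one SNP at a time; a
   window is *homozygous* when it contains at most ``window_het_max``
   heterozygous and at most ``window_missing_max`` missing calls;
2. each SNP receives the fraction of the windows overlapping it that are
   homozygous, using the actual number of overlapping windows (SNPs near a
   chromosome end are covered by fewer windows, and chromosomes shorter
   than one window yield no window at all, hence no run);
3. maximal stretches of SNPs whose fraction is >= ``window_hit_threshold``
   become candidate segments; a candidate is split wherever two adjacent
   in-run SNPs lie more than ``max_gap_kb`` apart;
4. candidates are kept when they span >= ``min_len_kb``, contain
   >= ``min_snps`` SNPs and have average density <= ``max_kb_per_snp``
   (boundary equality passes everywhere).

Segment coordinates are the bp positions of the first and last in-run SNP;
``length_kb = (end - start) / 1000``. There is no per-segment limit on
heterozygotes — hets enter only through the window rule.

``f_roh`` is the McQuillan genome fraction: the summed segment length of an
animal divided by the total autosomal length covered by the marker set
(per chromosome, last SNP bp minus first SNP bp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix
from .grm import adjust_to_reference

__all__ = ["ROHParams", "detect_roh", "f_roh", "f_roh0"]


@dataclass(frozen=True)
class ROHParams:
    """Scanner parameters; defaults follow the mouse high-density-array setup."""

    window_snps: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    window_hit_threshold: float = 0.5
    min_len_kb: float = 1000.0
    min_snps: int = 100
    max_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0

    def __post_init__(self):
        if min(self.window_snps, self.min_snps) <= 0:
            raise ValueError("window_snps and min_snps must be positive")
        if not (0.0 < self.window_hit_threshold <= 1.0):
            raise ValueError("window_hit_threshold must be in (0, 1]")
        if min(self.min_len_kb, self.max_kb_per_snp, self.max_gap_kb) <= 0:
            raise ValueError("length/density/gap parameters must be positive")


def _moving_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def _in_run_snps(codes_row: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean in-run status per SNP for one animal on one chromosome."""
    n = codes_row.shape[0]
    w = params.window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (codes_row == 1).astype(np.int64)
    miss = (codes_row < 0).astype(np.int64)
    homwin = (_moving_sum(het, w) <= params.window_het_max) & (
        _moving_sum(miss, w) <= params.window_missing_max
    )
    # windows overlapping SNP k start in [max(0, k-w+1), min(k, n-w)]
    k = np.arange(n)
    lo = np.maximum(0, k - w + 1)
    hi = np.minimum(k, n - w)
    csum = np.concatenate([[0], np.cumsum(homwin)])
    hits = csum[hi + 1] - csum[lo]
    cnt = hi - lo + 1
    return hits / cnt >= params.window_hit_threshold


def _segments_from_runs(
    inrun: np.ndarray, bp: np.ndarray, params: ROHParams
) -> list[tuple[int, int]]:
    """Maximal in-run index intervals, gap-split and filtered. Returns
    (start_idx, end_idx) inclusive pairs."""
    out: list[tuple[int, int]] = []
    idx = np.flatnonzero(inrun)
    if idx.size == 0:
        return out
    # break runs at non-consecutive indices or bp gaps beyond the limit
    brk = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(bp[idx]) > params.max_gap_kb * 1000.0)
    )
    starts = np.concatenate([[0], brk + 1])
    ends = np.concatenate([brk, [idx.size - 1]])
    for s, e in zip(starts, ends):
        i0, i1 = int(idx[s]), int(idx[e])
        n_snps = i1 - i0 + 1
        length_kb = (bp[i1] - bp[i0]) / 1000.0
        if n_snps < params.min_snps or length_kb < params.min_len_kb:
            continue
        if length_kb / n_snps > params.max_kb_per_snp:
            continue
        out.append((i0, i1))
    return out


def detect_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Scan every animal for ROH segments.

    Expects the ROH marker set (autosomal, missingness-filtered, **no** MAF
    filter) with positions sorted within chromosome. Deterministic and
    independent of animal ordering.

    Returns a frame with columns ``animal_id, chrom, start_bp, end_bp,
    n_snps, length_kb``, one row per segment.
    """
    params = params or ROHParams()
    chrom_arr = g.markers["chrom"].to_numpy()
    bp_all = g.markers["bp"].to_numpy(np.int64)
    chrom_slices = []
    for ch in pd.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == ch)
        chrom_slices.append((ch, cols, bp_all[cols]))
    rows = []
    for i, animal in enumerate(g.samples):
        for ch, cols, bp in chrom_slices:
            inrun = _in_run_snps(g.codes[i, cols], params)
            for i0, i1 in _segments_from_runs(inrun, bp, params):
                rows.append(
                    (animal, ch, int(bp[i0]), int(bp[i1]), i1 - i0 + 1,
                     (bp[i1] - bp[i0]) / 1000.0)
                )
    return pd.DataFrame(
        rows, columns=["animal_id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"]
    )


def autosome_length_kb(markers: pd.DataFrame) -> float:
    """Total map length: sum over chromosomes of (last - first SNP bp), in kb."""
    spans = markers.groupby("chrom", sort=False)["bp"].agg(lambda s: s.max() - s.min())
    return float(spans.sum()) / 1000.0


def f_roh(segments: pd.DataFrame, g_or_markers) -> pd.Series:
    """McQuillan F_ROH per animal: summed ROH length over autosomal map length.

    ``g_or_markers`` is the ROH-set :class:`GenotypeMatrix` (all its animals
    get a value; animals without segments get 0) or a marker map frame (then
    only animals present in ``segments`` are returned).
    """
    if isinstance(g_or_markers, GenotypeMatrix):
        markers = g_or_markers.markers
        index = g_or_markers.samples
    else:
        markers = g_or_markers
        index = pd.Index(pd.unique(segments["animal_id"]), name="id")
    total = autosome_length_kb(markers)
    summed = segments.groupby("animal_id")["length_kb"].sum().astype(float)
    out = summed.reindex(index).fillna(0.0).astype(float) / total
    out.name = "F_ROH"
    out.index.name = "id"
    return out


def f_roh0(froh: pd.Series, ref_mean: float) -> pd.Series:
    """Reference-generation-adjusted F_ROH (delegates to the 0-adjustment)."""
    return adjust_to_reference(froh, ref_mean, name="F_ROH0")
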