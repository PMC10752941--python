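"""Inbreeding coefficients from genomic-relationship-matrix diagonals.

Five marker-by-marker estimators of individual inbreeding, all functions of
the reference-allele count ``x`` in {0,1,2} and (for the frequency-dependent
ones) the reference-population allele frequency ``p`` per SNP:

* ``F_NEJ``  — observed homozygosity: fraction of non-missing SNPs where the
  individual is homozygous (diagonal of the allelic relationship matrix).
* ``F_L&H`` — excess homozygosity over Hardy–Weinberg expectation in the
  reference population: ``(Hobs - Hexp) / (1 - Hexp)``.
* ``F_VR1`` — VanRaden method-1 diagonal:
  ``sum_j (x - 2p)^2 / (2 sum_j p(1-p)) - 1``.
* ``F_VR2`` — VanRaden method-2 diagonal: per-SNP standardised squared
  deviation, ``mean_j (x - 2p)^2 / (2p(1-p)) - 1``.
* ``F_YAN`` — Yang diagonal:
  ``mean_j (x^2 - (1+2p) x + 2p^2) / (2p(1-p))``.

Per-individual sums and means run only over that individual's non-missing
SNPs (no imputation); SNPs fixed in the reference population (p = 0 or 1)
are excluded from VR2/YAN sums with a logged count, since drift after the
reference generation can fix SNPs that passed the MAF filter there.

``adjust_to_reference`` rescales any coefficient by the mean of a reference
cohort, ``F0 = (F - m) / (1 - m)``, which forces the reference-cohort mean
of F0 to zero; it produces the 0-adjusted variants F_NEJ0, F_L&H0, F_ROH0.

``expected_homozygosity`` gives the per-cohort genome-average expected
homozygosity ``F_EXP = mean_j [1 - 2 p_j (1 - p_j)]`` with frequencies
computed within the cohort (the per-SNP transform is averaged across SNPs,
not applied to an averaged p).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, _freq

__all__ = [
    "f_nej",
    "f_lh",
    "f_vr1",
    "f_vr2",
    "f_yan",
    "adjust_to_reference",
    "expected_homozygosity",
    "inbreeding_table",
]

logger = logging.getLogger(__name__)


def _codes_and_mask(g: GenotypeMatrix):
    codes = g.codes.astype(np.float64)
    ok = g.codes >= 0
    codes[~ok] = np.nan
    return codes, ok


def _p_array(g: GenotypeMatrix, freqs: pd.Series) -> np.ndarray:
    p = freqs.reindex(g.markers.index).to_numpy(dtype=float)
    if np.isnan(p).all():
        raise ValueError("no usable allele frequencies for this marker set")
    return p


def f_nej(g: GenotypeMatrix) -> pd.Series:
    """Observed homozygosity per individual (F_NEJ), in [0, 1]."""
    ok = g.codes >= 0
    n = ok.sum(axis=1).astype(float)
    hom = ((g.codes == 0) | (g.codes == 2)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = hom / np.where(n == 0, np.nan, n)
    if (n == 0).any():
        warnings.warn("individual(s) with zero non-missing SNPs; F_NEJ set to NaN")
    return pd.Series(out, index=g.samples, name="F_NEJ")


def f_lh(g: GenotypeMatrix, freqs: pd.Series) -> pd.Series:
    """Li & Horvitz excess homozygosity relative to the reference population.

    For individual i, ``Hexp_i`` is the mean of ``1 - 2p(1-p)`` over the SNPs
    that are non-missing in i, and ``F = (Hobs_i - Hexp_i) / (1 - Hexp_i)``.
    """
    p = _p_array(g, freqs)
    ok = (g.codes >= 0) & ~np.isnan(p)[None, :]
    n = ok.sum(axis=1).astype(float)
    hexp_snp = 1.0 - 2.0 * p * (1.0 - p)
    with np.errstate(invalid="ignore"):
        hexp = np.where(ok, hexp_snp[None, :], 0.0).sum(axis=1) / np.where(n == 0, np.nan, n)
        hobs = ((g.codes == 0) | (g.codes == 2)).astype(float)
        hobs = np.where(ok, hobs, 0.0).sum(axis=1) / np.where(n == 0, np.nan, n)
        out = np.where(hexp < 1.0, (hobs - hexp) / (1.0 - hexp), np.nan)
    return pd.Series(out, index=g.samples, name="F_LH")


def f_vr1(g: GenotypeMatrix, freqs: pd.Series) -> pd.Series:
    """VanRaden method-1 diagonal minus one."""
    p = _p_array(g, freqs)
    codes, ok = _codes_and_mask(g)
    ok = ok & ~np.isnan(p)[None, :]
    dev2 = np.where(ok, (np.nan_to_num(codes) - 2.0 * p[None, :]) ** 2, 0.0)
    den = 2.0 * np.where(ok, (p * (1.0 - p))[None, :], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = dev2.sum(axis=1) / np.where(den == 0, np.nan, den) - 1.0
    return pd.Series(out, index=g.samples, name="F_VR1")


def _per_snp_ratio(g: GenotypeMatrix, freqs: pd.Series, numerator) -> pd.Series:
    p = _p_array(g, freqs)
    usable = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    n_fixed = int((~np.isnan(p) & ~usable).sum())
    if n_fixed:
        logger.info("%d SNP(s) fixed in reference population excluded from sum", n_fixed)
    codes, ok = _codes_and_mask(g)
    ok = ok & usable[None, :]
    den_snp = np.where(usable, 2.0 * p * (1.0 - p), np.nan)
    term = numerator(np.nan_to_num(codes), p[None, :]) / den_snp[None, :]
    term = np.where(ok, term, 0.0)
    n = ok.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        return term.sum(axis=1) / np.where(n == 0, np.nan, n)


def f_vr2(g: GenotypeMatrix, freqs: pd.Series) -> pd.Series:
    """VanRaden method-2 diagonal minus one (per-SNP standardisation)."""
    out = _per_snp_ratio(g, freqs, lambda x, p: (x - 2.0 * p) ** 2) - 1.0
    return pd.Series(out.to_numpy() if isinstance(out, pd.Series) else out,
                     index=g.samples, name="F_VR2")


def f_yan(g: GenotypeMatrix, freqs: pd.Series) -> pd.Series:
    """Yang GRM diagonal: ``mean_j (x^2 - (1+2p)x + 2p^2) / (2p(1-p))``."""
    out = _per_snp_ratio(
        g, freqs, lambda x, p: x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p
    )
    return pd.Series(np.asarray(out), index=g.samples, name="F_YAN")


def adjust_to_reference(f: pd.Series, ref_mean: float, name: str | None = None) -> pd.Series:
    """0-adjust a coefficient: ``F0 = (F - ref_mean) / (1 - ref_mean)``.

    ``ref_mean`` is the mean of the raw coefficient over the reference
    cohort, so the reference-cohort mean of F0 is exactly zero, and F = 1
    remains a fixed point.
    """
    if ref_mean >= 1.0:
        raise ValueError("reference mean of 1 leaves the adjustment undefined")
    out = (f - ref_mean) / (1.0 - ref_mean)
    out.name = name or (str(f.name) + "0" if f.name else "F0")
    return out


def expected_homozygosity(g: GenotypeMatrix, groups: pd.Series) -> pd.Series:
    """Genome-average expected homozygosity per cohort.

    ``groups`` maps sample id -> cohort label (e.g. generation, or
    (generation, line)); frequencies are computed within each cohort and
    ``F_EXP = mean_j [1 - 2 p_j (1 - p_j)]`` is averaged over SNPs with a
    defined frequency. Cohorts with no genotyped animal are absent from the
    result.
    """
    groups = groups.loc[groups.index.intersection(g.samples)]
    out = {}
    for label, ids in groups.groupby(groups).groups.items():
        idx = g.sample_indexer(ids)
        p = _freq(g.codes[idx])
        ok = ~np.isnan(p)
        if not ok.any():
            continue
        out[label] = float(np.mean(1.0 - 2.0 * p[ok] * (1.0 - p[ok])))
    return pd.Series(out, name="F_EXP").sort_index()


def inbreeding_table(g: GenotypeMatrix, freqs: pd.Series) -> pd.DataFrame:
    """All five GRM coefficients for every individual, as one frame."""
    return pd.DataFrame(
        {
            "F_NEJ": f_nej(g),
            "F_LH": f_lh(g, freqs),
            "F_VR1": f_vr1(g, freqs),
            "F_VR2": f_vr2(g, freqs),
            "F_YAN": f_yan(g, freqs),
        }
    )
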