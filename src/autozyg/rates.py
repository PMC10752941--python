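"""Individual increases in inbreeding and realised effective population size.

Every inbreeding coefficient F of an animal in selection generation g >= 2
converts to an individual per-generation rate

    dF = 1 - (1 - F) ** (1 / t),   t = g - 1,

where the reference population sits at selection generation 1, so t counts
the generations elapsed since the reference cohort. Generation-1 animals
have no molecular rate (t = 0). Negative coefficients give bases above one
and hence negative rates, which are legitimate (diversity gain); F >= 1 is
clamped to a rate of 1 with a warning.

Cohort rates become effective sizes through ``Ne = 1 / (2 * mean(dF))``,
reported signed and unclamped. The expected-homozygosity route instead
differences the cohort series: ``dF_EXP(g) = (F_g - F_{g-1}) / (1 - F_{g-1})``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .pedigree import estimate_t

__all__ = [
    "delta_f_molecular",
    "ne_per_generation",
    "ne_expected",
    "founder_distance",
    "summarize_ne",
]


def delta_f_molecular(f: pd.Series, generation: pd.Series) -> pd.Series:
    """Per-animal molecular rate ``1 - (1 - F) ** (1 / (g - 1))``.

    ``generation`` maps animal id -> selection generation (1-based;
    generation 1 is the reference cohort and yields a missing rate).
    """
    gen = generation.reindex(f.index).to_numpy(dtype=float)
    t = gen - 1.0
    F = f.to_numpy(dtype=float).copy()
    high = F >= 1.0
    if high.any():
        warnings.warn(f"{int(high.sum())} coefficient(s) >= 1 clamped for rate computation")
        F[high] = 1.0 - 1e-12
    out = np.full(F.shape, np.nan)
    ok = (t >= 1.0) & ~np.isnan(F)
    # 1 - F may exceed 1 for negative coefficients; real-valued power is fine
    out[ok] = 1.0 - np.power(1.0 - F[ok], 1.0 / t[ok])
    out[ok & high] = 1.0
    name = str(f.name) if f.name else "F"
    return pd.Series(out, index=f.index, name="dF_" + name.removeprefix("F_"))


def ne_per_generation(rates: pd.Series, generation: pd.Series) -> pd.DataFrame:
    """Group per-animal rates by generation and convert to Ne.

    Returns a frame indexed by generation with columns ``mean_dF``, ``Ne``
    and ``n`` (animals with a non-missing rate). Generations whose mean rate
    is zero or that hold no usable animal get NaN Ne.
    """
    df = pd.DataFrame({"dF": rates, "generation": generation.reindex(rates.index)})
    df = df.dropna(subset=["generation"])
    out = []
    for gen, grp in df.groupby("generation", sort=True):
        vals = grp["dF"].dropna()
        if len(vals) == 0:
            out.append((gen, np.nan, np.nan, 0))
            continue
        m = vals.mean()
        ne = 1.0 / (2.0 * m) if m != 0.0 else np.nan
        out.append((gen, m, ne, len(vals)))
    res = pd.DataFrame(out, columns=["generation", "mean_dF", "Ne", "n"])
    return res.set_index("generation")


def ne_expected(series: pd.Series) -> pd.DataFrame:
    """Ne from an expected-homozygosity series indexed by generation.

    ``dF_EXP(g) = (F_g - F_{g-1}) / (1 - F_{g-1})``; the first generation of
    the series and zero rates give NaN.
    """
    s = series.sort_index()
    f = s.to_numpy(dtype=float)
    d = np.full(f.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        d[1:] = (f[1:] - f[:-1]) / (1.0 - f[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        ne = np.where(np.isnan(d) | (d == 0.0), np.nan, 1.0 / (2.0 * d))
    return pd.DataFrame({"mean_dF": d, "Ne": ne}, index=s.index)


def founder_distance(f_ref_mean: float, *, ne: float | None = None,
                     delta_f: float | None = None) -> float:
    """Generations from the (unobserved) founder pool to the reference cohort.

    Supply either an effective size (the rate becomes ``1 / (2 Ne)``, used
    for the marker-based distances with the sex-ratio Ne) or a rate
    directly (the pedigree distance uses the mean individual pedigree rate
    over all selection generations).
    """
    if (ne is None) == (delta_f is None):
        raise ValueError("supply exactly one of ne= or delta_f=")
    if delta_f is None:
        if ne <= 0:
            raise ValueError("ne must be positive")
        delta_f = 1.0 / (2.0 * ne)
    return estimate_t(f_ref_mean, delta_f)


def summarize_ne(table: pd.DataFrame) -> pd.Series:
    """Overall mean and SD of the per-generation Ne column (NaNs excluded)."""
    ne = table["Ne"].dropna()
    return pd.Series({"mean": ne.mean(), "sd": ne.std(ddof=1)}, name="Ne_summary")
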