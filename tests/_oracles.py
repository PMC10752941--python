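"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops over definitions,
sharing no code path with the package, so agreement is evidence and not
tautology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Pedigree: full additive relationship matrix by the tabular recursion
# ---------------------------------------------------------------------------

def tabular_inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """F from the dense A-matrix recursion (parents must precede offspring;
    -1 marks an unknown parent, treated as an unrelated non-inbred founder)."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[s, j]
            if d >= 0:
                a += 0.5 * A[d, j]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return np.diag(A) - 1.0


def random_pedigree(rng: np.random.Generator, n_max: int = 15) -> pd.DataFrame:
    """A random valid pedigree: stratified generations, random parent picks."""
    n_founders = int(rng.integers(2, 5))
    rows = []
    males, females = [], []
    for k in range(n_founders):
        sex = "M" if k % 2 == 0 else "F"
        rows.append((f"a{k}", None, None, sex, 0, "base"))
        (males if sex == "M" else females).append((f"a{k}", 0))
    n_total = int(rng.integers(n_founders + 1, n_max + 1))
    for k in range(n_founders, n_total):
        sire, sgen = males[int(rng.integers(len(males)))]
        dam, dgen = females[int(rng.integers(len(females)))]
        gen = max(sgen, dgen) + 1
        sex = "M" if rng.random() < 0.5 else "F"
        # occasionally drop a parent to exercise the unknown-parent path
        if rng.random() < 0.1:
            sire = None
        if rng.random() < 0.1:
            dam = None
        rows.append((f"a{k}", sire, dam, sex, gen, "base"))
        (males if sex == "M" else females).append((f"a{k}", gen))
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation", "line"])


def parent_indices(ped: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    row = {a: i for i, a in enumerate(ped["id"])}
    sire = np.array([row[v] if v is not None else -1 for v in ped["sire"]])
    dam = np.array([row[v] if v is not None else -1 for v in ped["dam"]])
    return sire, dam


# ---------------------------------------------------------------------------
# GRM estimators, per locus
# ---------------------------------------------------------------------------

def grm_estimators_bruteforce(codes: np.ndarray, p: np.ndarray) -> dict[str, np.ndarray]:
    """All five coefficients by explicit per-individual, per-locus loops."""
    n, m = codes.shape
    out = {k: np.full(n, np.nan) for k in ("F_NEJ", "F_LH", "F_VR1", "F_VR2", "F_YAN")}
    for i in range(n):
        hom = tot = 0
        hexp_sum = 0.0
        vr1_num = vr1_den = 0.0
        vr2_sum = yan_sum = 0.0
        n_poly = 0
        for j in range(m):
            x = codes[i, j]
            if x < 0 or np.isnan(p[j]):
                continue
            pj = p[j]
            tot += 1
            if x in (0, 2):
                hom += 1
            hexp_sum += 1.0 - 2.0 * pj * (1.0 - pj)
            vr1_num += (x - 2.0 * pj) ** 2
            vr1_den += pj * (1.0 - pj)
            if 0.0 < pj < 1.0:
                n_poly += 1
                vr2_sum += (x - 2.0 * pj) ** 2 / (2.0 * pj * (1.0 - pj))
                yan_sum += (x * x - (1.0 + 2.0 * pj) * x + 2.0 * pj * pj) / (
                    2.0 * pj * (1.0 - pj))
        if tot == 0:
            continue
        out["F_NEJ"][i] = hom / tot
        hexp = hexp_sum / tot
        if hexp < 1.0:
            out["F_LH"][i] = (hom / tot - hexp) / (1.0 - hexp)
        if vr1_den > 0:
            out["F_VR1"][i] = vr1_num / (2.0 * vr1_den) - 1.0
        if n_poly > 0:
            out["F_VR2"][i] = vr2_sum / n_poly - 1.0
            out["F_YAN"][i] = yan_sum / n_poly
    return out


def random_genotype_fixture(rng: np.random.Generator, n: int = 20, m: int = 50,
                            missing_rate: float = 0.05):
    """Random codes + reference-population frequencies for oracle batteries."""
    p = rng.uniform(0.02, 0.98, m)
    # a few SNPs fixed in the "reference" to exercise the exclusion rule
    p[rng.random(m) < 0.05] = rng.choice([0.0, 1.0])
    codes = rng.integers(0, 3, (n, m)).astype(np.int8)
    codes[rng.random((n, m)) < missing_rate] = -1
    return codes, p


# ---------------------------------------------------------------------------
# ROH: exhaustive enumeration
# ---------------------------------------------------------------------------

def roh_segments_bruteforce(codes_row: np.ndarray, bp: np.ndarray, params):
    """Maximal in-run SNP intervals satisfying window-fraction, gap, length,
    count and density rules, enumerated with plain loops."""
    n = len(bp)
    w = params.window_snps
    if n >= w:
        hom_win = []
        for s in range(0, n - w + 1):
            win = codes_row[s:s + w]
            hom_win.append(
                int((win == 1).sum()) <= params.window_het_max
                and int((win < 0).sum()) <= params.window_missing_max
            )
        inrun = []
        for k in range(n):
            lo, hi = max(0, k - w + 1), min(k, n - w)
            overl = hom_win[lo:hi + 1]
            inrun.append(bool(overl) and sum(overl) / len(overl) >= params.window_hit_threshold)
    else:
        inrun = [False] * n

    candidates = []
    k = 0
    while k < n:
        if not inrun[k]:
            k += 1
            continue
        j = k
        while j + 1 < n and inrun[j + 1]:
            j += 1
        start = k
        for t in range(k + 1, j + 1):
            if bp[t] - bp[t - 1] > params.max_gap_kb * 1000.0:
                candidates.append((start, t - 1))
                start = t
        candidates.append((start, j))
        k = j + 1

    kept = []
    for i0, i1 in candidates:
        n_snps = i1 - i0 + 1
        length_kb = (bp[i1] - bp[i0]) / 1000.0
        if n_snps < params.min_snps:
            continue
        if length_kb < params.min_len_kb:
            continue
        if length_kb / n_snps > params.max_kb_per_snp:
            continue
        kept.append((int(bp[i0]), int(bp[i1]), n_snps))
    return kept


def random_roh_fixture(rng: np.random.Generator, n_snps: int = 300,
                       hom_prob: float = 0.9):
    """One chromosome of mostly-homozygous calls with irregular spacing."""
    gaps = rng.integers(2_000, 30_000, n_snps)
    bp = np.cumsum(gaps).astype(np.int64)
    u = rng.random(n_snps)
    codes = np.where(u < hom_prob / 2, 0,
                     np.where(u < hom_prob, 2,
                              np.where(u < hom_prob + 0.07, 1, -1))).astype(np.int8)
    return codes, bp


# ---------------------------------------------------------------------------
# Pearson, textbook formula
# ---------------------------------------------------------------------------

def pearson_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))
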