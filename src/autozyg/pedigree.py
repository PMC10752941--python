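"""Pedigree handling and pedigree-based inbreeding.

A pedigree is held as a :class:`pandas.DataFrame` with one row per animal and
columns ``id``, ``sire``, ``dam``, ``sex``, ``generation`` and ``line``.
Unknown parents are ``None``; sex is ``"M"``/``"F"`` (or ``None``); ``line``
is one of ``"high"``, ``"low"``, ``"base"``; ``generation`` is the discrete
generation index, 0 for pedigree founders.

The individual inbreeding coefficient F is the probability that the two
alleles an animal carries at a neutral locus are identical by descent,
relative to the pedigree founders being unrelated and non-inbred. It is
computed with the Meuwissen & Luo ancestor-tracing recursion, which obtains
each diagonal element of the additive relationship matrix without ever
building the matrix.

Two per-generation rates of inbreeding are derived from F:

* the classic parent-offspring rate
  ``dF_t = (F_t - Fbar_parents) / (1 - Fbar_parents)``, and
* the individual (depth-standardised) rate
  ``dF_i = 1 - (1 - F) ** (1 / (t - 1))`` with ``t`` the animal's discrete
  generation counted from the founders (generation index + 1).

Either rate converts to a realised effective population size as
``Ne = 1 / (2 * mean(dF))``.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "PedigreeError",
    "load_pedigree",
    "write_pedigree",
    "validate_pedigree",
    "inbreeding_meuwissen_luo",
    "delta_f_pedt",
    "delta_f_pedi",
    "ne_from_rate",
    "ne_sex_ratio",
    "estimate_t",
]

PEDIGREE_COLUMNS = ("id", "sire", "dam", "sex", "generation", "line")

#: strings read as "parent unknown" on disk
UNKNOWN_CODES = {"", "0", "NA", "na", "nan", "None"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, orphan, duplicate...)."""


# ---------------------------------------------------------------------------
# I/O and validation
# ---------------------------------------------------------------------------

_DEFAULT_MAPPING = {
    "id": "id",
    "sire": "sire",
    "dam": "dam",
    "sex": "sex",
    "generation": "generation",
    "line": "line",
}


def load_pedigree(
    path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a pedigree from delimited text and validate it.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    columns
        Optional mapping from canonical names (``id``, ``sire``, ``dam``,
        ``sex``, ``generation``, ``line``) to the column names used in the
        file.
    sep
        Field separator; autodetected (csv/tsv/whitespace) when ``None``.

    Returns
    -------
    pandas.DataFrame
        Validated pedigree, topologically sorted so every parent precedes
        its offspring.
    """
    mapping = dict(_DEFAULT_MAPPING)
    if columns:
        mapping.update(columns)
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, comment="#")
    missing = [v for v in mapping.values() if v not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree file lacks columns: {missing}")
    out = pd.DataFrame(
        {canon: df[src] for canon, src in mapping.items()}
    )
    for col in ("sire", "dam"):
        out[col] = out[col].map(
            lambda v: None if (pd.isna(v) or str(v).strip() in UNKNOWN_CODES) else str(v).strip()
        )
    out["id"] = out["id"].astype(str).str.strip()
    out["sex"] = out["sex"].map(_norm_sex)
    out["generation"] = out["generation"].astype(int)
    out["line"] = out["line"].astype(str).str.strip().str.lower()
    return validate_pedigree(out)


def _norm_sex(v) -> str | None:
    if pd.isna(v):
        return None
    v = str(v).strip().upper()
    if v in {"M", "MALE", "1"}:
        return "M"
    if v in {"F", "FEMALE", "2"}:
        return "F"
    if v in UNKNOWN_CODES or v == "0":
        return None
    raise PedigreeError(f"unrecognised sex code {v!r}")


def write_pedigree(ped: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a pedigree back to delimited text (unknown parents as ``0``)."""
    out = ped.copy()
    for col in ("sire", "dam"):
        out[col] = out[col].map(lambda v: "0" if v is None else v)
    out.to_csv(path, sep=sep, index=False)


def validate_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants and return a topologically sorted copy.

    Raises :class:`PedigreeError` on duplicate ids, references to parents
    with no record, parentage cycles, a parent whose generation is not
    strictly below its offspring's, or a sire/dam of the wrong recorded sex.
    """
    ids = ped["id"]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise PedigreeError(f"duplicate animal id(s): {sorted(set(dup))[:5]}")
    known = set(ids)
    orphans = sorted(
        {p for p in pd.concat([ped["sire"], ped["dam"]]).dropna() if p not in known}
    )
    if orphans:
        raise PedigreeError(f"parents with no pedigree record: {orphans[:10]}")

    row = {a: i for i, a in enumerate(ids)}
    sire = ped["sire"].map(lambda v: -1 if v is None else row[v]).to_numpy(np.int64)
    dam = ped["dam"].map(lambda v: -1 if v is None else row[v]).to_numpy(np.int64)
    order = _topological_order(sire, dam, list(ids))
    ped = ped.iloc[order].reset_index(drop=True)

    # generation and sex consistency (checked after the sort so cycle errors
    # take precedence)
    gen = dict(zip(ped["id"], ped["generation"]))
    sex = dict(zip(ped["id"], ped["sex"]))
    for _, r in ped.iterrows():
        for parent, want in ((r["sire"], "M"), (r["dam"], "F")):
            if parent is None:
                continue
            if gen[parent] >= r["generation"]:
                raise PedigreeError(
                    f"parent {parent} (generation {gen[parent]}) not older than "
                    f"offspring {r['id']} (generation {r['generation']})"
                )
            if sex[parent] is not None and sex[parent] != want:
                raise PedigreeError(
                    f"{parent} used as {'sire' if want == 'M' else 'dam'} but recorded sex is {sex[parent]}"
                )
    return ped


def _topological_order(sire: np.ndarray, dam: np.ndarray, ids: Sequence[str]) -> list[int]:
    """Kahn's algorithm over the parent->offspring DAG; names a cycle member."""
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    out: list[int] = []
    while queue:
        i = queue.pop()
        out.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(out) < n:
        member = ids[int(np.flatnonzero(indeg > 0)[0])]
        raise PedigreeError(f"pedigree contains a parentage cycle involving {member!r}")
    return out


# ---------------------------------------------------------------------------
# Meuwissen & Luo inbreeding
# ---------------------------------------------------------------------------

def _ml_kernel_py(sire, dam):
    n = sire.shape[0]
    F = np.zeros(n)
    D = np.zeros(n)
    L = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            D[i] = 0.75 - 0.25 * F[s]
        elif d >= 0:
            D[i] = 0.75 - 0.25 * F[d]
        else:
            D[i] = 1.0
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        L[: i + 1] = 0.0
        L[i] = 1.0
        a_ii = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            a_ii += lj * lj * D[j]
            sj, dj = sire[j], dam[j]
            if sj >= 0:
                L[sj] += 0.5 * lj
            if dj >= 0:
                L[dj] += 0.5 * lj
        F[i] = a_ii - 1.0
    return F


if _HAVE_NUMBA:
    _ml_kernel = njit(cache=True)(_ml_kernel_py)
else:  # pragma: no cover
    _ml_kernel = _ml_kernel_py


def inbreeding_meuwissen_luo(ped: pd.DataFrame) -> pd.Series:
    """Per-animal pedigree inbreeding F by the Meuwissen & Luo recursion.

    The pedigree must be validated/sorted (parents before offspring), as
    returned by :func:`load_pedigree` or :func:`validate_pedigree`. Animals
    with an unknown parent get F = 0 (their unknown side is treated as an
    unrelated founder). Founders get F = 0 by construction.

    Returns a float Series indexed by animal id, values in [0, 1].
    """
    row = {a: i for i, a in enumerate(ped["id"])}
    sire = ped["sire"].map(lambda v: -1 if v is None else row[v]).to_numpy(np.int64)
    dam = ped["dam"].map(lambda v: -1 if v is None else row[v]).to_numpy(np.int64)
    if np.any(sire >= np.arange(len(sire))) or np.any(dam >= np.arange(len(dam))):
        raise PedigreeError("pedigree not sorted parents-first; call validate_pedigree")
    F = _ml_kernel(sire, dam)
    return pd.Series(F, index=pd.Index(ped["id"], name="id"), name="F_PED")


# ---------------------------------------------------------------------------
# Rates of inbreeding and Ne
# ---------------------------------------------------------------------------

def delta_f_pedt(
    ped: pd.DataFrame,
    f_ped: pd.Series,
    unknown_parent_as_founder: bool = False,
) -> pd.Series:
    """Classic parent-referenced rate ``(F_t - Fbar_par) / (1 - Fbar_par)``.

    ``Fbar_par`` is the mean inbreeding of the animal's two parents. By
    default animals with an unknown parent get a missing value; with
    ``unknown_parent_as_founder`` the unknown side contributes F = 0.
    Animals whose parents are fully inbred (``Fbar_par == 1``) get a missing
    value with a warning. Values may be negative.
    """
    fmap = f_ped.to_dict()
    out = np.full(len(ped), np.nan)
    for k, (_, r) in enumerate(ped.iterrows()):
        s, d = r["sire"], r["dam"]
        if s is None and d is None:
            continue
        if (s is None or d is None) and not unknown_parent_as_founder:
            continue
        fpar = ((fmap[s] if s is not None else 0.0) + (fmap[d] if d is not None else 0.0)) / 2.0
        if fpar >= 1.0:
            warnings.warn(f"parents of {r['id']} fully inbred; dF_PEDt undefined")
            continue
        out[k] = (f_ped[r["id"]] - fpar) / (1.0 - fpar)
    return pd.Series(out, index=pd.Index(ped["id"], name="id"), name="dF_PEDt")


def delta_f_pedi(ped: pd.DataFrame, f_ped: pd.Series) -> pd.Series:
    """Individual rate ``1 - (1 - F) ** (1 / (t - 1))``.

    ``t`` is the animal's discrete generation counted from the pedigree
    founders, i.e. generation index + 1, so offspring of founders (t = 2)
    use exponent 1 and satisfy dF = F for a single generation of
    inbreeding. Founders themselves (t = 1) get a missing value.
    """
    t = ped["generation"].to_numpy(float) + 1.0
    F = f_ped.loc[ped["id"]].to_numpy(float)
    out = np.full(len(ped), np.nan)
    ok = t >= 2.0
    out[ok] = 1.0 - np.power(1.0 - F[ok], 1.0 / (t[ok] - 1.0))
    return pd.Series(out, index=pd.Index(ped["id"], name="id"), name="dF_PEDi")


def ne_from_rate(rates) -> float:
    """Realised ``Ne = 1 / (2 * mean(dF))`` over a cohort's dF values.

    Missing values are dropped first; an empty cohort is an error and a
    zero mean rate yields NaN (undefined Ne). Negative means give negative
    Ne, reported as-is.
    """
    arr = np.asarray(pd.Series(rates).dropna(), dtype=float)
    if arr.size == 0:
        raise ValueError("no non-missing dF values")
    mean = arr.mean()
    if mean == 0.0:
        warnings.warn("mean dF is zero; Ne undefined")
        return math.nan
    return 1.0 / (2.0 * mean)


def ne_sex_ratio(n_males: int, n_females: int) -> float:
    """Sex-ratio effective size ``Ne_s = 4 M F / (M + F)``.

    ``M`` breeding males and ``F`` breeding females, both > 0.
    """
    if n_males <= 0 or n_females <= 0:
        raise ValueError("both sex counts must be positive")
    return 4.0 * n_males * n_females / (n_males + n_females)


def estimate_t(f_ref: float, delta_f: float) -> float:
    """Generations from an unrelated founder pool to mean inbreeding ``f_ref``.

    Inverts ``F_t = 1 - (1 - dF) ** t`` to ``t = ln(1 - F) / ln(1 - dF)``.
    Both arguments must lie strictly in (0, 1).
    """
    if not (0.0 < f_ref < 1.0):
        raise ValueError("f_ref must be in (0, 1)")
    if not (0.0 < delta_f < 1.0):
        raise ValueError("delta_f must be in (0, 1)")
    return math.log(1.0 - f_ref) / math.log(1.0 - delta_f)
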