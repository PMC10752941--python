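"""Genotype containers, PLINK text/binary I/O and quality control.

Genotypes are held as an individuals x SNPs ``int8`` matrix of
reference-allele counts (0/1/2) with ``-1`` marking a missing call, plus a
marker map (chromosome, 1-based bp position, reference/alternate allele
labels). The reference allele is the allele listed first for the SNP (A1 in
.bim); the hand-written text reader orients deterministically by taking the
alphabetically smallest observed allele as reference when no .bim is
available.

Quality control follows a fixed two-stage design:

1. individuals with call rate strictly below a threshold are dropped
   (default 0.97 — exactly 97% is kept);
2. the ROH marker set keeps autosomal SNPs with missing fraction <= 0.03,
   with **no** minor-allele-frequency filter;
3. the GRM marker set starts from the ROH set and applies two sequential
   MAF filters: SNPs with MAF strictly below 0.05 in the declared reference
   subset are dropped, then remnant SNPs with MAF strictly below 0.05 over
   all individuals are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "read_plink",
    "write_plink_text",
    "write_plink_bed",
    "qc_individuals",
    "qc_snps_roh_set",
    "qc_snps_grm_set",
    "allele_frequencies",
]

MISSING = np.int8(-1)

#: chromosome labels treated as non-autosomal
SEX_CHROMOSOMES = {"X", "Y", "XY", "MT", "M", "23", "24", "25", "26"}

_MAP_COLUMNS = ["chrom", "bp", "a1", "a2"]


def marker_map(chrom, snp_ids, bp, a1, a2) -> pd.DataFrame:
    """Assemble a marker map frame; positions must increase within chromosome."""
    m = pd.DataFrame(
        {"chrom": np.asarray(chrom, dtype=object), "bp": np.asarray(bp, dtype=np.int64),
         "a1": list(a1), "a2": list(a2)},
        index=pd.Index(snp_ids, name="snp"),
    )
    if m.index.duplicated().any():
        raise ValueError("duplicate SNP identifiers in marker map")
    for _, grp in m.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["bp"].to_numpy()) > 0):
            raise ValueError("bp positions not strictly increasing within chromosome")
    return m


def is_autosomal(markers: pd.DataFrame) -> np.ndarray:
    return ~markers["chrom"].astype(str).str.upper().isin(SEX_CHROMOSOMES).to_numpy()


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs reference-allele counts plus the marker map.

    ``codes[i, j]`` is 0/1/2 (copies of the reference allele of SNP j carried
    by individual i) or -1 for a missing call. ``samples`` holds pedigree
    animal ids; ``markers`` is the map frame indexed by SNP id.
    """

    codes: np.ndarray
    samples: pd.Index
    markers: pd.DataFrame
    log: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = pd.Index(self.samples, name="id")
        if self.codes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} SNPs"
            )
        bad = ~np.isin(self.codes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,missing}")
        if self.codes.dtype != np.int8:
            self.codes = self.codes.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypeMatrix":
        codes = self.codes
        samples = self.samples
        markers = self.markers
        if sample_mask is not None:
            codes = codes[np.asarray(sample_mask)]
            samples = samples[np.asarray(sample_mask)]
        if snp_mask is not None:
            codes = codes[:, np.asarray(snp_mask)]
            markers = markers.loc[np.asarray(snp_mask)] if np.asarray(snp_mask).dtype == bool else markers.iloc[snp_mask]
        return GenotypeMatrix(codes.copy(), samples, markers.copy(), list(self.log))

    def sample_indexer(self, ids) -> np.ndarray:
        idx = self.samples.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            raise KeyError("unknown sample id(s) requested")
        return idx


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------

def write_plink_text(g: GenotypeMatrix, prefix, sex=None) -> None:
    """Write .ped/.map. Allele symbols come from the marker map (a1/a2)."""
    prefix = Path(prefix)
    m = g.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for snp, r in m.iterrows():
            fh.write(f"{r['chrom']}\t{snp}\t0\t{r['bp']}\n")
    a1 = m["a1"].to_numpy(dtype=object)
    a2 = m["a2"].to_numpy(dtype=object)
    sex_codes = _sex_codes(g.samples, sex)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(g.samples):
            row = g.codes[i]
            fields = [str(sid), str(sid), "0", "0", sex_codes[i], "-9"]
            for j in range(g.n_snps):
                c = row[j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 2:
                    fields += [a1[j], a1[j]]
                elif c == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def _sex_codes(samples, sex) -> list[str]:
    if sex is None:
        return ["0"] * len(samples)
    lut = {"M": "1", "F": "2", None: "0"}
    return [lut.get(sex.get(s), "0") for s in samples]


def _read_plink_text(prefix: Path) -> GenotypeMatrix:
    mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                     names=["chrom", "snp", "cm", "bp"], dtype=str)
    n_snps = len(mp)
    samples, rows, sexes = [], [], {}
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, map says {2 * n_snps}"
                )
            samples.append(parts[1])
            sexes[parts[1]] = {"1": "M", "2": "F"}.get(parts[4])
            rows.append(parts[6:])
    allele = np.asarray(rows, dtype=object).reshape(len(samples), n_snps, 2)
    # deterministic orientation: reference = alphabetically smallest observed
    codes = np.empty((len(samples), n_snps), dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(n_snps):
        col = allele[:, j, :]
        seen = sorted({a for a in col.ravel() if a != "0"})
        if len(seen) > 2:
            raise ValueError(f"SNP {mp['snp'][j]} has >2 alleles: {seen}")
        ref = seen[0] if seen else "A"
        alt = seen[1] if len(seen) > 1 else ("B" if ref != "B" else "A")
        a1_list.append(ref)
        a2_list.append(alt)
        miss = (col[:, 0] == "0") | (col[:, 1] == "0")
        codes[:, j] = (col[:, 0] == ref).astype(np.int8) + (col[:, 1] == ref).astype(np.int8)
        codes[miss, j] = MISSING
    markers = marker_map(mp["chrom"], mp["snp"], mp["bp"].astype(np.int64), a1_list, a2_list)
    g = GenotypeMatrix(codes, pd.Index(samples), markers)
    g.sex = sexes  # type: ignore[attr-defined]
    return g


# ---------------------------------------------------------------------------
# PLINK binary (.bed/.bim/.fam), SNP-major
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes in .bed: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# Ours count A1, so: 2 -> 0b00, missing -> 0b01, 1 -> 0b10, 0 -> 0b11.
_ENC = np.array([3, 2, 0], dtype=np.uint8)  # index by code 0,1,2
_DEC = np.array([2, -1, 1, 0], dtype=np.int8)  # index by 2-bit field


def write_plink_bed(g: GenotypeMatrix, prefix, sex=None) -> None:
    """Write .bed (SNP-major with the standard magic) plus .bim and .fam."""
    prefix = Path(prefix)
    m = g.markers
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for snp, r in m.iterrows():
            fh.write(f"{r['chrom']}\t{snp}\t0\t{r['bp']}\t{r['a1']}\t{r['a2']}\n")
    sex_codes = _sex_codes(g.samples, sex)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, sid in enumerate(g.samples):
            fh.write(f"{sid} {sid} 0 0 {sex_codes[i]} -9\n")
    n = g.n_samples
    pad = (-n) % 4
    codes = g.codes.T  # SNP-major
    two_bit = np.where(codes < 0, 1, _ENC[np.clip(codes, 0, 2)]).astype(np.uint8)
    if pad:
        two_bit = np.concatenate([two_bit, np.zeros((g.n_snps, pad), np.uint8)], axis=1)
    q = two_bit.reshape(g.n_snps, -1, 4)
    packed = (q[:, :, 0] | (q[:, :, 1] << 2) | (q[:, :, 2] << 4) | (q[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def _read_plink_bed(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "bp", "a1", "a2"], dtype=str)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    n, n_snps = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(".bed magic bytes missing or not SNP-major")
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if body.size != bytes_per_snp * n_snps:
        raise ValueError(
            f".bed payload is {body.size} bytes; expected {bytes_per_snp * n_snps} "
            f"for {n} samples x {n_snps} SNPs"
        )
    body = body.reshape(n_snps, bytes_per_snp)
    two_bit = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(n_snps, -1)[:, :n]
    codes = _DEC[two_bit].T.astype(np.int8)
    markers = marker_map(bim["chrom"], bim["snp"], bim["bp"].astype(np.int64),
                         bim["a1"], bim["a2"])
    g = GenotypeMatrix(codes, pd.Index(fam["iid"]), markers)
    g.sex = {r["iid"]: {"1": "M", "2": "F"}.get(r["sex"]) for _, r in fam.iterrows()}  # type: ignore[attr-defined]
    return g


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK fileset from ``prefix`` (.bed/.bim/.fam or .ped/.map)."""
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        return _read_plink_bed(prefix)
    if prefix.with_suffix(".ped").exists():
        return _read_plink_text(prefix)
    raise FileNotFoundError(f"no .bed or .ped fileset at prefix {prefix}")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_individuals(g: GenotypeMatrix, min_call_rate: float = 0.97) -> GenotypeMatrix:
    """Drop individuals whose call rate is strictly below ``min_call_rate``."""
    if not (0.0 < min_call_rate <= 1.0):
        raise ValueError("min_call_rate must be in (0, 1]")
    call = (g.codes >= 0).mean(axis=1)
    keep = call >= min_call_rate
    if not keep.any():
        raise ValueError("individual QC removed every individual")
    removed = list(g.samples[~keep])
    out = g.subset(sample_mask=keep)
    out.log.append(
        {"stage": "qc_individuals", "min_call_rate": min_call_rate,
         "n_removed": len(removed), "removed": removed}
    )
    return out


def qc_snps_roh_set(g: GenotypeMatrix, max_missing: float = 0.03) -> GenotypeMatrix:
    """ROH marker set: autosomal SNPs with missing fraction <= ``max_missing``.

    Deliberately applies no MAF filter so that ROH detection keeps maximum
    genome coverage.
    """
    miss = (g.codes < 0).mean(axis=0)
    keep = is_autosomal(g.markers) & (miss <= max_missing)
    if not keep.any():
        raise ValueError("ROH SNP QC removed every SNP")
    out = g.subset(snp_mask=keep)
    out.log.append(
        {"stage": "qc_snps_roh_set", "max_missing": max_missing,
         "n_removed": int((~keep).sum()), "n_kept": int(keep.sum())}
    )
    return out


def qc_snps_grm_set(
    g: GenotypeMatrix, ref_samples, min_maf: float = 0.05
) -> GenotypeMatrix:
    """GRM marker set: two sequential MAF filters on the ROH set.

    First SNPs with MAF strictly below ``min_maf`` in the reference subset
    are removed, then remnant SNPs with MAF strictly below ``min_maf`` over
    all individuals. Equality with the threshold is kept.
    """
    ref_idx = g.sample_indexer(ref_samples)
    p_ref = _freq(g.codes[ref_idx])
    maf_ref = np.minimum(p_ref, 1.0 - p_ref)
    keep1 = ~np.isnan(maf_ref) & (maf_ref >= min_maf)
    p_all = _freq(g.codes)
    maf_all = np.minimum(p_all, 1.0 - p_all)
    keep = keep1 & ~np.isnan(maf_all) & (maf_all >= min_maf)
    if not keep.any():
        raise ValueError("GRM SNP QC removed every SNP")
    out = g.subset(snp_mask=keep)
    out.log.append(
        {"stage": "qc_snps_grm_set", "min_maf": min_maf,
         "n_removed_ref": int((~keep1).sum()),
         "n_removed_all": int((keep1 & ~keep).sum()),
         "n_kept": int(keep.sum())}
    )
    return out


def _freq(codes: np.ndarray) -> np.ndarray:
    """Reference-allele frequency per SNP ignoring missing; NaN if all missing."""
    ok = codes >= 0
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(ok, codes, 0).sum(axis=0) / (2.0 * np.where(n == 0, np.nan, n))


def allele_frequencies(g: GenotypeMatrix, subset=None) -> pd.Series:
    """Per-SNP reference-allele frequency over a declared individual subset.

    ``subset`` is an iterable of sample ids (default: all). SNPs entirely
    missing in the subset get NaN with a warning.
    """
    if subset is None:
        codes = g.codes
    else:
        idx = g.sample_indexer(subset)
        if idx.size == 0:
            raise ValueError("empty reference subset")
        codes = g.codes[idx]
    p = _freq(codes)
    n_bad = int(np.isnan(p).sum())
    if n_bad:
        warnings.warn(f"{n_bad} SNP(s) entirely missing in subset; frequency set to NaN")
    return pd.Series(p, index=g.markers.index, name="p")
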