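"""Correlation matrices, the end-to-end pipeline, and report artifacts.

Pearson correlations are computed among all inbreeding coefficients and
among all per-animal rates of inbreeding, for the whole genotyped
population and within generation groups (by default the initial 1–4,
intermediate 16–19 and most recent 23–26 selection generations). Cells use
pairwise-complete observations — rates are undefined for generation-1
animals under some estimators, so listwise deletion would discard the
reference cohort everywhere.

``run_pipeline`` chains every stage — simulation (or file input), quality
control, pedigree inbreeding, GRM estimators, ROH, 0-adjustments, rates,
effective sizes, founder distances and correlations — and writes tidy
delimited tables plus figures. Figures are always rendered from the written
tables, never from in-memory state, so the tables remain the single source
of truth.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import genio, grm, pedigree as pedmod, rates, roh as rohmod
from .simulate import BreedingDesign, Genome, SimulationResult, simulate

__all__ = ["correlate", "CorrelationResult", "PipelineConfig", "PipelineError",
           "run_pipeline", "DEFAULT_GROUPS"]

logger = logging.getLogger(__name__)

DEFAULT_GROUPS: dict[str, tuple[int, ...]] = {
    "initial": (1, 2, 3, 4),
    "intermediate": (16, 17, 18, 19),
    "recent": (23, 24, 25, 26),
}

F_ESTIMATORS = ["F_PED", "F_NEJ", "F_LH", "F_VR1", "F_VR2", "F_YAN", "F_ROH"]
DF_ESTIMATORS = ["dF_PEDi", "dF_PEDt", "dF_NEJ0", "dF_LH", "dF_LH0",
                 "dF_VR1", "dF_VR2", "dF_YAN", "dF_ROH0"]


@dataclass
class CorrelationResult:
    """Pearson r matrix with the paired-observation count behind each cell."""

    r: pd.DataFrame
    n: pd.DataFrame
    group: str


def correlate(
    values: pd.DataFrame,
    generation: pd.Series | None = None,
    groups: Mapping[str, Sequence[int]] | None = None,
    min_pairs: int = 3,
) -> dict[str, CorrelationResult]:
    """Pairwise-complete Pearson correlations, overall and per group.

    ``values`` holds one column per estimator, indexed by animal id;
    ``generation`` maps id -> (selection) generation and is only needed
    when ``groups`` restricts to generation subsets. Cells with fewer than
    ``min_pairs`` paired observations, or a zero-variance column, are NaN.
    """
    out = {"all": _corr_one(values, "all", min_pairs)}
    if groups:
        if generation is None:
            raise ValueError("generation labels required for grouped correlations")
        gen = generation.reindex(values.index)
        for name, gens in groups.items():
            sub = values.loc[gen.isin(list(gens))]
            if len(sub):
                out[name] = _corr_one(sub, name, min_pairs)
    return out


def _corr_one(values: pd.DataFrame, group: str, min_pairs: int) -> CorrelationResult:
    notna = values.notna().astype(int)
    n = notna.T @ notna
    r = values.corr(method="pearson", min_periods=min_pairs)
    r[n < min_pairs] = np.nan
    return CorrelationResult(r=r, n=n, group=group)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, YAML-serialisable.

    Either provide ``pedigree_path``/``genotype_prefix`` for real data, or
    leave them unset to run the breeding simulator with ``design``/``seed``.
    ``selection_starts_at`` is the absolute pedigree generation index of the
    first selection generation (defaults to the design's random phase
    length + 1); generation labels in all outputs are selection
    generations, 1-based.
    """

    design: BreedingDesign = field(default_factory=BreedingDesign)
    seed: int = 0
    pedigree_path: str | None = None
    genotype_prefix: str | None = None
    selection_starts_at: int | None = None
    reference_generation: int = 1
    min_call_rate: float = 0.97
    max_snp_missing: float = 0.03
    min_maf: float = 0.05
    roh_params: rohmod.ROHParams = field(default_factory=rohmod.ROHParams)
    groups: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GROUPS.items()})
    breeding_males: int = 32
    breeding_females: int = 64
    out_dir: str = "autozyg_out"
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design_raw = raw.pop("design", {})
        genome_raw = design_raw.pop("genome", {}) if isinstance(design_raw, dict) else {}
        design = BreedingDesign(**design_raw, genome=Genome(**genome_raw))
        roh_raw = raw.pop("roh_params", {})
        return cls(design=design, roh_params=rohmod.ROHParams(**roh_raw), **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage '{name}' failed: {e}") from e
        return wrapped
    return deco


@dataclass
class PipelineResult:
    config: PipelineConfig
    pedigree: pd.DataFrame
    inbreeding: pd.DataFrame          # per genotyped animal, all coefficients
    delta_f: pd.DataFrame             # per genotyped animal, all rates
    rate_ne: pd.DataFrame             # generation x estimator tidy table
    ne_summary: pd.DataFrame          # overall mean/SD of Ne per estimator
    f_exp: pd.DataFrame               # generation x {all, high, low}
    ne_exp: pd.DataFrame
    correlations_f: dict
    correlations_df: dict
    segments: pd.DataFrame
    founder_distances: dict
    qc_log: list
    truth: pd.DataFrame | None = None
    simulation: SimulationResult | None = None


_FROM_CONFIG = "__from_config__"


def run_pipeline(config: PipelineConfig | None = None, out_dir=_FROM_CONFIG,
                 sim: SimulationResult | None = None) -> PipelineResult:
    """Execute the full analysis and (optionally) write the report bundle.

    ``out_dir`` defaults to ``config.out_dir``; pass ``out_dir=None`` to
    skip writing entirely. Set ``config.make_figures=False`` to keep the
    tables but skip figure rendering. A pre-built :class:`SimulationResult`
    can be supplied to skip the simulation stage.
    """
    config = config or PipelineConfig()
    if out_dir == _FROM_CONFIG:
        out_dir = config.out_dir
    out_dir = Path(out_dir) if out_dir is not None else None

    sim, ped, g, sex = _load_inputs(config, sim)
    sel_start = config.selection_starts_at
    if sel_start is None:
        sel_start = config.design.random_generations + 1

    # selection-generation label per animal (1-based); base-phase animals NaN
    ped_idx = ped.set_index("id")
    sel_gen_all = ped_idx["generation"] - (sel_start - 1)
    sel_gen_all[ped_idx["line"] == "base"] = np.nan

    g, qc_log = _run_qc(config, g)
    sel_gen = sel_gen_all.reindex(g.samples)
    line = ped_idx["line"].reindex(g.samples)
    ref_ids = g.samples[(sel_gen == config.reference_generation).to_numpy()]
    if len(ref_ids) == 0:
        raise PipelineError("stage 'reference' failed: no genotyped animals in the "
                            f"reference generation {config.reference_generation}")

    fped, dpedt, dpedi = _pedigree_stage(ped)
    grm_set, freqs, ftab = _grm_stage(config, g, ref_ids)
    segments, froh = _roh_stage(config, g)

    # merge per-animal coefficients
    inb = ftab.copy()
    inb["F_ROH"] = froh.reindex(inb.index)
    inb["F_PED"] = fped.reindex(inb.index)
    for raw, adj in (("F_NEJ", "F_NEJ0"), ("F_LH", "F_LH0"), ("F_ROH", "F_ROH0")):
        ref_mean = float(inb.loc[ref_ids, raw].mean())
        inb[adj] = grm.adjust_to_reference(inb[raw], ref_mean, name=adj)
    inb.insert(0, "generation", sel_gen)
    inb.insert(1, "line", line)

    # rates
    dfs = pd.DataFrame(index=inb.index)
    dfs["dF_PEDi"] = dpedi.reindex(inb.index)
    dfs["dF_PEDt"] = dpedt.reindex(inb.index)
    for col in ("F_NEJ0", "F_LH", "F_LH0", "F_VR1", "F_VR2", "F_YAN", "F_ROH0"):
        dfs["dF_" + col.removeprefix("F_")] = rates.delta_f_molecular(inb[col], sel_gen)

    rate_ne, ne_summary = _rates_stage(dfs, sel_gen)

    f_exp, ne_exp = _fexp_stage(grm_set, sel_gen, line)

    corr_f = correlate(inb[F_ESTIMATORS], sel_gen, config.groups)
    corr_df = correlate(dfs[DF_ESTIMATORS], sel_gen, config.groups)

    founder = _founder_stage(config, inb, dfs, ref_ids)

    result = PipelineResult(
        config=config, pedigree=ped, inbreeding=inb, delta_f=dfs,
        rate_ne=rate_ne, ne_summary=ne_summary, f_exp=f_exp, ne_exp=ne_exp,
        correlations_f=corr_f, correlations_df=corr_df, segments=segments,
        founder_distances=founder, qc_log=qc_log,
        truth=sim.truth if sim is not None else None, simulation=sim,
    )
    if out_dir is not None:
        write_report(result, out_dir)
    return result


@_stage("input")
def _load_inputs(config: PipelineConfig, sim=None):
    if sim is not None:
        ped = pedmod.validate_pedigree(sim.pedigree)
        return sim, ped, sim.genotypes, getattr(sim.genotypes, "sex", {})
    if config.pedigree_path or config.genotype_prefix:
        if not (config.pedigree_path and config.genotype_prefix):
            raise ValueError("provide both pedigree_path and genotype_prefix")
        ped = pedmod.load_pedigree(config.pedigree_path)
        g = genio.read_plink(config.genotype_prefix)
        return None, ped, g, getattr(g, "sex", {})
    sim = simulate(config.design, config.seed)
    ped = pedmod.validate_pedigree(sim.pedigree)
    return sim, ped, sim.genotypes, getattr(sim.genotypes, "sex", {})


@_stage("qc")
def _run_qc(config: PipelineConfig, g):
    g = genio.qc_individuals(g, config.min_call_rate)
    g = genio.qc_snps_roh_set(g, config.max_snp_missing)
    for entry in g.log:
        logger.info("QC %s", {k: v for k, v in entry.items() if k != "removed"})
    return g, list(g.log)


@_stage("pedigree")
def _pedigree_stage(ped):
    fped = pedmod.inbreeding_meuwissen_luo(ped)
    return fped, pedmod.delta_f_pedt(ped, fped), pedmod.delta_f_pedi(ped, fped)


@_stage("grm")
def _grm_stage(config: PipelineConfig, g_roh, ref_ids):
    grm_set = genio.qc_snps_grm_set(g_roh, ref_ids, config.min_maf)
    freqs = genio.allele_frequencies(grm_set, ref_ids)
    ftab = grm.inbreeding_table(grm_set, freqs)
    return grm_set, freqs, ftab


@_stage("roh")
def _roh_stage(config: PipelineConfig, g_roh):
    segments = rohmod.detect_roh(g_roh, config.roh_params)
    return segments, rohmod.f_roh(segments, g_roh)


@_stage("rates")
def _rates_stage(dfs, sel_gen):
    tables = {}
    for col in dfs.columns:
        t = rates.ne_per_generation(dfs[col], sel_gen)
        t.insert(0, "estimator", col.removeprefix("dF_"))
        tables[col] = t
    rate_ne = pd.concat(tables.values()).reset_index()
    summary = (
        rate_ne.groupby("estimator")["Ne"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1))
        .reindex([c.removeprefix("dF_") for c in dfs.columns])
    )
    return rate_ne, summary


@_stage("f_exp")
def _fexp_stage(grm_set, sel_gen, line):
    gen = sel_gen.dropna()
    series = {"all": grm.expected_homozygosity(grm_set, gen)}
    for ln in ("high", "low"):
        ids = line.index[(line == ln) & sel_gen.notna()]
        if len(ids):
            series[ln] = grm.expected_homozygosity(grm_set, gen.loc[ids])
    f_exp = pd.DataFrame(series)
    f_exp.index.name = "generation"
    ne_exp = pd.concat(
        {name: rates.ne_expected(col.dropna()) for name, col in f_exp.items()},
        names=["series", "generation"],
    ).reset_index()
    return f_exp, ne_exp


@_stage("founder_distance")
def _founder_stage(config: PipelineConfig, inb, dfs, ref_ids):
    ne_s = pedmod.ne_sex_ratio(config.breeding_males, config.breeding_females)
    out = {"Ne_s": ne_s}
    for key, col in (("t_NEJ", "F_NEJ"), ("t_ROH", "F_ROH")):
        f_ref = float(inb.loc[ref_ids, col].mean())
        try:
            out[key] = rates.founder_distance(f_ref, ne=ne_s)
        except ValueError:
            out[key] = float("nan")
    f_ped_ref = float(inb.loc[ref_ids, "F_PED"].mean())
    mean_dpedi = float(dfs["dF_PEDi"].mean())
    try:
        out["t_PED"] = rates.founder_distance(f_ped_ref, delta_f=mean_dpedi)
    except ValueError:
        out["t_PED"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def write_report(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    tables = out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    pedmod.write_pedigree(result.pedigree, tables / "pedigree.csv")
    result.inbreeding.to_csv(tables / "inbreeding.csv")
    result.delta_f.to_csv(tables / "delta_f.csv")
    result.rate_ne.to_csv(tables / "rate_ne.csv", index=False)
    result.ne_summary.to_csv(tables / "ne_summary.csv")
    result.f_exp.to_csv(tables / "f_exp.csv")
    result.ne_exp.to_csv(tables / "ne_exp.csv", index=False)
    result.segments.to_csv(tables / "roh_segments.csv", index=False)
    for tag, bundle in (("f", result.correlations_f), ("df", result.correlations_df)):
        for name, cr in bundle.items():
            cr.r.to_csv(tables / f"correlations_{tag}_{name}.csv")
    meta = {"founder_distances": {k: float(v) for k, v in result.founder_distances.items()},
            "qc": [{k: v for k, v in e.items() if k != "removed"} for e in result.qc_log]}
    with open(tables / "summary.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    if result.truth is not None:
        result.truth.to_csv(tables / "truth.csv")
    if result.config.make_figures:
        render_figures(tables, out / "figures")


def render_figures(tables_dir, fig_dir) -> None:
    """Render generation-trend figures from the written tables only."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tables = Path(tables_dir)
    fig_dir = Path(fig_dir)
    fig_dir.mkdir(parents=True, exist_ok=True)

    inb = pd.read_csv(tables / "inbreeding.csv", index_col=0)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    cols = [c for c in inb.columns if c.startswith("F_")]
    trend = inb.groupby("generation")[cols].mean()
    for c in cols:
        ax.plot(trend.index, trend[c], label=c, lw=1.2)
    ax.set_xlabel("selection generation")
    ax.set_ylabel("mean inbreeding coefficient")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(fig_dir / "inbreeding_trends.png", dpi=150)
    plt.close(fig)

    fexp = pd.read_csv(tables / "f_exp.csv", index_col=0)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in fexp.columns:
        ax.plot(fexp.index, fexp[c], label=f"F_EXP ({c})", lw=1.2)
    nej = inb.groupby("generation")["F_NEJ"].mean()
    ax.plot(nej.index, nej, label="F_NEJ (all)", lw=1.6, ls="--", color="k")
    ax.set_xlabel("selection generation")
    ax.set_ylabel("expected homozygosity / F_NEJ")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(fig_dir / "expected_homozygosity.png", dpi=150)
    plt.close(fig)

    dfs = pd.read_csv(tables / "delta_f.csv", index_col=0)
    gen = inb["generation"]
    cols = [c for c in dfs.columns if c.startswith("dF_")]
    ncol = 3
    nrow = -(-len(cols) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(11, 3 * nrow), sharex=True)
    for ax, c in zip(np.ravel(axes), cols):
        m = dfs[c].groupby(gen).mean()
        ax.plot(m.index, m, lw=1.2)
        ax.axhline(0, color="grey", lw=0.6)
        ax.set_title(c, fontsize=9)
    for ax in np.ravel(axes)[len(cols):]:
        ax.axis("off")
    fig.supxlabel("selection generation")
    fig.supylabel("mean rate of inbreeding")
    fig.tight_layout()
    fig.savefig(fig_dir / "delta_f_trends.png", dpi=150)
    plt.close(fig)
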