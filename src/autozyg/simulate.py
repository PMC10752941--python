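"""Breeding-design simulator: gene dropping with true-IBD tracking.

Emulates the history of a mouse population divergently selected over many
discrete generations: a founder pool mixing a small number of fully inbred
lines, a long panmictic burn-in, a random-mating phase of a few generations
with a fixed sex ratio (each male mated to two females), then a split into
two reproductively closed selection lines with a fixed number of dams per
line, matings that avoid shared grandparents, and random thinning standing
in for the selection criterion (the trait itself is not modelled — the
inbreeding/Ne machinery depends only on the mating structure).

Chromosomes are carried as founder-origin mosaics: a haplotype is a
piecewise-constant map from bp position to an ancestral label, and meiosis
recombines the two parental mosaics with a Poisson crossover process on the
genetic map (no interference, no mutation). Two label layers are tracked:

* **line labels** — which fully inbred founder line a stretch descends
  from. Lines are internally IBD (each is a single homozygous haplotype),
  so line-label identity is what marker homozygosity and ROH can see.
* **pedigree-copy labels** — at the pedigree-founder generation (after the
  unrecorded burn-in) every founder's two gametes receive fresh unique
  labels. Identity of these labels is IBD *relative to the recorded
  pedigree*, exactly the probability pedigree inbreeding estimates.

Each genotyped animal's :class:`TruthRecord` therefore carries
``autozygosity_ibd`` (pedigree-copy layer; matches pedigree F in
expectation) and ``autozygosity_line`` (line layer; the quantity IBS-based
estimators respond to). Genotypes derive from line labels: every founder
line holds a line-specific allele at a configurable fraction of SNPs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genio import GenotypeMatrix, marker_map, write_plink_bed, write_plink_text

__all__ = ["Genome", "BreedingDesign", "SimulationResult", "simulate", "write_fixture",
           "gene_drop_child", "ibd_autozygosity", "line_autozygosity"]


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genome:
    """Autosomal map. Default: 5 x 10 Mb chromosomes, 1,000 evenly spaced
    SNPs each (10 kb spacing), 1 cM/Mb — a deliberately scaled-down stand-in
    for a high-density array."""

    n_chromosomes: int = 5
    snps_per_chromosome: int = 1000
    chrom_span_bp: int = 10_000_000
    cm_per_mb: float = 1.0

    @property
    def morgans_per_chrom(self) -> float:
        return self.chrom_span_bp / 1e6 * self.cm_per_mb / 100.0

    def positions(self, chrom: int) -> np.ndarray:
        step = self.chrom_span_bp // (self.snps_per_chromosome + 1)
        return (np.arange(1, self.snps_per_chromosome + 1) * step).astype(np.int64)


@dataclass(frozen=True)
class BreedingDesign:
    """The stated world of the experiment's breeding history.

    The selection phase records (and genotypes) roughly
    ``dams_per_line * parturitions_max * litter_size * selected_proportion``
    animals per line per generation — the random 30% thinning that stands in
    for the selection criterion. ``sires_per_line`` is not stated by the
    experiment's description (one male per 43-female cohort is ambiguous)
    and defaults to 13, about 30% of male candidates.
    """

    n_founder_lines: int = 3
    founder_pool_size: int = 96
    burn_in_generations: int = 40
    random_generations: int = 5
    random_males: int = 32
    random_females: int = 64
    females_per_male: int = 2
    random_offspring: int = 180
    selection_generations: int = 26
    n_lines: int = 2
    dams_per_line: int = 43
    sires_per_line: int = 13
    parturitions_max: int = 2
    litter_size: int = 5
    selected_proportion: float = 0.30
    avoid_shared_grandparents: bool = True
    random_union: bool = False  # True: idealised multinomial family sizes
    discriminating_fraction: float = 0.7
    missing_rate: float = 0.002
    genotype_from_generation: int | None = None  # default: selection phase
    genome: Genome = field(default_factory=Genome)

    def __post_init__(self):
        for name in ("n_founder_lines", "founder_pool_size", "random_males",
                     "random_females", "dams_per_line", "sires_per_line",
                     "litter_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.founder_pool_size != self.random_males + self.random_females:
            raise ValueError("founder_pool_size must equal random_males + random_females")

    @property
    def recorded_per_line(self) -> int:
        return max(1, round(self.dams_per_line * self.parturitions_max
                            * self.litter_size * self.selected_proportion))

    @property
    def first_genotyped_generation(self) -> int:
        if self.genotype_from_generation is not None:
            return self.genotype_from_generation
        return self.random_generations + 1

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Mosaic haplotypes
# ---------------------------------------------------------------------------
# A haplotype on one chromosome is (ends, labels): ends is an ascending
# float array whose last entry is the chromosome span; segment k covers
# (ends[k-1], ends[k]] with ancestral label labels[k].

Hap = tuple[np.ndarray, np.ndarray]


def _single_segment(span: float, label: int) -> Hap:
    return (np.array([span], dtype=np.float64), np.array([label], dtype=np.int32))


def _meiosis(h0: Hap, h1: Hap, span: float, morgans: float, rng: np.random.Generator) -> Hap:
    """One recombinant gamete from a parent's two chromosome mosaics."""
    k = int(rng.poisson(morgans))
    phase = int(rng.integers(2))
    pair = (h0, h1)
    if k == 0:
        e, l = pair[phase]
        return (e.copy(), l.copy())
    cuts = np.sort(rng.uniform(0.0, span, k))
    ends_out: list[float] = []
    labs_out: list[int] = []
    bounds = np.append(cuts, span)
    cur = 0.0
    src = phase
    for b in bounds:
        if b > cur:
            e, l = pair[src]
            i0 = int(np.searchsorted(e, cur, side="right"))
            i1 = int(np.searchsorted(e, b, side="left"))
            for i in range(i0, min(i1, len(e) - 1) + 1):
                seg_end = min(float(e[i]), float(b))
                if seg_end > cur:
                    if labs_out and labs_out[-1] == l[i]:
                        ends_out[-1] = seg_end
                    else:
                        ends_out.append(seg_end)
                        labs_out.append(int(l[i]))
                    cur = seg_end
        src ^= 1
        cur = b
    ends_out[-1] = span  # guard against float round-off at the terminus
    return (np.asarray(ends_out, dtype=np.float64), np.asarray(labs_out, dtype=np.int32))


def _match_length(a: Hap, b: Hap) -> float:
    """Total length where the two mosaics carry the same label."""
    ea, la = a
    eb, lb = b
    i = j = 0
    prev = 0.0
    tot = 0.0
    while i < len(ea) and j < len(eb):
        end = min(ea[i], eb[j])
        if la[i] == lb[j]:
            tot += end - prev
        prev = end
        if ea[i] <= end:
            i += 1
        if eb[j] <= end:
            j += 1
    return tot


def _compose(hap: Hap, sub_mosaics: list[Hap]) -> Hap:
    """Resolve a copy-label mosaic through per-copy sub-mosaics (copy -> line)."""
    ends, labels = hap
    out_e: list[float] = []
    out_l: list[int] = []
    prev = 0.0
    for e, c in zip(ends, labels):
        se, sl = sub_mosaics[int(c)]
        i0 = int(np.searchsorted(se, prev, side="right"))
        i1 = int(np.searchsorted(se, e, side="left"))
        for i in range(i0, min(i1, len(se) - 1) + 1):
            seg_end = min(float(se[i]), float(e))
            if seg_end > prev:
                if out_l and out_l[-1] == int(sl[i]):
                    out_e[-1] = seg_end
                else:
                    out_e.append(seg_end)
                    out_l.append(int(sl[i]))
                prev = seg_end
        prev = float(e)
    return (np.asarray(out_e, dtype=np.float64), np.asarray(out_l, dtype=np.int32))


class _Animal:
    __slots__ = ("id", "sire", "dam", "sex", "generation", "line", "haps")

    def __init__(self, id, sire, dam, sex, generation, line, haps):
        self.id = id
        self.sire = sire
        self.dam = dam
        self.sex = sex
        self.generation = generation
        self.line = line
        self.haps = haps  # list over chromosomes of [Hap, Hap]


def gene_drop_child(sire: "_Animal", dam: "_Animal", genome: Genome,
                    rng: np.random.Generator) -> list[list[Hap]]:
    """Recombinant chromosome pairs for one offspring (paternal, maternal)."""
    span = float(genome.chrom_span_bp)
    m = genome.morgans_per_chrom
    return [
        [_meiosis(sire.haps[c][0], sire.haps[c][1], span, m, rng),
         _meiosis(dam.haps[c][0], dam.haps[c][1], span, m, rng)]
        for c in range(genome.n_chromosomes)
    ]


def ibd_autozygosity(haps: list[list[Hap]], genome: Genome) -> float:
    """Fraction of the genome where the two gametes carry the same label."""
    tot = sum(_match_length(h[0], h[1]) for h in haps)
    return tot / (genome.n_chromosomes * genome.chrom_span_bp)


def line_autozygosity(haps: list[list[Hap]], copy_line_mosaics: list[list[Hap]],
                      genome: Genome) -> float:
    """As :func:`ibd_autozygosity` but after resolving copy labels to lines."""
    tot = 0.0
    for c, h in enumerate(haps):
        a = _compose(h[0], copy_line_mosaics[c])
        b = _compose(h[1], copy_line_mosaics[c])
        tot += _match_length(a, b)
    return tot / (genome.n_chromosomes * genome.chrom_span_bp)


# ---------------------------------------------------------------------------
# Simulation proper
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    pedigree: pd.DataFrame
    genotypes: GenotypeMatrix
    truth: pd.DataFrame
    design: BreedingDesign
    seed: int

    @property
    def selection_generation(self) -> pd.Series:
        """Selection-phase generation (1-based) per genotyped animal."""
        ped = self.pedigree.set_index("id")
        gen = ped.loc[self.genotypes.samples, "generation"]
        return gen - self.design.random_generations


class _MatingError(RuntimeError):
    pass


def simulate(design: BreedingDesign | None = None, seed: int = 0) -> SimulationResult:
    """Run the full breeding history and return pedigree, genotypes, truth.

    Deterministic given ``(design, seed)``. Raises a RuntimeError suggesting
    a census increase when the grandparent-avoidance rule leaves a dam with
    no admissible sire after many reshuffles.
    """
    design = design or BreedingDesign()
    rng = np.random.default_rng(seed)
    genome = design.genome
    span = float(genome.chrom_span_bp)
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"I{counter[0]:06d}"

    # --- burn-in (unrecorded): line-label haplotypes, panmixia ------------
    pool = design.founder_pool_size
    sexes_founder = ["M"] * design.random_males + ["F"] * design.random_females

    def fresh_line_animal(k: int, sex: str) -> _Animal:
        line_id = k % design.n_founder_lines
        haps = [[_single_segment(span, line_id), _single_segment(span, line_id)]
                for _ in range(genome.n_chromosomes)]
        return _Animal(new_id(), None, None, sex, -1, "burnin", haps)

    if design.burn_in_generations > 0:
        half = pool // 2
        burn = [fresh_line_animal(k, "M" if k < half else "F") for k in range(pool)]
        for _ in range(design.burn_in_generations):
            males = [a for a in burn if a.sex == "M"]
            females = [a for a in burn if a.sex == "F"]
            nxt = []
            for k in range(pool):
                s = males[int(rng.integers(len(males)))]
                d = females[int(rng.integers(len(females)))]
                nxt.append(_Animal(new_id(), None, None, "M" if k % 2 == 0 else "F",
                                   -1, "burnin", gene_drop_child(s, d, genome, rng)))
            burn = nxt
        founders = burn
        for a, sx in zip(founders, sexes_founder):
            a.sex = sx
    else:
        founders = [fresh_line_animal(k, sexes_founder[k]) for k in range(pool)]

    # --- pedigree-founder snapshot: relabel gametes with unique copies ----
    copy_line_mosaics: list[list[Hap]] = [[] for _ in range(genome.n_chromosomes)]
    for a in founders:
        a.sire = a.dam = None
        a.generation = 0
        a.line = "base"
        new_haps = []
        for c in range(genome.n_chromosomes):
            pair = []
            for h in a.haps[c]:
                copy_id = len(copy_line_mosaics[c])
                copy_line_mosaics[c].append(h)
                pair.append(_single_segment(span, copy_id))
            new_haps.append(pair)
        a.haps = new_haps
    recorded: list[_Animal] = list(founders)

    # --- random-mating phase ---------------------------------------------
    def make_offspring(pairs, n_offspring, generation, line, random_union):
        """pairs: list of (sire, dam); offspring distributed round-robin over
        pairs, or drawn uniformly at random when random_union."""
        kids = []
        for k in range(n_offspring):
            if random_union:
                s, d = pairs[int(rng.integers(len(pairs)))]
            else:
                s, d = pairs[k % len(pairs)]
            sex = "M" if k % 2 == 0 else "F"
            kids.append(_Animal(new_id(), s.id, d.id, sex, generation, line,
                                gene_drop_child(s, d, genome, rng)))
        return kids

    prev = founders
    for g in range(1, design.random_generations + 1):
        males = [a for a in prev if a.sex == "M"]
        females = [a for a in prev if a.sex == "F"]
        if len(males) < design.random_males or len(females) < design.random_females:
            raise _MatingError("not enough candidates for the random phase; "
                               "increase random_offspring")
        sires = list(rng.choice(males, design.random_males, replace=False))
        dams = list(rng.choice(females, design.random_females, replace=False))
        # each male with females_per_male females, one male per female
        pairs = [(sires[i // design.females_per_male], d) for i, d in enumerate(dams)]
        kids = make_offspring(pairs, design.random_offspring, g, "base",
                              design.random_union)
        recorded.extend(kids)
        prev = kids

    # --- selection phase: closed lines -----------------------------------
    by_id = {a.id: a for a in recorded}

    def grandparents(a: _Animal) -> set:
        out = set()
        for pid in (a.sire, a.dam):
            if pid is not None and pid in by_id:
                p = by_id[pid]
                out.update(x for x in (p.sire, p.dam) if x is not None)
        return out

    def assign_mates(sires, dams) -> list:
        """Assign every dam one admissible sire under a per-sire capacity.

        Solved exactly as bipartite b-matching with Kuhn's augmenting
        paths, so a mating plan is found whenever one exists; only a
        genuinely infeasible census raises."""
        cap = -(-len(dams) // len(sires))  # ceil
        admissible = []
        for d in dams:
            gpd = grandparents(d)
            ok = [si for si, s in enumerate(sires)
                  if not (design.avoid_shared_grandparents and grandparents(s) & gpd)]
            admissible.append(ok)
        match = [-1] * len(dams)          # dam -> sire index
        load = [0] * len(sires)

        def augment(di, seen) -> bool:
            for si in admissible[di]:
                if si in seen:
                    continue
                seen.add(si)
                if load[si] < cap:
                    match[di] = si
                    load[si] += 1
                    return True
                for dj in range(len(dams)):
                    if match[dj] == si and augment(dj, seen):
                        match[di] = si  # dj moved off si, slot reused
                        return True
            return False

        order = rng.permutation(len(dams))
        for di in order:
            di = int(di)
            rng.shuffle(admissible[di])
            if not augment(di, set()):
                raise _MatingError(
                    "could not mate all dams without shared grandparents; "
                    "increase the census"
                )
        return [(sires[match[di]], dams[di]) for di in range(len(dams))]

    def draw_breeders_and_mate(pool_m, pool_f):
        """Random breeder sample plus an exact mating plan; when a drawn
        sample admits no grandparent-avoiding plan, replacement breeders
        are drawn (as a breeder replacing an unusable male would), up to a
        bounded number of times."""
        if len(pool_m) < design.sires_per_line or len(pool_f) < design.dams_per_line:
            raise _MatingError("line census too small to renew breeders; "
                               "increase litter_size or dams_per_line")
        last_err = None
        for _ in range(25):
            sires = list(rng.choice(pool_m, design.sires_per_line, replace=False))
            dams = list(rng.choice(pool_f, design.dams_per_line, replace=False))
            try:
                return assign_mates(sires, dams)
            except _MatingError as e:
                last_err = e
        raise last_err

    line_names = ["high", "low"][: design.n_lines]
    pools = {}
    if design.selection_generations > 0:
        last = prev
        males = [a for a in last if a.sex == "M"]
        females = [a for a in last if a.sex == "F"]
        need_m = design.sires_per_line * design.n_lines
        need_f = design.dams_per_line * design.n_lines
        if len(males) < need_m or len(females) < need_f:
            raise _MatingError("random phase did not produce enough line founders; "
                               "increase random_offspring")
        # disjoint candidate pools per line; breeders are drawn inside each
        midx = rng.permutation(len(males))
        fidx = rng.permutation(len(females))
        half_m = len(males) // design.n_lines
        half_f = len(females) // design.n_lines
        for li, ln in enumerate(line_names):
            pools[ln] = (
                [males[int(i)] for i in midx[li * half_m:(li + 1) * half_m]],
                [females[int(i)] for i in fidx[li * half_f:(li + 1) * half_f]],
            )

    per_line = design.recorded_per_line
    for sg in range(1, design.selection_generations + 1):
        g = design.random_generations + sg
        for ln in line_names:
            pool_m, pool_f = pools[ln]
            pairs = draw_breeders_and_mate(pool_m, pool_f)
            kids = make_offspring(pairs, per_line, g, ln, False)
            recorded.extend(kids)
            for a in kids:
                by_id[a.id] = a
            pools[ln] = ([a for a in kids if a.sex == "M"],
                         [a for a in kids if a.sex == "F"])

    # --- outputs -----------------------------------------------------------
    ped = pd.DataFrame(
        {
            "id": [a.id for a in recorded],
            "sire": [a.sire for a in recorded],
            "dam": [a.dam for a in recorded],
            "sex": [a.sex for a in recorded],
            "generation": [a.generation for a in recorded],
            "line": [a.line for a in recorded],
        }
    )
    genotyped = [a for a in recorded
                 if a.generation >= design.first_genotyped_generation]

    markers, allele_bit, chrom_cols, chrom_pos = _make_markers(design, rng)
    copy_line_per_snp = _copy_lines_at_snps(copy_line_mosaics, chrom_pos, chrom_cols,
                                            len(markers))
    codes = np.empty((len(genotyped), len(markers)), dtype=np.int8)
    truth_rows = []
    for i, a in enumerate(genotyped):
        row = np.empty(len(markers), dtype=np.int8)
        for c in range(genome.n_chromosomes):
            cols = chrom_cols[c]
            pos = chrom_pos[c]
            bits = np.zeros(len(cols), dtype=np.int8)
            for h in a.haps[c]:
                seg = np.searchsorted(h[0], pos, side="left")
                copies = h[1][seg]
                lines = copy_line_per_snp[copies, cols]
                bits = bits + allele_bit[lines, cols]
            row[cols] = bits
        codes[i] = row
        truth_rows.append(
            (a.id, ibd_autozygosity(a.haps, genome),
             line_autozygosity(a.haps, copy_line_mosaics, genome))
        )
    if design.missing_rate > 0:
        mask = rng.random(codes.shape) < design.missing_rate
        codes[mask] = -1

    g = GenotypeMatrix(codes, pd.Index([a.id for a in genotyped]), markers)
    g.sex = {a.id: a.sex for a in genotyped}  # type: ignore[attr-defined]
    truth = pd.DataFrame(truth_rows,
                         columns=["id", "autozygosity_ibd", "autozygosity_line"]
                         ).set_index("id")
    return SimulationResult(ped, g, truth, design, seed)


def _make_markers(design: BreedingDesign, rng: np.random.Generator):
    genome = design.genome
    n_chrom, m_per = genome.n_chromosomes, genome.snps_per_chromosome
    m = n_chrom * m_per
    disc = rng.random(m) < design.discriminating_fraction
    common = rng.integers(0, 2, m).astype(np.int8)
    allele_bit = np.tile(common, (design.n_founder_lines, 1))
    per_line = rng.integers(0, 2, (design.n_founder_lines, m)).astype(np.int8)
    allele_bit[:, disc] = per_line[:, disc]

    chroms, ids, bps = [], [], []
    chrom_cols, chrom_pos = [], []
    for c in range(n_chrom):
        pos = genome.positions(c)
        chroms.extend([str(c + 1)] * m_per)
        ids.extend([f"snp{c + 1}_{k + 1}" for k in range(m_per)])
        bps.extend(pos.tolist())
        chrom_cols.append(np.arange(c * m_per, (c + 1) * m_per))
        chrom_pos.append(pos.astype(np.float64))
    markers = marker_map(chroms, ids, bps, ["A"] * m, ["B"] * m)
    return markers, allele_bit, chrom_cols, chrom_pos


def _copy_lines_at_snps(copy_line_mosaics, chrom_pos, chrom_cols, m) -> np.ndarray:
    n_copies = len(copy_line_mosaics[0])
    out = np.zeros((n_copies, m), dtype=np.int32)
    for c, (cols, pos) in enumerate(zip(chrom_cols, chrom_pos)):
        for k, hap in enumerate(copy_line_mosaics[c]):
            seg = np.searchsorted(hap[0], pos, side="left")
            out[k, cols] = hap[1][seg]
    return out


# ---------------------------------------------------------------------------
# Fixture output
# ---------------------------------------------------------------------------

def write_fixture(result: SimulationResult, out_dir) -> dict:
    """Write PLINK text+binary genotypes, pedigree CSV and truth CSV.

    Deterministic given the simulation seed. CSVs carry a ``#`` header with
    the seed and design hash; the PLINK dialect forbids comments, so the
    same metadata also lands in ``fixture.yaml`` alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# seed={result.seed} design={result.design.hash()}\n"
    sex = getattr(result.genotypes, "sex", None)
    write_plink_text(result.genotypes, out / "genotypes", sex=sex)
    write_plink_bed(result.genotypes, out / "genotypes", sex=sex)
    with open(out / "pedigree.csv", "w") as fh:
        fh.write(header)
        ped = result.pedigree.copy()
        for col in ("sire", "dam"):
            ped[col] = ped[col].map(lambda v: "0" if v is None else v)
        ped.to_csv(fh, index=False)
    with open(out / "truth.csv", "w") as fh:
        fh.write(header)
        result.truth.to_csv(fh)
    meta = {"seed": result.seed, "design_hash": result.design.hash(),
            "design": asdict(result.design)}
    with open(out / "fixture.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return meta
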