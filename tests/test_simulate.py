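"""Gene-dropping simulator: degenerate designs, truth tracking, drift."""

import hashlib
import warnings
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from autozyg import pedigree as pm
from autozyg.simulate import (BreedingDesign, Genome, _meiosis, _single_segment,
                              gene_drop_child, ibd_autozygosity, simulate,
                              write_fixture)

SPAN = 50_000_000.0


def _founder(genome, label_pair):
    return SimpleNamespace(haps=[
        [_single_segment(float(genome.chrom_span_bp), label_pair[0]),
         _single_segment(float(genome.chrom_span_bp), label_pair[1])]
        for _ in range(genome.n_chromosomes)
    ])


class TestMeiosisMechanics:
    @pytest.mark.parametrize("seed", range(20))
    def test_gamete_is_valid_mosaic_of_parent_labels(self, seed):
        rng = np.random.default_rng(seed)
        h0 = (np.array([1e7, 3e7, SPAN]), np.array([1, 2, 3], dtype=np.int32))
        h1 = (np.array([2e7, SPAN]), np.array([4, 5], dtype=np.int32))
        out = _meiosis(h0, h1, SPAN, 1.5, rng)
        ends, labels = out
        assert ends[-1] == SPAN
        assert np.all(np.diff(ends) > 0)
        assert set(labels) <= {1, 2, 3, 4, 5}
        assert np.all(labels[:-1] != labels[1:])  # adjacent segments merged

    def test_no_crossover_copies_one_parent(self):
        rng = np.random.default_rng(0)
        h0 = (np.array([SPAN]), np.array([7], dtype=np.int32))
        h1 = (np.array([SPAN]), np.array([8], dtype=np.int32))
        out = _meiosis(h0, h1, SPAN, 0.0, rng)
        assert list(out[1]) in ([7], [8])


class TestDegenerateDesigns:
    def test_single_founder_line_fully_homozygous(self):
        design = BreedingDesign(
            n_founder_lines=1, burn_in_generations=2, random_generations=1,
            random_males=4, random_females=8, founder_pool_size=12,
            random_offspring=30, selection_generations=2, dams_per_line=4,
            sires_per_line=2, litter_size=4, avoid_shared_grandparents=False,
            missing_rate=0.0,
            genome=Genome(n_chromosomes=1, snps_per_chromosome=100,
                          chrom_span_bp=1_000_000),
        )
        res = simulate(design, seed=3)
        assert not (res.genotypes.codes == 1).any()
        assert (res.truth["autozygosity_line"] == 1.0).all()

    def test_f1_of_two_lines_heterozygous_at_discriminating_snps(self):
        """An F1 between two fully inbred lines is heterozygous at exactly
        the SNPs where the parental lines differ, with zero line
        autozygosity."""
        design = BreedingDesign(
            n_founder_lines=2, burn_in_generations=0, random_generations=1,
            random_males=1, random_females=1, founder_pool_size=2,
            females_per_male=1, random_offspring=12, selection_generations=0,
            missing_rate=0.0, genotype_from_generation=0,
            genome=Genome(n_chromosomes=2, snps_per_chromosome=150,
                          chrom_span_bp=3_000_000),
        )
        res = simulate(design, seed=2)
        ped = res.pedigree.set_index("id")
        founders = ped.index[ped["generation"] == 0]
        fg = pd.DataFrame(res.genotypes.codes, index=res.genotypes.samples,
                          columns=res.genotypes.markers.index)
        line_rows = fg.loc[founders].drop_duplicates()
        assert len(line_rows) == 2  # the two pure-line genotype patterns
        disc = (line_rows.iloc[0] != line_rows.iloc[1]).to_numpy()
        f1 = res.truth.index[res.truth["autozygosity_line"] == 0.0]
        assert len(f1) > 0
        for aid in f1:
            row = fg.loc[aid].to_numpy()
            np.testing.assert_array_equal(row == 1, disc)

    def test_infeasible_grandparent_rule_raises(self):
        design = BreedingDesign(
            burn_in_generations=0, random_generations=1, random_males=2,
            random_females=4, founder_pool_size=6, random_offspring=20,
            selection_generations=2, dams_per_line=4, sires_per_line=2,
            litter_size=4, avoid_shared_grandparents=True,
            genome=Genome(n_chromosomes=1, snps_per_chromosome=20,
                          chrom_span_bp=1_000_000),
        )
        with pytest.raises(RuntimeError, match="census"):
            simulate(design, seed=0)


class TestTruthTracking:
    def test_full_sib_offspring_mean_autozygosity_quarter(self):
        """Gene dropping reproduces the pedigree expectation: offspring of a
        full-sib mating between outbred parents average 0.25 autozygosity
        over 300 replicates (within 3 SE)."""
        genome = Genome(n_chromosomes=4, snps_per_chromosome=10,
                        chrom_span_bp=50_000_000)
        rng = np.random.default_rng(42)
        vals = []
        for _ in range(300):
            gp1 = _founder(genome, (0, 1))
            gp2 = _founder(genome, (2, 3))
            sib1 = SimpleNamespace(haps=gene_drop_child(gp1, gp2, genome, rng))
            sib2 = SimpleNamespace(haps=gene_drop_child(gp1, gp2, genome, rng))
            child = gene_drop_child(sib1, sib2, genome, rng)
            vals.append(ibd_autozygosity(child, genome))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.25) < 3 * se

    def test_pedigree_f_predicts_ibd_truth(self, pooled_ibd_regression):
        """Meuwissen-Luo F regresses on realised copy-label autozygosity
        with slope ~1 over replicate runs of the default 26-generation
        design (pooled to beat the small-genome Monte-Carlo error)."""
        slope, intercept = pooled_ibd_regression
        assert 0.9 < slope < 1.1
        assert abs(intercept) < 0.02

    def test_adjusted_estimators_track_line_truth(self, default_pipeline):
        """F_NEJ0 and F_ROH0 regress on reference-adjusted line-level
        autozygosity with slope in [0.8, 1.2]: the 0-adjustment cancels the
        IBS baseline that raw homozygosity carries."""
        res = default_pipeline
        truth = res.truth["autozygosity_line"]
        ref_ids = res.inbreeding.index[res.inbreeding["generation"] == 1]
        m = truth.loc[ref_ids].mean()
        truth0 = (truth - m) / (1.0 - m)
        for col in ("F_NEJ0", "F_ROH0"):
            both = pd.concat({"x": truth0, "y": res.inbreeding[col]}, axis=1).dropna()
            slope = np.polyfit(both.x, both.y, 1)[0]
            assert 0.8 < slope < 1.2, col


def test_drift_variance_matches_sex_ratio_ne():
    """Across replicate random-union generations, the cohort-to-cohort
    allele-frequency change has variance p(1-p)/(2 Ne_s) within 3 SE of the
    replicate mean.

    The drift baseline is the full previous cohort (not the realised
    breeders): sampling 8 + 16 breeders out of it is precisely what the
    sex-ratio Ne describes.
    """
    design = BreedingDesign(
        burn_in_generations=0, random_generations=2, random_males=8,
        random_females=16, founder_pool_size=24, random_offspring=300,
        random_union=True, selection_generations=0, missing_rate=0.0,
        discriminating_fraction=1.0, genotype_from_generation=1,
        genome=Genome(n_chromosomes=2, snps_per_chromosome=60,
                      chrom_span_bp=30_000_000),
    )
    stats = []
    for seed in range(120):
        res = simulate(design, seed=seed)
        gen = res.pedigree.set_index("id")["generation"]
        fg = pd.DataFrame(res.genotypes.codes, index=res.genotypes.samples,
                          columns=res.genotypes.markers.index)
        p1 = fg.loc[gen.index[gen == 1]].mean() / 2
        p2 = fg.loc[gen.index[gen == 2]].mean() / 2
        num = ((p2 - p1) ** 2).mean()
        den = (p1 * (1 - p1)).mean()
        stats.append(num / den)
    stats = np.asarray(stats)
    ne_s = pm.ne_sex_ratio(8, 16)
    predicted = 1.0 / (2.0 * ne_s)
    se = stats.std(ddof=1) / np.sqrt(len(stats))
    assert abs(stats.mean() - predicted) < 3 * se


class TestFixtureIO:
    def test_roundtrip_and_seed_determinism(self, small_design, tmp_path):
        from autozyg import genio

        res = simulate(small_design, seed=4)
        write_fixture(res, tmp_path / "a")
        write_fixture(simulate(small_design, seed=4), tmp_path / "b")
        back = genio.read_plink(tmp_path / "a" / "genotypes")
        np.testing.assert_array_equal(back.codes, res.genotypes.codes)
        for name in ("genotypes.bed", "genotypes.ped", "pedigree.csv", "truth.csv"):
            a = (tmp_path / "a" / name).read_bytes()
            b = (tmp_path / "b" / name).read_bytes()
            assert hashlib.md5(a).hexdigest() == hashlib.md5(b).hexdigest(), name

    def test_changed_seed_changes_output(self, small_design, tmp_path):
        write_fixture(simulate(small_design, seed=4), tmp_path / "a")
        write_fixture(simulate(small_design, seed=5), tmp_path / "b")
        a = (tmp_path / "a" / "genotypes.bed").read_bytes()
        b = (tmp_path / "b" / "genotypes.bed").read_bytes()
        assert hashlib.md5(a).hexdigest() != hashlib.md5(b).hexdigest()
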