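"""Pedigree loading, Meuwissen–Luo inbreeding, pedigree rates and Ne."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from autozyg import pedigree as pm

from _oracles import parent_indices, random_pedigree, tabular_inbreeding


def _frame(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation", "line"])


FOUNDER_PAIR = [
    ("p1", None, None, "M", 0, "base"),
    ("p2", None, None, "F", 0, "base"),
]


class TestLoadValidate:
    def test_minimal_pedigree_sorted_offspring_last(self, tmp_path):
        path = tmp_path / "ped.csv"
        path.write_text(
            "id,sire,dam,sex,generation,line\n"
            "kid,p1,p2,F,1,base\np1,0,0,M,0,base\np2,,0,F,0,base\n"
        )
        ped = pm.load_pedigree(path)
        assert len(ped) == 3
        assert ped["id"].iloc[-1] == "kid"
        assert ped["sire"].iloc[-1] == "p1" and ped["dam"].iloc[-1] == "p2"
        assert ped[ped["id"] == "p2"]["sire"].iloc[0] is None

    def test_two_animal_cycle_is_reported(self):
        bad = _frame([("A", "B", None, "M", 1, "base"), ("B", "A", None, "M", 1, "base")])
        with pytest.raises(pm.PedigreeError, match="cycle"):
            pm.validate_pedigree(bad)

    def test_duplicate_and_orphan_errors(self):
        with pytest.raises(pm.PedigreeError, match="duplicate"):
            pm.validate_pedigree(_frame(FOUNDER_PAIR + [("p1", None, None, "M", 0, "base")]))
        with pytest.raises(pm.PedigreeError, match="no pedigree record"):
            pm.validate_pedigree(_frame(FOUNDER_PAIR + [("k", "ghost", "p2", "F", 1, "base")]))

    def test_generation_and_sex_consistency(self):
        rows = FOUNDER_PAIR + [("k", "p1", "p2", "F", 0, "base")]
        with pytest.raises(pm.PedigreeError, match="not older"):
            pm.validate_pedigree(_frame(rows))
        rows = FOUNDER_PAIR + [("k", "p2", "p1", "F", 1, "base")]  # sexes swapped
        with pytest.raises(pm.PedigreeError, match="recorded sex"):
            pm.validate_pedigree(_frame(rows))

    @pytest.mark.parametrize("seed", range(10))
    def test_shuffled_pedigree_matches_topological_oracle(self, seed):
        """Disk order must not matter: the sorted table puts every parent
        before its offspring and preserves the record set."""
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, n_max=10)
        shuffled = ped.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        out = pm.validate_pedigree(shuffled)
        assert sorted(out["id"]) == sorted(ped["id"])
        pos = {a: i for i, a in enumerate(out["id"])}
        for _, r in out.iterrows():
            for p in (r["sire"], r["dam"]):
                if p is not None:
                    assert pos[p] < pos[r["id"]]


class TestMeuwissenLuo:
    def test_outbred_offspring_zero(self):
        ped = pm.validate_pedigree(_frame(FOUNDER_PAIR + [("k", "p1", "p2", "F", 1, "base")]))
        assert pm.inbreeding_meuwissen_luo(ped)["k"] == 0.0

    def test_full_sib_mating_quarter(self):
        rows = FOUNDER_PAIR + [
            ("s", "p1", "p2", "M", 1, "base"),
            ("d", "p1", "p2", "F", 1, "base"),
            ("x", "s", "d", "F", 2, "base"),
        ]
        ped = pm.validate_pedigree(_frame(rows))
        F = pm.inbreeding_meuwissen_luo(ped)
        assert F["x"] == pytest.approx(0.25, abs=0)
        assert (F.drop("x") == 0).all()

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_tabular_oracle(self, seed):
        """Recursion equals F from the dense relationship-matrix recursion."""
        ped = pm.validate_pedigree(random_pedigree(np.random.default_rng(seed)))
        F = pm.inbreeding_meuwissen_luo(ped).to_numpy()
        sire, dam = parent_indices(ped)
        np.testing.assert_allclose(F, tabular_inbreeding(sire, dam), atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_nonnegative_and_order_invariant(self, seed):
        ped = random_pedigree(np.random.default_rng(seed))
        f1 = pm.inbreeding_meuwissen_luo(pm.validate_pedigree(ped))
        shuffled = ped.sample(frac=1.0, random_state=seed + 1).reset_index(drop=True)
        f2 = pm.inbreeding_meuwissen_luo(pm.validate_pedigree(shuffled))
        assert (f1 >= 0).all()
        pd.testing.assert_series_equal(f1.sort_index(), f2.sort_index())


class TestPedigreeRates:
    def _trio(self):
        rows = FOUNDER_PAIR + [("x", "p1", "p2", "F", 1, "base")]
        return pm.validate_pedigree(_frame(rows))

    def test_delta_f_pedt_formula(self):
        ped = self._trio()
        # fabricated F values exercise the formula directly
        for fx, fpar, want in [(0.25, 0.0, 0.25), (0.2, 0.2, 0.0), (0.1, 0.2, -0.125)]:
            F = pd.Series({"p1": fpar, "p2": fpar, "x": fx})
            assert pm.delta_f_pedt(ped, F)["x"] == pytest.approx(want, abs=1e-15)

    def test_delta_f_pedt_unknown_parent_policy(self):
        rows = FOUNDER_PAIR + [("x", "p1", None, "F", 1, "base")]
        ped = pm.validate_pedigree(_frame(rows))
        F = pd.Series({"p1": 0.0, "p2": 0.0, "x": 0.1})
        assert math.isnan(pm.delta_f_pedt(ped, F)["x"])
        assert pm.delta_f_pedt(ped, F, unknown_parent_as_founder=True)["x"] == pytest.approx(0.1)

    def test_delta_f_pedt_fully_inbred_parents_missing(self):
        ped = self._trio()
        F = pd.Series({"p1": 1.0, "p2": 1.0, "x": 1.0})
        with pytest.warns(UserWarning, match="fully inbred"):
            out = pm.delta_f_pedt(ped, F)
        assert math.isnan(out["x"])

    def test_delta_f_pedi_examples(self):
        rows = FOUNDER_PAIR + [
            ("a", "p1", "p2", "M", 1, "base"),
            ("b", "p1", "p2", "F", 1, "base"),
            ("c", "a", "b", "F", 2, "base"),
        ]
        ped = pm.validate_pedigree(_frame(rows))
        F = pd.Series({"p1": 0.0, "p2": 0.0, "a": 0.0, "b": 0.5, "c": 0.75})
        d = pm.delta_f_pedi(ped, F)
        assert math.isnan(d["p1"])  # founders: t = 1, undefined
        assert d["a"] == 0.0
        assert d["b"] == pytest.approx(0.5)  # one generation: dF = F
        assert d["c"] == pytest.approx(0.5)  # (1-0.75)^(1/2) = 0.5

    @given(
        f=st.floats(0.0, 0.999),
        gen=st.integers(1, 40),
    )
    def test_delta_f_pedi_roundtrip(self, f, gen):
        """dF_i <-> F is an exact bijection for fixed generation."""
        ped = pm.validate_pedigree(
            _frame(FOUNDER_PAIR + [("x", "p1", "p2", "F", gen, "base")])
        )
        F = pd.Series({"p1": 0.0, "p2": 0.0, "x": f})
        d = pm.delta_f_pedi(ped, F)["x"]
        t = gen + 1
        assert 1.0 - (1.0 - d) ** (t - 1) == pytest.approx(f, abs=1e-12)


class TestNeFormulas:
    def test_ne_from_rate_signs(self):
        assert pm.ne_from_rate([0.005]) == pytest.approx(100.0)
        assert pm.ne_from_rate([-0.005]) == pytest.approx(-100.0)
        assert pm.ne_from_rate([0.01, np.nan, 0.02]) == pytest.approx(1 / 0.03)
        with pytest.raises(ValueError):
            pm.ne_from_rate([np.nan])
        with pytest.warns(UserWarning):
            assert math.isnan(pm.ne_from_rate([0.01, -0.01]))

    def test_ne_sex_ratio_values(self):
        assert f"{pm.ne_sex_ratio(32, 64):.2f}" == "85.33"
        assert pm.ne_sex_ratio(10, 10) == pytest.approx(20.0)
        assert pm.ne_sex_ratio(1, 1000) == pytest.approx(3.996, abs=5e-4)
        with pytest.raises(ValueError):
            pm.ne_sex_ratio(0, 10)

    @given(m=st.integers(1, 10_000), f=st.integers(1, 10_000))
    def test_ne_sex_ratio_symmetry_and_bound(self, m, f):
        assert pm.ne_sex_ratio(m, f) == pytest.approx(pm.ne_sex_ratio(f, m))
        assert pm.ne_sex_ratio(m, f) <= 4 * min(m, f) + 1e-9

    def test_estimate_t_roundtrips(self):
        assert pm.estimate_t(0.75, 0.5) == pytest.approx(2.0)
        f40 = 1.0 - (1.0 - 0.01) ** 40
        assert pm.estimate_t(f40, 0.01) == pytest.approx(40.0)

    def test_estimate_t_with_printed_reference_means(self):
        """Rounded first-generation homozygosity and sex-ratio Ne bracket the
        founder distances of ~160 and ~132 generations."""
        rate = 1.0 / (2.0 * 85.33)
        assert 155 < pm.estimate_t(0.61, rate) < 165
        assert 128 < pm.estimate_t(0.54, rate) < 138

    def test_estimate_t_domain_errors(self):
        for bad in [(0.0, 0.1), (1.0, 0.1), (0.5, 0.0), (0.5, 1.0)]:
            with pytest.raises(ValueError):
                pm.estimate_t(*bad)
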