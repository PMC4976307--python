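"""Parent-offspring regression heritability and the assortative-mating correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import owlfid as o
from owlfid.regression import RegressionDataset

from tests.conftest import founders


def trio_data(offspring_values=(1.0, 2.0, 3.0)):
    """One brood of measured sibs with measured parents."""
    recs = [
        o.Individual(id="pa", sex="male", habitat="rural"),
        o.Individual(id="ma", sex="female", habitat="rural"),
    ] + [
        o.Individual(id=f"k{i}", sire="pa", dam="ma", habitat="rural")
        for i in range(len(offspring_values))
    ]
    ped = o.validate_pedigree(recs)
    vals = {"pa": 3.0, "ma": 2.0}
    vals.update({f"k{i}": v for i, v in enumerate(offspring_values)})
    phen = pd.DataFrame(
        {"id": list(vals), "log_fid": list(vals.values())}
    )
    return ped, phen


class TestBuildDataset:
    def test_brood_mean_of_full_sibs(self):
        ped, phen = trio_data((1.0, 2.0, 6.0))
        ds = o.build_po_dataset(ped, phen, "midparent")
        assert len(ds) == 1
        row = ds.data.iloc[0]
        assert row["offspring_value"] == pytest.approx(3.0)
        assert row["parent_value"] == pytest.approx(2.5)
        assert row["brood_size"] == 3

    def test_midparent_requires_both_parents_measured(self):
        ped, phen = trio_data((1.0, 2.0))
        phen = phen[phen["id"] != "ma"]  # dam unmeasured
        with pytest.raises(ValueError, match="no usable broods"):
            o.build_po_dataset(ped, phen, "midparent")
        assert len(o.build_po_dataset(ped, phen, "father")) == 1

    def test_unknown_mode(self):
        ped, phen = trio_data()
        with pytest.raises(ValueError, match="unknown mode"):
            o.build_po_dataset(ped, phen, "grandparent")

    def test_father_and_mother_datasets_share_broods(self, default_dataset):
        ds = default_dataset
        father = o.build_po_dataset(ds.pedigree, ds.phenotypes, "father")
        mother = o.build_po_dataset(ds.pedigree, ds.phenotypes, "mother")
        key = ["sire", "dam"]
        merged = father.data.merge(mother.data, on=key, suffixes=("_f", "_m"))
        assert len(merged) > 0
        assert (merged["parent_value_f"] != merged["parent_value_m"]).any()
        assert (merged["offspring_value_f"] == merged["offspring_value_m"]).all()


class TestOlsSlope:
    def test_exact_line(self):
        x = np.arange(4.0)
        b, _, p = o.ols_slope(x, 2.0 * x)
        assert b == pytest.approx(2.0, abs=1e-12)
        assert p < 1e-10

    def test_normal_equations_oracle(self):
        # hand computation: Sxx=5, Sxy=3 -> b=0.6; SSE=0.2, s^2=0.1,
        # se=sqrt(0.1/5)=0.14142; t=4.2426 on 2 df -> p=0.05131
        b, se, p = o.ols_slope([0, 1, 2, 3], [1, 2, 2, 3])
        assert b == pytest.approx(0.6, abs=1e-12)
        assert se == pytest.approx(np.sqrt(0.02), abs=1e-12)
        assert p == pytest.approx(0.051317, abs=1e-5)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            x = rng.normal(size=50)
            ps.append(o.ols_slope(x, rng.normal(size=50))[2])
        assert 0.35 < np.mean(ps) < 0.65  # mean of U(0,1) is 0.5
        assert min(ps) < 0.1 and max(ps) > 0.9

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            o.ols_slope([1, 2], [1, 2])
        with pytest.raises(ValueError):
            o.ols_slope([1, 1, 1], [1, 2, 3])


class TestHeritabilityEstimators:
    def test_offspring_duplicating_midparent_gives_unit_h2(self):
        mp = np.linspace(1, 3, 10)
        data = pd.DataFrame(
            {"parent_value": mp, "offspring_value": mp, "brood_size": 1, "habitat": "rural"}
        )
        est = o.midparent_h2(RegressionDataset(data, "midparent"))
        assert est.h2 == pytest.approx(1.0, abs=1e-12)
        assert est.correction_r is None

    def test_single_parent_doubling_and_correction_limits(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        data = pd.DataFrame(
            {"parent_value": x, "offspring_value": 0.5 * x + rng.normal(0, 0.1, 40),
             "brood_size": 1, "habitat": "rural"}
        )
        ds = RegressionDataset(data, "father")
        b, se, _ = o.ols_slope(data["parent_value"], data["offspring_value"])
        e0 = o.single_parent_h2(ds, 0.0)
        assert e0.h2 == 2.0 * b and e0.se == 2.0 * se  # classical doubling, exact
        e1 = o.single_parent_h2(ds, 1.0)
        assert e1.h2 == pytest.approx(b) and e1.correction_r == 1.0

    @given(st.floats(min_value=-0.9, max_value=0.95))
    @settings(max_examples=30, deadline=None)
    def test_corrected_h2_strictly_decreasing_in_r(self, r):
        data = pd.DataFrame(
            {"parent_value": [0.0, 1.0, 2.0, 3.0], "offspring_value": [1.0, 2.0, 2.0, 3.0],
             "brood_size": 1, "habitat": "rural"}
        )
        ds = RegressionDataset(data, "mother")
        assert o.single_parent_h2(ds, r).h2 > o.single_parent_h2(ds, r + 0.04).h2

    def test_midparent_invariant_to_parent_swap(self, default_dataset):
        # midparent mean is symmetric in sire and dam values
        ds = o.build_po_dataset(default_dataset.pedigree, default_dataset.phenotypes, "midparent")
        log_fid = dict(zip(default_dataset.phenotypes["id"], default_dataset.phenotypes["log_fid"]))
        swapped = ds.data.copy()
        swapped["parent_value"] = [
            0.5 * (log_fid[r.dam] + log_fid[r.sire]) for r in swapped.itertuples()
        ]
        pd.testing.assert_series_equal(swapped["parent_value"], ds.data["parent_value"])

    def test_pseudo_replication_immunity(self):
        # duplicating every offspring within a brood leaves estimates unchanged
        rng = np.random.default_rng(12)
        recs, vals = [], {}
        for k in range(30):
            recs += [
                o.Individual(id=f"s{k}", sex="male", habitat="rural"),
                o.Individual(id=f"d{k}", sex="female", habitat="rural"),
            ]
            vals[f"s{k}"], vals[f"d{k}"] = rng.normal(size=2)
            for j in range(2):
                recs.append(o.Individual(id=f"c{k}_{j}", sire=f"s{k}", dam=f"d{k}", habitat="rural"))
                vals[f"c{k}_{j}"] = rng.normal()
        ped = o.validate_pedigree(recs)
        phen = pd.DataFrame({"id": list(vals), "log_fid": list(vals.values())})
        base = o.midparent_h2(o.build_po_dataset(ped, phen, "midparent"))

        recs2, vals2 = list(recs), dict(vals)
        for k in range(30):
            for j in range(2):
                recs2.append(
                    o.Individual(id=f"c{k}_{j}x", sire=f"s{k}", dam=f"d{k}", habitat="rural")
                )
                vals2[f"c{k}_{j}x"] = vals[f"c{k}_{j}"]
        ped2 = o.validate_pedigree(recs2)
        phen2 = pd.DataFrame({"id": list(vals2), "log_fid": list(vals2.values())})
        dup = o.midparent_h2(o.build_po_dataset(ped2, phen2, "midparent"))
        assert dup.h2 == pytest.approx(base.h2, abs=1e-12)
        assert dup.se == pytest.approx(base.se, abs=1e-12)

    def test_simulation_recovery_at_h2_06(self):
        # midparent slope recovers the founders' h2 (assortative mating does
        # not bias midparent regressions); mean over 30 seeds
        ests = []
        for seed in range(30):
            cfg = o.SimulationConfig(
                n_founders=450, n_generations=2, mean_brood=2.0, h2_true=0.6, seed=seed
            )
            ds = o.simulate_dataset(cfg)
            dset = o.build_po_dataset(ds.pedigree, ds.phenotypes, "midparent")
            ests.append(o.midparent_h2(dset).h2)
        assert np.mean(ests) == pytest.approx(0.6, abs=0.05)


class TestMateCorrelation:
    def test_identical_values_per_pair(self):
        pairs = [(v, v) for v in np.linspace(1, 2, 10)]
        assert o.mate_correlation(pairs) == pytest.approx(1.0)

    def test_sign_flipped_copy(self):
        pairs = [(v, -v) for v in np.linspace(1, 2, 10)]
        assert o.mate_correlation(pairs) == pytest.approx(-1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            o.mate_correlation([(1, 2), (2, 3)])
        with pytest.raises(ValueError):
            o.mate_correlation([(1.0, 2), (1.0, 3), (1.0, 4)])

    def test_recovers_simulated_target(self):
        # generator run at mate_r = 0.72 with ~264 pairs: estimate within the
        # Fisher-z sampling band (+/-0.08)
        cfg = o.SimulationConfig(
            n_founders=530, n_generations=2, mate_r=0.72, seed=6
        )
        ds = o.simulate_dataset(cfg)
        rural = ds.pairs[ds.pairs["habitat"] == "rural"]
        pairs = list(zip(rural["female_value"], rural["male_value"]))
        assert len(pairs) > 200
        assert o.mate_correlation(pairs) == pytest.approx(0.72, abs=0.08)


class TestHeritabilityTable:
    def test_layout_and_correction_bookkeeping(self, default_dataset):
        table = o.heritability_table(default_dataset.pedigree, default_dataset.phenotypes)
        assert set(table["method"]) == {"midparent", "father", "mother"}
        assert set(table["habitat"]) <= {"rural", "urban", "all"}
        single = table[table["method"] != "midparent"]
        assert single["correction_r"].notna().all()
        assert table.loc[table["method"] == "midparent", "correction_r"].isna().all()
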