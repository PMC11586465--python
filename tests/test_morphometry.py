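"""Case-control t-maps, network contrasts, clinical associations, subgroups."""

import numpy as np
import pandas as pd
import pytest

from morphotx import (
    AtrophySpec,
    case_control_map,
    clinical_associations,
    fit_region_model,
    make_atlas,
    network_contrast,
    select_subgroup,
    simulate_cohort,
)
from morphotx.morphometry import _ols_t


def _toy_data(rng, n=60, delta=0.0):
    age = rng.uniform(18, 60, n)
    sex = rng.integers(0, 2, n).astype(float)
    tiv = rng.normal(1500, 100, n)
    group = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
    gmv = 10 - 0.02 * age + 0.3 * sex + 0.001 * tiv - delta * group + rng.normal(size=n)
    return gmv, age, sex, tiv, group


class TestFitRegionModel:
    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        gmv, age, sex, tiv, group = _toy_data(rng, delta=0.5)
        t, p = fit_region_model(gmv, age, sex, tiv, group)
        X = sm.add_constant(np.column_stack([age, sex, tiv, group]))
        fit = sm.OLS(gmv, X).fit()
        assert t == pytest.approx(fit.tvalues[-1])
        assert p == pytest.approx(fit.pvalues[-1])

    def test_affine_invariance_of_t(self, rng):
        gmv, age, sex, tiv, group = _toy_data(rng, delta=1.0)
        t0, _ = fit_region_model(gmv, age, sex, tiv, group)
        t1, _ = fit_region_model(3.7 * gmv + 42.0, age, sex, tiv, group)
        assert t1 == pytest.approx(t0)

    def test_atrophy_gives_negative_unbounded_t(self, rng):
        n = 40
        age, sex = rng.uniform(20, 40, n), rng.integers(0, 2, n).astype(float)
        tiv = rng.normal(1500, 80, n)
        group = np.r_[np.zeros(20), np.ones(20)]
        gmv = 10.0 - 2.0 * group + 1e-9 * rng.normal(size=n)
        t, p = fit_region_model(gmv, age, sex, tiv, group)
        assert t < -1e5
        assert p < 1e-10

    def test_null_t_follows_student_t(self, rng):
        # group-coefficient t under the null vs Student t with n - 5 d.f.
        from scipy.stats import kstest, t as tdist

        n = 30
        age, sex = rng.uniform(20, 40, n), rng.integers(0, 2, n).astype(float)
        tiv = rng.normal(1500, 80, n)
        group = np.r_[np.zeros(15), np.ones(15)]
        X = np.column_stack([np.ones(n), age, sex, tiv, group])
        Y = rng.normal(size=(n, 2000))
        tvals, _ = _ols_t(Y, X, coef_index=4)
        assert kstest(tvals, tdist(n - 5).cdf).pvalue > 1e-3

    def test_collinear_design_rejected(self, rng):
        gmv, age, sex, tiv, group = _toy_data(rng)
        with pytest.raises(np.linalg.LinAlgError):
            fit_region_model(gmv, age, age, tiv, group)  # duplicated predictor


class TestCaseControlMap:
    def test_planted_regions_all_flagged(self, planted_cohort):
        subjects, planted = planted_cohort
        cc = case_control_map(subjects, "TLE")
        assert set(planted).issubset(set(cc.significant_regions.tolist()))
        tab = cc.table.set_index("region_id")
        assert (tab.loc[list(planted), "t"] < 0).all()
        assert np.all(tab["q"].to_numpy() >= tab["p"].to_numpy() - 1e-15)

    def test_single_huge_effect_dominates(self, small_atlas):
        target = int(small_atlas.region_ids[0])
        spec = AtrophySpec((target,), effect_size=20.0)
        subj = simulate_cohort(
            small_atlas, {"HC": 30, "FBTCS+": 30}, atrophy_specs={"FBTCS+": spec}, seed=3
        )
        cc = case_control_map(subj, "FBTCS+")
        assert int(cc.table.loc[cc.table["t"].idxmin(), "region_id"]) == target

    def test_empty_group_rejected(self, small_atlas):
        subj = simulate_cohort(small_atlas, {"HC": 20}, seed=1)
        with pytest.raises(ValueError):
            case_control_map(subj, "FBTCS+")

    def test_patient_vs_patient_contrast(self, planted_cohort):
        subjects, _ = planted_cohort
        cc = case_control_map(subjects, "FBTCS+", control_group="FBTCS-")
        # same atrophy planted in both groups: no systematic difference
        assert cc.table["significant"].sum() <= 2


class TestNetworkContrast:
    def test_seven_networks_in_seven_out(self, planted_cohort, small_atlas):
        subjects, _ = planted_cohort
        for scheme in ("yeo", "veconomo"):
            nc = network_contrast(subjects, small_atlas, scheme, "TLE")
            assert len(nc.table) == 7

    def test_global_atrophy_negative_everywhere(self, small_atlas):
        all_regions = tuple(int(r) for r in small_atlas.region_ids)
        spec = AtrophySpec(all_regions, effect_size=3.0)
        subj = simulate_cohort(
            small_atlas, {"HC": 40, "FBTCS+": 40}, atrophy_specs={"FBTCS+": spec}, seed=6
        )
        nc = network_contrast(subj, small_atlas, "yeo", "FBTCS+")
        assert (nc.table["t"] < 0).all()

    def test_localized_atrophy_hits_its_network(self, small_atlas):
        t = small_atlas.table
        net = "limbic"
        regions = tuple(
            int(r) for r in t.loc[(t.yeo_label == net), "region_id"]
        )
        spec = AtrophySpec(regions, effect_size=3.0)
        subj = simulate_cohort(
            small_atlas, {"HC": 50, "FBTCS+": 50}, atrophy_specs={"FBTCS+": spec}, seed=8
        )
        nc = network_contrast(subj, small_atlas, "yeo", "FBTCS+")
        row = nc.table.set_index("network").loc[net]
        assert row["significant"]
        assert row["t"] == nc.table["t"].min()

    def test_unknown_scheme_rejected(self, planted_cohort, small_atlas):
        subjects, _ = planted_cohort
        with pytest.raises(ValueError):
            network_contrast(subjects, small_atlas, "foo", "TLE")


class TestClinicalAssociations:
    def test_onset_equal_to_gmv_gives_unit_rho(self, planted_cohort):
        subjects, planted = planted_cohort
        cc = case_control_map(subjects, "TLE")
        patients = subjects.select(subjects.table["group"].isin(["FBTCS-", "FBTCS+"]).to_numpy())
        target = str(planted[0])
        patients.table.loc[:, "onset_age"] = patients.table[target].to_numpy()
        assoc = clinical_associations(patients, cc)
        row = assoc["onset_age"].set_index("region_id").loc[planted[0]]
        assert row["rho"] == pytest.approx(1.0)

    def test_no_significant_regions_gives_empty_tables(self, small_atlas):
        subj = simulate_cohort(small_atlas, {"HC": 25, "FBTCS-": 12, "FBTCS+": 13}, seed=21)
        cc = case_control_map(subj, "TLE")
        assert cc.table["significant"].sum() == 0  # nothing planted
        patients = subj.select(subj.table["group"].isin(["FBTCS-", "FBTCS+"]).to_numpy())
        assoc = clinical_associations(patients, cc)
        assert len(assoc["onset_age"]) == 0
        assert len(assoc["seizure_frequency"]) == 0

    def test_independent_frequency_label_is_null(self, planted_cohort):
        subjects, _ = planted_cohort
        cc = case_control_map(subjects, "TLE")
        patients = subjects.select(subjects.table["group"].isin(["FBTCS-", "FBTCS+"]).to_numpy())
        assoc = clinical_associations(patients, cc)
        freq = assoc["seizure_frequency"]
        assert abs(freq["t"].mean()) < 1.0


class TestSelectSubgroup:
    def _subjects(self, small_atlas, years):
        subj = simulate_cohort(small_atlas, {"HC": 5, "FBTCS+": len(years)}, seed=2)
        fb = subj.table["group"] == "FBTCS+"
        subj.table.loc[fb, "years_since_last_fbtcs"] = years
        return subj

    def test_strict_two_year_boundary(self, small_atlas):
        subj = self._subjects(small_atlas, [3.0, 2.0, 1.0, 2.0001])
        remote = select_subgroup(subj, "remote")
        current = select_subgroup(subj, "current")
        assert sorted(remote.table["years_since_last_fbtcs"]) == [2.0001, 3.0]
        assert sorted(current.table["years_since_last_fbtcs"]) == [1.0, 2.0]

    def test_partition_is_exhaustive_and_disjoint(self, small_atlas):
        subj = self._subjects(small_atlas, [0.5, 1.5, 2.5, 4.0, 2.0])
        remote = set(select_subgroup(subj, "remote").table["subject_id"])
        current = set(select_subgroup(subj, "current").table["subject_id"])
        fbtcs = set(subj.table.loc[subj.table["group"] == "FBTCS+", "subject_id"])
        assert remote | current == fbtcs
        assert remote & current == set()

    def test_missing_recency_rejected(self, small_atlas):
        subj = self._subjects(small_atlas, [1.0, np.nan, 3.0])
        with pytest.raises(ValueError, match="years_since_last_fbtcs"):
            select_subgroup(subj, "remote")
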