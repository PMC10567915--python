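"""Cohort statistics: contrasts, MANOVA, Scheffé, hemispheric tests, report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import mrsquant as mq
from mrsquant import tables
from mrsquant.cohort import (build_report, group_manova, hemispheric_contrast,
                             posthoc_scheffe, relative_diff, round_percent)
from mrsquant.errors import (PairingError, RankDeficiencyError, SchemaError,
                             UndefinedContrastError)


class TestRelativeDiff:
    @pytest.mark.parametrize("num,ref,percent", [
        (2.51, 2.70, -7),    # consumers vs male non-users, frontal ATP
        (2.16, 2.43, -11),   # male vs female non-users, right-thalamic ATP
        (3.50, 3.88, -10),   # consumers vs male non-users, left-BG PCr
        (3.22, 3.88, -17),   # right vs left BG PCr, male non-users
        (3.73, 3.33, 12),    # male vs female non-users, left-FWM PCr
        (2.0, 2.0, 0),
    ])
    def test_printed_contrasts(self, num, ref, percent):
        assert relative_diff(num, ref).percent == percent

    def test_zero_reference_rejected(self):
        with pytest.raises(UndefinedContrastError):
            relative_diff(1.0, 0.0)

    @settings(max_examples=60, derandomize=True)
    @given(a=st.floats(0.1, 50.0), b=st.floats(0.1, 50.0))
    def test_reciprocity_invariant(self, a, b):
        """(1 + d_ab)(1 + d_ba) = 1 exactly."""
        d_ab = relative_diff(a, b).fraction
        d_ba = relative_diff(b, a).fraction
        assert (1 + d_ab) * (1 + d_ba) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("frac,percent", [
        (0.045, 5), (-0.045, -5), (0.004, 0), (-0.004, 0), (0.175, 18),
        (-0.175, -18)])
    def test_round_half_away_from_zero(self, frac, percent):
        assert round_percent(frac) == percent


def _wide_cohort(groups, n, means, sds, region="FGM", seed=0):
    """Build a tidy cohort with Gaussian metabolite columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        for i in range(n):
            sid = f"{g}{i:04d}"
            for m, mu in means.items():
                val = rng.normal(mu[g] if isinstance(mu, dict) else mu, sds[m])
                rows.append((sid, g, region, "midline", m, val))
    return pd.DataFrame(rows, columns=["subject_id", "group", "region",
                                       "hemisphere", "metabolite",
                                       "concentration_mmol_per_kg"])


class TestManova:
    def test_identical_groups_lambda_one(self):
        base = _wide_cohort(["mN"], 30, {"PME": 2.3, "Pi": 0.6}, {"PME": 0.2, "Pi": 0.1})
        dup = []
        for g in ("fN", "mC"):
            c = base.copy()
            c["group"] = g
            c["subject_id"] = c["subject_id"].str.replace("mN", g)
            dup.append(c)
        cohort = pd.concat([base] + dup, ignore_index=True)
        res = group_manova(cohort, "FGM", ("PME", "Pi"))
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-12)
        assert res.f_value == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_matches_statsmodels_oracle(self):
        """Wilks Λ and p agree with the statsmodels MANOVA implementation."""
        from statsmodels.multivariate.manova import MANOVA
        means = {"PME": {"fN": 2.3, "mN": 2.1, "mC": 2.2},
                 "Pi": {"fN": 0.65, "mN": 0.6, "mC": 0.55},
                 "PCr": {"fN": 3.6, "mN": 3.5, "mC": 3.4}}
        sds = {"PME": 0.3, "Pi": 0.1, "PCr": 0.4}
        cohort = _wide_cohort(["fN", "mN", "mC"], 25, means, sds, seed=5)
        res = group_manova(cohort, "FGM", ("PME", "Pi", "PCr"))
        wide = cohort.pivot_table(index=["subject_id", "group"], columns="metabolite",
                                  values="concentration_mmol_per_kg").reset_index()
        sm = MANOVA.from_formula("PME + Pi + PCr ~ group", data=wide)
        table = sm.mv_test().results["group"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), rel=1e-8)
        assert res.p_value == pytest.approx(
            float(table.loc["Wilks' lambda", "Pr > F"]), rel=1e-6)

    def test_affine_rescaling_invariance(self):
        means = {"PME": {"fN": 2.3, "mN": 2.1, "mC": 2.2},
                 "Pi": {"fN": 0.65, "mN": 0.6, "mC": 0.55}}
        sds = {"PME": 0.3, "Pi": 0.1}
        cohort = _wide_cohort(["fN", "mN", "mC"], 25, means, sds, seed=6)
        res1 = group_manova(cohort, "FGM", ("PME", "Pi"))
        scaled = cohort.copy()
        mask = scaled["metabolite"] == "Pi"
        scaled.loc[mask, "concentration_mmol_per_kg"] = \
            17.0 * scaled.loc[mask, "concentration_mmol_per_kg"] + 3.0
        res2 = group_manova(scaled, "FGM", ("PME", "Pi"))
        assert res1.wilks_lambda == pytest.approx(res2.wilks_lambda, rel=1e-9)

    def test_rank_deficiency_names_constant_dependent(self):
        cohort = _wide_cohort(["fN", "mN", "mC"], 20, {"PME": 2.3, "Pi": 0.6},
                              {"PME": 0.2, "Pi": 0.0})
        with pytest.raises(RankDeficiencyError) as err:
            group_manova(cohort, "FGM", ("PME", "Pi"))
        assert "Pi" in err.value.dependents

    def test_small_group_rejected(self):
        cohort = _wide_cohort(["fN", "mN"], 2, {"PME": 2.3, "Pi": 0.6, "PCr": 3.5},
                              {"PME": 0.2, "Pi": 0.1, "PCr": 0.3})
        with pytest.raises(SchemaError):
            group_manova(cohort, "FGM", ("PME", "Pi", "PCr"))


class TestScheffe:
    def test_identical_means_p_near_one(self):
        cohort = _wide_cohort(["fN", "mN", "mC"], 200, {"Pi": 0.6}, {"Pi": 0.0},
                              seed=2)
        assert posthoc_scheffe(cohort, "FGM", "Pi", ("mC", "mN")) > 0.99

    def test_conservative_versus_t(self):
        """Scheffé p >= the pooled-variance t-test p on the same contrast."""
        rng = np.random.default_rng(3)
        for seed in range(20):
            means = {"Pi": {"fN": 0.6, "mN": 0.6 + rng.normal(0, 0.05),
                            "mC": 0.6 + rng.normal(0, 0.05)}}
            cohort = _wide_cohort(["fN", "mN", "mC"], 20, means, {"Pi": 0.1},
                                  seed=seed)
            p_s = posthoc_scheffe(cohort, "FGM", "Pi", ("mC", "mN"))
            sub = cohort[cohort["metabolite"] == "Pi"]
            samples = {g: sub[sub["group"] == g]["concentration_mmol_per_kg"].to_numpy()
                       for g in ("fN", "mN", "mC")}
            sse = sum(((x - x.mean()) ** 2).sum() for x in samples.values())
            df = sum(len(x) for x in samples.values()) - 3
            mse = sse / df
            t = (samples["mC"].mean() - samples["mN"].mean()) / np.sqrt(
                mse * (1 / len(samples["mC"]) + 1 / len(samples["mN"])))
            p_t = 2 * sps.t.sf(abs(t), df)
            assert p_s >= p_t - 1e-12

    def test_missing_group_rejected(self):
        cohort = _wide_cohort(["fN", "mN"], 20, {"Pi": 0.6}, {"Pi": 0.1})
        with pytest.raises(SchemaError):
            posthoc_scheffe(cohort, "FGM", "Pi", ("mC", "mN"))


def _paired_cohort(n=26, asym=1.0, cv=0.15, rho=0.7, seed=0, group="mN"):
    """l_BG/r_BG cohort with a controlled right/left PCr ratio ``asym``."""
    mt = tables.phosphorus_mean_table()
    mt = mt[mt["group"] == group].copy()
    mask = (mt["region"] == "r_BG") & (mt["metabolite"] == "PCr")
    left_mean = float(mt.loc[(mt["region"] == "l_BG")
                             & (mt["metabolite"] == "PCr"), "mean"].iloc[0])
    mt.loc[mask, "mean"] = asym * left_mean
    design = mq.CohortDesign(group_sizes={group: n}, mean_table=mt, cv=cv,
                             hemispheric_correlation=rho, seed=seed)
    return mq.simulate_cohort(design)


class TestHemispheric:
    def test_identical_hemispheres_null_sentinels(self):
        cohort = _paired_cohort(seed=4)
        left = cohort[cohort["region"].str.startswith("l_")].copy()
        right = left.copy()
        right["region"] = right["region"].str.replace("l_", "r_")
        right["hemisphere"] = "right"
        sym = pd.concat([left, right], ignore_index=True)
        res = hemispheric_contrast(sym, "BG", groups=("mN",))
        assert res.pooled_p == 1.0
        assert all(c.percent == 0 and c.p_value == 1.0 for c in res.contrasts)

    def test_published_bg_asymmetry_from_mean_table(self):
        """Degenerate cohort at the group means: mN BG PCr shows -17%."""
        cohort = mq.simulate_cohort(mq.CohortDesign(cv=0.0, cv_ph=0.0))
        res = hemispheric_contrast(cohort, "BG")
        row = [c for c in res.contrasts if c.group == "mN" and c.metabolite == "PCr"][0]
        assert row.percent == -17

    def test_power_for_ten_percent_asymmetry(self):
        """n = 26 pairs at CV 15%: a 10% PCr asymmetry detected in >= 90/100."""
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            cohort = _paired_cohort(n=26, asym=0.9, cv=0.15,
                                    seed=int(rng.integers(2**31)))
            res = hemispheric_contrast(cohort, "BG", groups=("mN",))
            row = [c for c in res.contrasts
                   if c.group == "mN" and c.metabolite == "PCr"][0]
            hits += row.p_value < 0.05
        assert hits >= 90

    def test_unpaired_subject_reported(self):
        cohort = _paired_cohort(seed=9)
        broken = cohort[~((cohort["subject_id"] == "mN001")
                          & (cohort["region"] == "r_BG"))]
        with pytest.raises(PairingError) as err:
            hemispheric_contrast(broken, "BG", groups=("mN",))
        assert "mN001" in err.value.subject_ids

    def test_region_stem_required(self):
        cohort = _paired_cohort(seed=9)
        with pytest.raises(SchemaError):
            hemispheric_contrast(cohort, "l_BG")


class TestReport:
    def test_degenerate_report_reproduces_printed_means(self):
        """CV -> 0 cohort reproduces every tabulated group mean to 2 decimals."""
        cohort = mq.simulate_cohort(mq.CohortDesign(cv=0.0, cv_ph=0.0))
        report = build_report(cohort)
        for table_fn, blocks in ((tables.phosphorus_mean_table, report.phosphorus_groups),
                                 (tables.proton_mean_table, report.proton_groups)):
            reference = table_fn()
            for row in reference.itertuples():
                got = blocks[row.region].loc[row.metabolite, row.group]
                assert round(got, 2) == pytest.approx(row.mean, abs=5e-3)

    def test_no_hemispheric_block_for_midline_fgm(self):
        cohort = mq.simulate_cohort(mq.CohortDesign(seed=2))
        report = build_report(cohort)
        assert set(report.hemispheric) <= set(tables.BILATERAL_REGIONS)
        assert "FGM" in report.phosphorus_groups

    def test_serialisation_deterministic(self):
        cohort = mq.simulate_cohort(mq.CohortDesign(seed=3))
        t1 = build_report(cohort).to_tsv()
        t2 = build_report(cohort.copy()).to_tsv()
        assert t1 == t2

    def test_missing_cell_warns_not_raises(self):
        cohort = mq.simulate_cohort(mq.CohortDesign(seed=3))
        partial = cohort[~((cohort["group"] == "mC") & (cohort["region"] == "l_TL"))]
        report = build_report(partial)
        assert any("l_TL" in w for w in report.warnings)
        assert np.isnan(report.phosphorus_groups["l_TL"].loc["PCr", "mC"])

    def test_analysis_object_surface(self):
        cohort = mq.simulate_cohort(mq.CohortDesign(seed=4))
        analysis = mq.CohortAnalysis(cohort)
        report = analysis.fit()
        assert set(report.phosphorus_groups) == set(tables.PHOSPHORUS_REGIONS)
        assert analysis.manova("FGM").p_value <= 1.0
        assert 0.0 <= analysis.scheffe("FGM", "ATP") <= 1.0
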