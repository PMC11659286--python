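"""Mixed-model layer: Tukey degeneracies, transform selection, reporting."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind

import pneumotrace as pt
from pneumotrace.stats import (ModelSpec, fit_lmem, choose_transform,
                               render_report, PAPER_TRANSFORMS)


def _two_group_frame(seed=0, shift=1.0, n=12):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "animal_id": [f"a{i}" for i in range(2 * n)],
        "group": ["SPF"] * n + ["GF"] * n,
        "y": np.r_[rng.normal(0, 1, n), rng.normal(shift, 1, n)],
    })


class TestFitLmem:
    def test_null_constant_data(self):
        df = pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(8) for _ in range(3)],
            "group": (["SPF"] * 12 + ["GF"] * 12),
            "sex": ["F", "M"] * 12,
            "y": 5.0,
        })
        res = fit_lmem(df, ModelSpec(outcome="y"))
        assert np.allclose(res.contrasts["estimate"], 0.0, atol=1e-8)
        assert (res.contrasts["p_tukey"] > 0.99).all()

    def test_balanced_two_group_reduces_to_pooled_t(self):
        df = _two_group_frame()
        res = fit_lmem(df, ModelSpec(outcome="y", fixed=("group",)))
        t, p = ttest_ind(df.y[df.group == "GF"], df.y[df.group == "SPF"])
        assert not res.used_mixed       # one observation per animal
        assert res.contrasts["p_tukey"].iloc[0] == pytest.approx(p, rel=1e-6)

    def test_tukey_never_smaller_than_unadjusted(self):
        rng = np.random.default_rng(3)
        des = pt.CohortDesign(n_per_cell=6, animal_sd=0.5, residual_sd=1.0,
                              seed=4)
        for rep in range(10):
            tab = pt.simulate_outcome_table(des, 10.0, 4,
                                            seed=int(rng.integers(0, 2**31)))
            res = fit_lmem(tab, ModelSpec(outcome="outcome"))
            assert (res.contrasts["p_tukey"] >= res.contrasts["p_unadj"]
                    - 1e-12).all()

    def test_group_effect_recovered(self):
        des = pt.CohortDesign(n_per_cell=12, group_effect=1.0,
                              animal_sd=0.5, residual_sd=0.5, seed=1)
        tab = pt.simulate_outcome_table(des, 10.0, 5, seed=11)
        res = fit_lmem(tab, ModelSpec(outcome="outcome"))
        eff = res.main_effect("group", "GF", "SPF")
        assert eff["ci_low"] <= 1.0 <= eff["ci_high"]
        assert eff["estimate"] == pytest.approx(1.0, abs=0.5)

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            fit_lmem(_two_group_frame(), ModelSpec(outcome="nope",
                                                   fixed=("group",)))

    def test_undersized_cells_rejected(self):
        df = _two_group_frame(n=12).iloc[:13]   # one GF animal only
        with pytest.raises(ValueError):
            fit_lmem(df, ModelSpec(outcome="y", fixed=("group",)))

    def test_log10_on_nonpositive_named_rows(self):
        df = _two_group_frame()
        df.loc[3, "y"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            fit_lmem(df, ModelSpec(outcome="y", transform="log10",
                                   fixed=("group",)))


class TestChooseTransform:
    def test_standard_normal_data_selects_raw_in_auto_mode(self):
        # residuals already normal; log10/sqrt are inapplicable (negatives)
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(40)],
            "group": ["SPF"] * 20 + ["GF"] * 20,
            "y": rng.standard_normal(40),
        })
        best, diag = choose_transform(df, ModelSpec(outcome="y",
                                                    fixed=("group",)),
                                      mode="auto")
        assert best == "raw"
        assert set(diag) == {"raw", "log10", "sqrt"}

    def test_lognormal_outcome_selects_log10(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(120)],
            "group": ["SPF"] * 60 + ["GF"] * 60,
            "y": np.exp(rng.normal(0, 1.2, 120)),
        })
        best, diag = choose_transform(df, ModelSpec(outcome="y",
                                                    fixed=("group",)),
                                      mode="auto")
        assert best == "log10"
        assert diag["log10"]["qq_corr"] > diag["raw"]["qq_corr"]

    def test_table_mode_uses_study_transforms(self):
        df = _two_group_frame()
        df["ti_s"] = np.abs(df["y"]) + 0.1
        best, _ = choose_transform(df, ModelSpec(outcome="ti_s",
                                                 fixed=("group",)),
                                   mode="table")
        assert best == "sqrt" == PAPER_TRANSFORMS["ti_s"]

    def test_log10_skipped_on_nonpositive_data(self):
        df = _two_group_frame()            # has negative values
        best, diag = choose_transform(df, ModelSpec(outcome="y",
                                                    fixed=("group",)),
                                      mode="auto")
        assert diag["log10"].get("skipped") or \
            not np.isfinite(diag["log10"]["qq_corr"])
        assert best in ("raw",)


class TestPowerAndLevel:
    def test_power_monotone_in_effect_size(self):
        # rejection rate nondecreasing with |group effect|
        rng = np.random.default_rng(8)
        rates = []
        for effect in (0.0, 0.8, 2.0):
            rej = 0
            for rep in range(25):
                des = pt.CohortDesign(n_per_cell=6, group_effect=effect,
                                      animal_sd=0.5, residual_sd=0.7,
                                      seed=0)
                tab = pt.simulate_outcome_table(des, 10.0, 4,
                                                seed=int(rng.integers(0, 2**31)))
                res = fit_lmem(tab, ModelSpec(outcome="outcome"))
                rej += (res.contrasts["p_tukey"] < 0.05).any()
            rates.append(rej / 25)
        assert rates[0] <= rates[1] + 0.15
        assert rates[1] <= rates[2] + 0.1
        assert rates[2] > 0.9

    def test_alpha_zero_never_rejects(self):
        des = pt.CohortDesign(n_per_cell=4, animal_sd=0.5, seed=9)
        frac = pt.type1_error_suite(des, n_reps=5, seed=1, alpha=0.0)
        assert frac == 0.0

    def test_nonnull_design_rejected(self):
        with pytest.raises(ValueError):
            pt.type1_error_suite(pt.CohortDesign(n_per_cell=4,
                                                 group_effect=1.0), 5, 1)


class TestRenderReport:
    def _results(self):
        des = pt.CohortDesign(n_per_cell=6, group_effect=1.0, animal_sd=0.4,
                              residual_sd=0.6, seed=10)
        tab = pt.simulate_outcome_table(des, 10.0, 4, seed=12)
        return [fit_lmem(tab, ModelSpec(outcome="outcome"))], tab

    def test_report_deterministic(self, tmp_path):
        results, tab = self._results()
        p1 = render_report(results, tab, tmp_path / "r1")
        p2 = render_report(results, tab, tmp_path / "r2")
        assert p1["json"].read_bytes() == p2["json"].read_bytes()
        assert p1["contrasts"].read_bytes() == p2["contrasts"].read_bytes()

    def test_cell_means_match_brute_force(self, tmp_path):
        results, tab = self._results()
        render_report(results, tab, tmp_path)
        cells = pd.read_csv(tmp_path / "cell_means.tsv", sep="\t")
        # independent aggregation oracle: animal means then cell means
        want = (tab.groupby(["group", "sex", "animal_id"])["outcome"].mean()
                .groupby(["group", "sex"]).mean())
        for (g, s), v in want.items():
            got = cells.loc[cells["cell"] == f"{g}:{s}", "estimate"].iloc[0]
            assert got == pytest.approx(v, abs=0.05)

    def test_empty_contrasts_still_renders(self, tmp_path):
        res = self._results()[0][0]
        res.contrasts = res.contrasts.iloc[:0]
        paths = render_report([res], None, tmp_path)
        payload = json.loads(paths["json"].read_text())
        assert payload["outcomes"][0]["note"] == "no contrasts"
        assert "no contrasts" in paths["txt"].read_text()

    def test_transform_order_preserved_after_backtransform(self):
        # back-transformed cell means keep the raw-scale ordering
        rng = np.random.default_rng(13)
        df = pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(40)],
            "group": ["SPF"] * 20 + ["GF"] * 20,
            "y": np.r_[rng.lognormal(0.0, 0.3, 20),
                       rng.lognormal(0.8, 0.3, 20)],
        })
        res = fit_lmem(df, ModelSpec(outcome="y", transform="log10",
                                     fixed=("group",)))
        cells = res.cell_means.set_index("cell")["estimate"]
        raw_means = df.groupby("group")["y"].mean()
        assert (cells["GF"] > cells["SPF"]) == \
            (raw_means["GF"] > raw_means["SPF"])
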