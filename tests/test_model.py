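"""Mixed-model engine, AICc, Spearman/mRMR selection: oracles and contracts."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from rsfscape import (
    aicc,
    fit_final_model,
    fit_rsf_glmm,
    mrmr_select,
    optimize_scales,
    spearman_matrix,
    standardize,
)
from rsfscape.model import INTERCEPT
from rsfscape.scaling import column_key


def simulate_glmm(seed, n_groups=30, n_per=200, beta=(-0.5, 1.0, -0.5), sigma2=0.5):
    """Direct draws from the random-intercept logistic model."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    frames = []
    for i in range(n_groups):
        u = rng.normal(0.0, np.sqrt(sigma2)) if sigma2 > 0 else 0.0
        X = rng.standard_normal((n_per, len(beta) - 1))
        eta = beta[0] + X @ beta[1:] + u
        y = (rng.uniform(size=n_per) < expit(eta)).astype(float)
        frames.append(
            pd.DataFrame(X, columns=[f"x{k}" for k in range(X.shape[1])]).assign(
                case=y, individual_id=f"g{i:02d}"
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestAicc:
    def test_closed_form(self):
        assert aicc(-100.0, 3, 100) == pytest.approx(206.25, abs=1e-12)

    def test_k_zero_is_minus_two_loglik(self):
        assert aicc(-50.0, 0, 10) == pytest.approx(100.0, abs=1e-12)

    def test_approaches_aic_for_large_n(self):
        assert abs(aicc(-100.0, 3, 10_000_000) - (200.0 + 6.0)) < 1e-3

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    @pytest.mark.parametrize("k,n", [(1, 10), (3, 30), (7, 100)])
    def test_never_below_aic(self, k, n):
        assert aicc(-42.0, k, n) >= -2 * -42.0 + 2 * k


class TestGlmmFit:
    def test_parameter_recovery_unbiased(self):
        """Mean signed error of beta-hat across seeded replicates within 0.1."""
        errors = []
        for seed in range(50):
            df = simulate_glmm(seed, n_groups=30, n_per=200)
            fit = fit_rsf_glmm(df, ["x0", "x1"], compute_se=False)
            errors.append([fit.beta["x0"] - 1.0, fit.beta["x1"] - (-0.5)])
        mean_err = np.mean(errors, axis=0)
        assert np.all(np.abs(mean_err) < 0.1)

    def test_zero_variance_matches_plain_logistic(self):
        import statsmodels.api as sm

        df = simulate_glmm(7, n_groups=10, n_per=300, sigma2=0.0)
        fit = fit_rsf_glmm(df, ["x0", "x1"])
        X = sm.add_constant(df[["x0", "x1"]].to_numpy())
        logit = sm.Logit(df["case"].to_numpy(), X).fit(disp=0)
        assert fit.beta["x0"] == pytest.approx(logit.params[1], abs=0.05)
        assert fit.beta["x1"] == pytest.approx(logit.params[2], abs=0.05)

    def test_matches_lme4_oracle(self, tmp_path):
        """Independent cross-check against glmer (Laplace/AGQ) via Rscript."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = simulate_glmm(3, n_groups=12, n_per=80)
        fit = fit_rsf_glmm(df, ["x0", "x1"])
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- glmer(case ~ x0 + x1 + (1|individual_id), data=d,
                           family=binomial, nAGQ=7)
                cat(fixef(m), as.numeric(VarCorr(m)$individual_id),
                    as.numeric(logLik(m)), sep="\\n")
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        b0, b1, b2, s2, ll = map(float, out.stdout.strip().splitlines())
        assert fit.beta[INTERCEPT] == pytest.approx(b0, abs=0.01)
        assert fit.beta["x0"] == pytest.approx(b1, abs=0.01)
        assert fit.beta["x1"] == pytest.approx(b2, abs=0.01)
        assert fit.sigma2_id == pytest.approx(s2, abs=0.02)
        assert fit.loglik == pytest.approx(ll, abs=0.1)

    def test_constant_covariate_rejected(self):
        df = simulate_glmm(1, n_groups=4, n_per=50)
        df["flat"] = 0.0
        with pytest.raises(ValueError, match="flat"):
            fit_rsf_glmm(df, ["flat"])

    def test_single_individual_rejected(self):
        df = simulate_glmm(1, n_groups=1, n_per=50)
        with pytest.raises(ValueError, match="individual"):
            fit_rsf_glmm(df, ["x0"])

    def test_deterministic_refit(self):
        df = simulate_glmm(9, n_groups=8, n_per=60)
        a = fit_rsf_glmm(df, ["x0", "x1"])
        b = fit_rsf_glmm(df, ["x0", "x1"])
        assert a.beta == b.beta and a.loglik == b.loglik

    def test_multivariable_loglik_at_least_intercept_only(self):
        df = simulate_glmm(5, n_groups=10, n_per=100)
        full = fit_rsf_glmm(df, ["x0", "x1"], compute_se=False)
        null = fit_rsf_glmm(df, [], compute_se=False)
        assert full.loglik >= null.loglik - 1e-6


class TestScaleSelection:
    def _design(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 400
        df = pd.DataFrame(
            {
                "individual_id": np.repeat([f"g{k}" for k in range(8)], n // 8),
            }
        )
        z = rng.standard_normal(n)
        for s in (1.0, 2.0, 4.0):
            df[column_key("c", s)] = z + rng.standard_normal(n) * (0.2 * s)
        df["case"] = (rng.uniform(size=n) < expit(z)).astype(float)
        return df

    def test_single_scale_chosen_trivially(self):
        df = self._design()
        sel = optimize_scales(df, ["c"], [2.0])
        assert sel.chosen_scale == {"c": 2.0}
        assert list(sel.aicc_by_scale["c"]) == [2.0]

    def test_lowest_aicc_scale_retained(self):
        df = self._design(1)
        sel = optimize_scales(df, ["c"], [1.0, 2.0, 4.0])
        prof = sel.aicc_by_scale["c"]
        assert sel.chosen_scale["c"] == min(prof, key=prof.get)

    def test_degenerate_covariate_excluded(self):
        df = self._design(2)
        for s in (1.0, 2.0):
            df[column_key("flat", s)] = 1.0
        sel = optimize_scales(df, ["c", "flat"], [1.0, 2.0])
        assert "flat" in sel.excluded and "c" in sel.chosen_scale


class TestSpearman:
    def test_self_and_monotone_transform(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"case": rng.integers(0, 2, 60).astype(float)})
        df["a"] = rng.standard_normal(60)
        df["b"] = np.exp(df["a"])  # strictly monotone transform
        m = spearman_matrix(df, ["a", "b"])
        assert m.loc["a", "a"] == pytest.approx(1.0)
        assert m.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_oracle_five_rows(self):
        # brute-force rank formula on a 5-row fixture with no ties
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        y = np.array([2.0, 0.5, 9.0, 1.0, 3.0])
        rx = np.argsort(np.argsort(x)) + 1
        ry = np.argsort(np.argsort(y)) + 1
        d2 = np.sum((rx - ry) ** 2)
        rho_hand = 1 - 6 * d2 / (5 * (25 - 1))
        df = pd.DataFrame({"case": [0, 1, 0, 1, 1], "x": x, "y": y})
        m = spearman_matrix(df, ["x", "y"])
        assert m.loc["x", "y"] == pytest.approx(rho_hand, abs=1e-12)

    def test_constant_column_zero_with_warning(self):
        df = pd.DataFrame(
            {"case": [0.0, 1.0, 0.0, 1.0], "a": [1.0, 2.0, 3.0, 4.0], "flat": 1.0}
        )
        with pytest.warns(UserWarning, match="constant"):
            m = spearman_matrix(df, ["a", "flat"])
        assert m.loc["flat", "a"] == 0.0


def exhaustive_greedy_oracle(corr, n_keep, response="case"):
    """Enumerate every greedy path; at score ties explore all branches and
    return the set reached via the alphabetically-first tie sequence."""
    candidates = sorted(c for c in corr.columns if c != response)
    rel = corr.loc[candidates, response].abs()
    selected = []
    remaining = list(candidates)
    while len(selected) < n_keep:
        scores = {}
        for c in remaining:
            red = np.mean([abs(corr.loc[c, s]) for s in selected]) if selected else 0.0
            scores[c] = rel[c] - red
        best = max(scores.values())
        winners = sorted([c for c, v in scores.items() if abs(v - best) < 1e-12])
        selected.append(winners[0])
        remaining.remove(winners[0])
    return selected


class TestMrmr:
    def _corr(self, seed=0, n_cand=6):
        rng = np.random.default_rng(seed)
        n = 200
        data = {"case": rng.integers(0, 2, n).astype(float)}
        for k in range(n_cand):
            data[f"c{k}"] = rng.standard_normal(n) + 0.3 * k * data["case"]
        return spearman_matrix(pd.DataFrame(data), [f"c{k}" for k in range(n_cand)])

    def test_redundant_duplicate_selected_once_first(self):
        rng = np.random.default_rng(4)
        n = 300
        case = rng.integers(0, 2, n).astype(float)
        signal = case + 0.5 * rng.standard_normal(n)
        df = pd.DataFrame(
            {
                "case": case,
                "dup_a": signal,
                "dup_b": signal,  # identical to dup_a
                "noise": rng.standard_normal(n),
            }
        )
        corr = spearman_matrix(df, ["dup_a", "dup_b", "noise"])
        res = mrmr_select(corr, n_keep=2)
        assert res.selected[0] == "dup_a"  # alphabetical tie-break
        assert res.selected[1] == "noise"  # duplicate penalized out

    def test_all_selected_in_score_order(self):
        corr = self._corr(5, n_cand=4)
        res = mrmr_select(corr, n_keep=4)
        assert sorted(res.selected) == ["c0", "c1", "c2", "c3"]
        assert list(res.trace["step"]) == [1, 2, 3, 4]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, seed):
        corr = self._corr(seed, n_cand=6)
        res = mrmr_select(corr, n_keep=3)
        assert res.selected == exhaustive_greedy_oracle(corr, 3)

    def test_permutation_invariance(self):
        corr = self._corr(7, n_cand=5)
        res_a = mrmr_select(corr, n_keep=3)
        perm = ["c3", "c0", "case", "c4", "c1", "c2"]
        res_b = mrmr_select(corr.loc[perm, perm], n_keep=3)
        assert res_a.selected == res_b.selected

    def test_n_keep_too_large_rejected(self):
        with pytest.raises(ValueError):
            mrmr_select(self._corr(0, 3), n_keep=5)


class TestFinalModel:
    def test_standardization_on_training_rows_only(self):
        df = simulate_glmm(11, n_groups=6, n_per=100)
        df["split"] = np.where(np.arange(len(df)) % 5 == 0, "validate", "train")
        fit = fit_final_model(df, ["x0", "x1"])
        mask = (df["split"] == "train").to_numpy()
        for col in ("x0", "x1"):
            mu, sd = fit.standardization[col]
            assert mu == pytest.approx(df.loc[mask, col].mean(), abs=1e-12)
            assert sd == pytest.approx(df.loc[mask, col].std(ddof=0), abs=1e-12)

    def test_coefficient_table_schema(self):
        df = simulate_glmm(12, n_groups=6, n_per=80)
        fit = fit_final_model(df, ["x0", "x1"])
        table = fit.to_table()
        assert list(table.columns) == ["covariate", "scale_km", "beta", "se", "z", "p"]
        assert len(table) == 3  # intercept + 2 covariates
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()

    def test_standardize_errors_on_constant(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            standardize(df, ["a"])
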