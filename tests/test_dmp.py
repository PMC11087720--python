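"""Differential-methylation statistics: OLS oracle equivalence, variance
moderation limits and limma agreement, BH step-up, probe selection, and
iterative case pruning."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from episig.dmp import (
    SelectionParams,
    bh_fdr,
    compute_delta_beta,
    dmp_table,
    ebayes_moderate,
    fit_probe_models,
    fit_variance_prior,
    iterative_case_pruning,
    select_probes,
)
from episig.exceptions import (
    ArgumentError,
    DegenerateVarianceError,
    InstabilityError,
    ModelError,
    SelectionError,
)
from episig.simulate import SimulationConfig, simulate_cohort


def _m_frame(values, sheet):
    return pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"p{i}" for i in range(len(values))],
        columns=sheet["sample_id"],
    )


def _sheet(groups):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(groups))],
            "group": groups,
            "age": 10.0,
            "sex": "F",
            "cohort": "c",
        }
    )


class TestFitProbeModels:
    def test_exact_separation(self):
        sheet = _sheet(["case"] * 3 + ["control"] * 3)
        m = _m_frame([[1, 1, 1, 0, 0, 0]], sheet)
        fit = fit_probe_models(m, sheet, covariates=())
        assert fit["coef"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert fit["s2"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert fit["df"].iloc[0] == 4

    def test_matches_normal_equations_oracle(self, tiny_sheet):
        rng = np.random.default_rng(11)
        m = _m_frame(rng.normal(0, 1, (5, 8)), tiny_sheet)
        fit = fit_probe_models(m, tiny_sheet)
        from episig.dmp import build_design

        x = build_design(tiny_sheet).to_numpy()
        for i in range(5):
            y = m.iloc[i].to_numpy()
            coefs = np.linalg.solve(x.T @ x, x.T @ y)
            assert fit["coef"].iloc[i] == pytest.approx(coefs[1], abs=1e-10)
            resid = y - x @ coefs
            s2 = resid @ resid / (8 - x.shape[1])
            assert fit["s2"].iloc[i] == pytest.approx(s2, abs=1e-10)

    def test_orthogonal_covariate_leaves_coef_unchanged(self):
        # balanced design with a covariate orthogonal to the group contrast
        sheet = _sheet(["case"] * 4 + ["control"] * 4)
        sheet["age"] = [5.0, 15.0, 5.0, 15.0, 5.0, 15.0, 5.0, 15.0]
        rng = np.random.default_rng(2)
        m = _m_frame(rng.normal(0, 1, (6, 8)), sheet)
        with_cov = fit_probe_models(m, sheet, covariates=("age",))
        without = fit_probe_models(m, sheet, covariates=())
        assert np.allclose(with_cov["coef"], without["coef"], atol=1e-10)

    def test_rank_deficient_design_named(self):
        sheet = _sheet(["case"] * 3 + ["control"] * 3)
        sheet["age"] = 7.0  # constant: collinear with the intercept
        m = _m_frame(np.random.default_rng(0).normal(size=(2, 6)), sheet)
        with pytest.raises(ModelError, match="age|intercept"):
            fit_probe_models(m, sheet, covariates=("age",))


class TestEbayes:
    @staticmethod
    def _random_fit(n_probes=200, n=20, seed=4, hetero=True):
        sheet = _sheet(["case"] * (n // 2) + ["control"] * (n - n // 2))
        rng = np.random.default_rng(seed)
        sd = np.exp(rng.normal(0, 0.8, n_probes)) if hetero else np.ones(n_probes)
        m = _m_frame(rng.normal(0, 1, (n_probes, n)) * sd[:, None], sheet)
        return fit_probe_models(m, sheet, covariates=())

    def test_d0_zero_recovers_ordinary_t(self):
        fit = self._random_fit()
        _, mod = ebayes_moderate(fit, d0=0)
        ordinary = fit["coef"] / (np.sqrt(fit["s2"]) * fit["se_unit"])
        assert np.allclose(mod["t_mod"], ordinary, atol=1e-8)

    def test_infinite_d0_full_shrinkage(self):
        fit = self._random_fit()
        prior, mod = ebayes_moderate(fit, d0=np.inf, s0_sq=0.7)
        assert np.allclose(mod["s2_post"], 0.7)

    def test_null_p_values_uniform(self):
        from scipy.stats import kstest

        fit = self._random_fit(n_probes=200, n=20)
        _, mod = ebayes_moderate(fit)
        assert kstest(mod["p"], "uniform").statistic < 0.1

    def test_posterior_blends_toward_prior(self):
        fit = self._random_fit()
        prior, mod = ebayes_moderate(fit)
        assert 0 < prior.d0 < np.inf
        raw, post = fit["s2"].to_numpy(), mod["s2_post"].to_numpy()
        # moderation pulls extreme variances toward s0_sq
        assert post[np.argmax(raw)] < raw.max()
        assert post[np.argmin(raw)] > raw.min()

    def test_all_zero_variances_degenerate(self):
        fit = self._random_fit(n_probes=5)
        fit["s2"] = 0.0
        with pytest.raises(DegenerateVarianceError):
            fit_variance_prior(fit["s2"].to_numpy(), float(fit["df"].iloc[0]))

    def test_matches_limma(self, tmp_path):
        """Moderated t and p agree with Bioconductor limma's eBayes on the
        same design (independent reference implementation)."""
        rng = np.random.default_rng(42)
        n_probes, n = 80, 12
        sheet = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "group": ["case"] * 6 + ["control"] * 6,
                "age": rng.uniform(5, 30, n).round(1),
                "sex": rng.choice(["F", "M"], n),
                "cohort": "c",
            }
        )
        sd = np.exp(rng.normal(0, 0.8, n_probes))
        m = pd.DataFrame(
            rng.normal(0, 1, (n_probes, n)) * sd[:, None],
            index=[f"p{i}" for i in range(n_probes)],
            columns=sheet["sample_id"],
        )
        fit = fit_probe_models(m, sheet)
        prior, mod = ebayes_moderate(fit)

        m.to_csv(tmp_path / "m.tsv", sep="\t")
        sheet.to_csv(tmp_path / "sheet.csv", index=False)
        script = tmp_path / "limma.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            "m <- as.matrix(read.delim('m.tsv', row.names=1, check.names=FALSE))\n"
            "sheet <- read.csv('sheet.csv')\n"
            "design <- model.matrix(~ factor(group, levels=c('control','case'))"
            " + age + (sex=='F'), data=sheet)\n"
            "fit <- eBayes(lmFit(m, design))\n"
            "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior)\n"
            "write.table(out, 'limma.tsv', sep='\\t', quote=FALSE)\n"
        )
        subprocess.run(
            ["Rscript", "limma.R"], cwd=tmp_path, check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        assert prior.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-6)
        assert np.allclose(mod["t_mod"].to_numpy(), ref["t"].to_numpy(), atol=1e-8)
        assert np.allclose(mod["p"].to_numpy(), ref["p"].to_numpy(), atol=1e-8)


def bh_oracle(p):
    """Exhaustive step-up: q(i) = min over j>=i of p(j)*m/j on the sorted
    p-values, mapped back to input order and clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, idx in enumerate(order):
        q[idx] = min(
            min(p[order[j]] * m / (j + 1) for j in range(rank_i, m)), 1.0
        )
    return q


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.05], [0.05]),
            ([0.01, 0.04, 0.90], [0.03, 0.06, 0.90]),
        ],
    )
    def test_hand_computed(self, p, expected):
        assert np.allclose(bh_fdr(p), expected, atol=1e-12)

    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exhaustive_step_up(self, p):
        assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ArgumentError):
            bh_fdr([])


class TestDeltaBeta:
    def test_constant_groups(self):
        sheet = _sheet(["case"] * 3 + ["control"] * 3)
        beta = _m_frame([[0.6, 0.6, 0.6, 0.5, 0.5, 0.5]], sheet)
        assert compute_delta_beta(beta, sheet).iloc[0] == pytest.approx(0.10)

    def test_identical_groups_zero(self):
        sheet = _sheet(["case"] * 3 + ["control"] * 3)
        beta = _m_frame([[0.4] * 6], sheet)
        assert compute_delta_beta(beta, sheet).iloc[0] == 0.0

    def test_matches_two_mean_oracle(self):
        sheet = _sheet(["case"] * 3 + ["control"] * 3)
        rng = np.random.default_rng(1)
        beta = _m_frame(rng.uniform(0, 1, (4, 6)), sheet)
        db = compute_delta_beta(beta, sheet)
        for i in range(4):
            row = beta.iloc[i].to_numpy()
            assert db.iloc[i] == row[:3].mean() - row[3:].mean()

    def test_missing_group_rejected(self):
        sheet = _sheet(["case"] * 6)
        beta = _m_frame([[0.5] * 6], sheet)
        with pytest.raises(ArgumentError):
            compute_delta_beta(beta, sheet)


class TestSelectProbes:
    def test_recovery_on_planted_truth(self, small_cohort):
        beta, sheet, truth = small_cohort
        probe_set = select_probes(dmp_table(beta, sheet), beta, sheet)
        selected = set(probe_set.probe_ids)
        precision = len(selected & truth.planted_set) / len(selected)
        assert precision >= 0.8

    def test_duplicated_probe_pruned(self, small_cohort):
        beta, sheet, truth = small_cohort
        table = dmp_table(beta, sheet)
        top = table.sort_values("rank_score", ascending=False).index[0]
        dup_beta = pd.concat([beta, beta.loc[[top]].rename(index={top: "dup"})])
        dup_table = pd.concat([table, table.loc[[top]].rename(index={top: "dup"})])
        probe_set = select_probes(dup_table, dup_beta, sheet)
        assert (top in probe_set.probe_ids) != ("dup" in probe_set.probe_ids)

    def test_truncation_only(self, small_cohort):
        beta, sheet, _ = small_cohort
        table = dmp_table(beta, sheet)
        params = SelectionParams(q_max=1.0, min_abs_delta=0.0, top_n=3, corr_max=1.0)
        probe_set = select_probes(table, beta, sheet, params)
        expected = table.sort_values("rank_score", ascending=False).index[:3]
        assert set(probe_set.probe_ids) == set(expected)

    def test_nothing_passes_reports_thresholds(self, small_cohort):
        beta, sheet, _ = small_cohort
        table = dmp_table(beta, sheet)
        with pytest.raises(SelectionError, match="strictest passing"):
            select_probes(table, beta, sheet, SelectionParams(q_max=1e-300, min_abs_delta=0.9))

    def test_invariant_to_row_and_column_order(self, small_cohort):
        beta, sheet, _ = small_cohort
        rng = np.random.default_rng(0)
        beta_perm = beta.iloc[rng.permutation(len(beta))]
        beta_perm = beta_perm.iloc[:, rng.permutation(beta.shape[1])]
        sheet_perm = sheet.iloc[rng.permutation(len(sheet))].reset_index(drop=True)
        a = select_probes(dmp_table(beta, sheet), beta, sheet)
        b = select_probes(dmp_table(beta_perm, sheet_perm), beta_perm, sheet_perm)
        assert a.probe_ids == b.probe_ids


class TestCasePruning:
    @staticmethod
    def _cohort(seed, n_negative=3):
        cfg = SimulationConfig(
            seed=seed, n_probes=6000, n_cases=20, n_controls=30, n_true_dmps=150,
            n_negative_cases=n_negative,
        )
        return simulate_cohort(cfg)

    def test_removes_exactly_the_planted_negatives(self):
        beta, sheet, truth = self._cohort(31)
        result = iterative_case_pruning(beta, sheet, seed=31)
        assert set(result.removed_case_ids) == truth.negative_case_ids

    def test_clean_cohort_removes_nothing(self):
        beta, sheet, _ = self._cohort(32, n_negative=0)
        result = iterative_case_pruning(beta, sheet, seed=32)
        assert result.removed_case_ids == []
        assert (result.rounds["round"] == 1).all()

    def test_idempotent_on_retained_cohort(self):
        beta, sheet, truth = self._cohort(33)
        first = iterative_case_pruning(beta, sheet, seed=33)
        retained = sheet[~sheet["sample_id"].isin(first.removed_case_ids)]
        second = iterative_case_pruning(beta, retained, seed=33)
        assert second.removed_case_ids == []

    def test_all_negative_cases_unstable(self):
        beta, sheet, _ = self._cohort(34, n_negative=20)
        with pytest.raises(InstabilityError):
            iterative_case_pruning(beta, sheet, seed=34)

    def test_small_cohort_rejected(self):
        cfg = SimulationConfig(seed=1, n_probes=200, n_cases=4, n_controls=4, n_true_dmps=10)
        beta, sheet, _ = simulate_cohort(cfg)
        with pytest.raises(ArgumentError, match=">= 10"):
            iterative_case_pruning(beta, sheet)
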