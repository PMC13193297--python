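import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from exposim.measures import REGISTRY
from exposim.synth import DEFAULT_CELL_MEANS, GeneratorConfig, generate_trial
from exposim.analysis import (
    BinomialOutcome,
    analyze_endpoint,
    analyze_trial,
    build_contrasts,
    cohens_d,
    fit_marginal_binomial,
    holm_adjust,
    rescale_to_binomial,
)


def holm_oracle(p):
    """Brute-force step-down reference: walk the sorted sequence directly."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    best = 0.0
    for rank, idx in enumerate(order):
        candidate = min(1.0, (m - rank) * p[idx])
        best = max(best, candidate)
        adj[idx] = best
    return adj


class TestRescale:
    def test_tbes_score(self):
        out = rescale_to_binomial(21, REGISTRY["tbes"])
        assert (out.successes, out.trials) == (21, 84)

    def test_self_efficacy_minimum(self):
        out = rescale_to_binomial(27, REGISTRY["self_efficacy"])
        assert (out.successes, out.trials) == (0, 108)

    def test_knowledge_percent(self):
        out = rescale_to_binomial(50.0, REGISTRY["knowledge"])
        assert (out.successes, out.trials) == (50.0, 100)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            rescale_to_binomial(85, REGISTRY["tbes"])
        with pytest.raises(ValueError):
            rescale_to_binomial(26, REGISTRY["self_efficacy"])

    @given(st.floats(0, 84))
    @settings(max_examples=40, deadline=None)
    def test_roundtrip(self, score):
        spec = REGISTRY["tbes"]
        out = rescale_to_binomial(score, spec)
        assert out.successes + spec.total_min == pytest.approx(score)

    def test_invalid_outcome_rejected(self):
        with pytest.raises(ValueError):
            BinomialOutcome(successes=90, trials=84)


class TestBuildContrasts:
    def test_sixteen_hypotheses(self):
        assert len(build_contrasts()) == 16

    def test_family_sizes(self):
        cset = build_contrasts()
        assert len(cset.family("within_change")) == 8
        assert len(cset.family("cross_sectional")) == 4
        assert len(cset.family("change_difference")) == 4

    def test_vectors_sum_to_zero(self):
        for c in build_contrasts().contrasts:
            assert sum(c.vector) == pytest.approx(0.0)

    def test_change_definitions(self):
        labels = [c.label for c in build_contrasts().family("within_change")]
        assert labels == [
            "hmd:T1-T0", "hmd:T2-T1", "hmd:T3-T1", "hmd:T3-T2",
            "desktop:T1-T0", "desktop:T2-T1", "desktop:T3-T1", "desktop:T3-T2",
        ]

    def test_two_arms_required(self):
        with pytest.raises(ValueError):
            build_contrasts(arms=("only",))


class TestHolm:
    def test_worked_example(self):
        assert holm_adjust([0.001, 0.02, 0.04]) == pytest.approx(
            [0.003, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert holm_adjust([0.37]) == pytest.approx([0.37])

    def test_sixteen_equal_p(self):
        assert holm_adjust([0.05] * 16) == pytest.approx([0.8] * 16)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 20))
            assert holm_adjust(p) == pytest.approx(holm_oracle(p))

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(0, 1, size=16)
            _, ref, _, _ = multipletests(p, method="holm")
            assert holm_adjust(p) == pytest.approx(ref)

    def test_never_below_raw_and_bonferroni_for_smallest(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 0.2, size=16)
        adj = holm_adjust(p)
        assert (adj >= p).all()
        assert adj[np.argmin(p)] == pytest.approx(min(1.0, 16 * p.min()))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, size=10)
        perm = rng.permutation(10)
        assert holm_adjust(p[perm]) == pytest.approx(holm_adjust(p)[perm])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            holm_adjust([])


class TestFitMarginalBinomial:
    def test_saturated_fit_matches_tabulation(self):
        ds = generate_trial(GeneratorConfig(seed=1))
        for measure in ("tbes", "self_efficacy", "knowledge"):
            spec = REGISTRY[measure]
            res = fit_marginal_binomial(ds.data, measure)
            sub = ds.data[ds.data.measure == measure]
            emp = sub.groupby(["arm", "timepoint"], sort=False)["score"].mean()
            for i, cell in enumerate(res.cells):
                arm, tp = cell.split(":")
                expected = (emp[(arm, tp)] - spec.total_min) / spec.trials
                assert expit(res.params[i]) == pytest.approx(expected, abs=1e-8)

    def test_exchangeable_option(self):
        ds = generate_trial(GeneratorConfig(seed=1))
        res = fit_marginal_binomial(ds.data, "tbes", "exchangeable")
        assert res.working_correlation == "exchangeable"
        assert np.all(np.isfinite(res.params))

    def test_unknown_working_correlation(self):
        ds = generate_trial(GeneratorConfig(seed=1))
        with pytest.raises(ValueError):
            fit_marginal_binomial(ds.data, "tbes", "ar1")

    def test_missing_measure_rejected(self):
        ds = generate_trial(GeneratorConfig(seed=1))
        with pytest.raises(ValueError):
            fit_marginal_binomial(ds.data, "sus")

    def test_single_observation_clusters_equal_glm_hc0(self):
        # with one participant per cluster and independence working
        # correlation, the sandwich must coincide with the robust covariance
        # of the equivalent generalized linear fit
        ds = generate_trial(GeneratorConfig(seed=3))
        sub = ds.data[ds.data.measure == "tbes"].copy()
        sub["participant_id"] = np.arange(len(sub))
        res = fit_marginal_binomial(sub, "tbes")
        exog = pd.DataFrame(
            {c: ((sub.arm + ":" + sub.timepoint) == c).astype(float) for c in res.cells}
        ).to_numpy()
        glm = sm.GLM(
            (sub.score / 84).to_numpy(), exog, family=sm.families.Binomial()
        ).fit(cov_type="HC0")
        assert res.params == pytest.approx(np.asarray(glm.params), abs=1e-8)
        assert res.cov == pytest.approx(np.asarray(glm.cov_params()), abs=1e-10)

    def test_large_n_parameter_recovery(self):
        # marginal truth under the logit-normal mixture via quadrature
        sd = 0.4
        cfg = GeneratorConfig(
            n_per_arm={"hmd": 2000, "desktop": 2000},
            measures=("tbes",),
            cell_means={"tbes": DEFAULT_CELL_MEANS["tbes"]},
            subject_sd=sd,
            seed=9,
        )
        ds = generate_trial(cfg)
        res = fit_marginal_binomial(ds.data, "tbes")
        x, w = np.polynomial.hermite_e.hermegauss(61)
        for i, cell in enumerate(res.cells):
            arm, tp = cell.split(":")
            p = DEFAULT_CELL_MEANS["tbes"][arm][tp] / 84
            marginal = np.sum(w * expit(logit(p) + sd * x)) / np.sum(w)
            assert expit(res.params[i]) == pytest.approx(marginal, abs=0.01)

    def test_degenerate_cell_continuity_adjustment(self):
        records = []
        for i in range(8):
            arm = "hmd" if i < 4 else "desktop"
            for tp in ("T0", "T1"):
                score = 0 if (arm == "hmd" and tp == "T0") else 20 + i
                records.append(
                    {
                        "participant_id": f"P{i}",
                        "arm": arm,
                        "timepoint": tp,
                        "measure": "tbes",
                        "score": score,
                    }
                )
        df = pd.DataFrame(records)
        res = fit_marginal_binomial(df, "tbes")
        assert np.all(np.isfinite(res.params))
        i = res.cells.index("hmd:T0")
        assert expit(res.params[i]) == pytest.approx(0.5 / 84, rel=1e-3)


class TestCohensD:
    def make_change_data(self, t0, t1, arm="hmd"):
        rows = []
        for i, (a, b) in enumerate(zip(t0, t1)):
            rows.append({"participant_id": f"P{i}", "arm": arm,
                         "timepoint": "T0", "measure": "tbes", "score": a})
            rows.append({"participant_id": f"P{i}", "arm": arm,
                         "timepoint": "T1", "measure": "tbes", "score": b})
        return pd.DataFrame(rows)

    def contrast(self, label):
        return next(c for c in build_contrasts().contrasts if c.label == label)

    def test_zero_variance_raises(self):
        df = self.make_change_data([10, 20, 30], [15, 25, 35])
        with pytest.raises(ZeroDivisionError):
            cohens_d(df, "tbes", self.contrast("hmd:T1-T0"))

    def test_balanced_changes_give_zero(self):
        df = self.make_change_data([10, 20], [11, 19])
        assert cohens_d(df, "tbes", self.contrast("hmd:T1-T0")) == pytest.approx(0.0)

    def test_simulated_standardized_change(self):
        rng = np.random.default_rng(12)
        n = 5000
        t0 = 40 + rng.normal(0, 5, n)
        t1 = t0 + rng.normal(4, 5, n)  # true d = 4/5 = 0.8
        df = self.make_change_data(t0, t1)
        d = cohens_d(df, "tbes", self.contrast("hmd:T1-T0"))
        assert d == pytest.approx(0.8, abs=0.05)

    def test_cross_sectional_pooled_sd(self):
        rng = np.random.default_rng(13)
        n = 4000
        x = 40 + rng.normal(0, 6, n)
        y = 34 + rng.normal(0, 6, n)  # true d = 1.0
        df = pd.concat(
            [
                self.make_change_data(x, x, arm="hmd"),
                self.make_change_data(y, y, arm="desktop").assign(
                    participant_id=lambda f: "D" + f.participant_id
                ),
            ]
        )
        d = cohens_d(df, "tbes", self.contrast("hmd-desktop:T0"))
        assert d == pytest.approx(1.0, abs=0.06)


@pytest.fixture(scope="module")
def report():
    return analyze_trial(generate_trial(GeneratorConfig(seed=1)))


class TestAnalyzeTrial:
    def test_sixteen_rows_per_measure(self, report):
        frame = report.contrast_frame()
        assert frame.groupby("measure").size().eq(16).all()
        assert set(report.measures) == {"knowledge", "self_efficacy", "tbes"}

    def test_adjusted_at_least_raw(self, report):
        frame = report.contrast_frame()
        assert (frame["p_holm"] >= frame["p_raw"] - 1e-15).all()

    def test_adjusted_monotone_in_raw_order(self, report):
        for ma in report.measures.values():
            f = ma.contrasts.sort_values("p_raw")
            assert f["p_holm"].is_monotonic_increasing

    def test_cis_contain_estimates(self, report):
        frame = report.contrast_frame()
        assert (frame["ci_low"] <= frame["estimate"]).all()
        assert (frame["estimate"] <= frame["ci_high"]).all()

    def test_cell_table_structure(self, report):
        cells = report.cell_frame()
        assert len(cells) == 3 * 8
        assert (cells["ci_low"] <= cells["mean"]).all()
        assert (cells["mean"] <= cells["ci_high"]).all()

    def test_json_and_csv_outputs(self, report, tmp_path):
        report.to_csv(tmp_path / "contrasts.csv")
        report.to_json(tmp_path / "report.json")
        back = pd.read_csv(tmp_path / "contrasts.csv")
        assert len(back) == 48

    def test_t_reference_distribution(self):
        ds = generate_trial(GeneratorConfig(seed=2))
        normal = analyze_trial(ds, measures=["tbes"])
        heavy = analyze_trial(ds, measures=["tbes"], dist="t", df=117)
        pn = normal.measures["tbes"].contrasts["p_raw"]
        pt = heavy.measures["tbes"].contrasts["p_raw"]
        assert (pt >= pn - 1e-12).all()

    def test_t_requires_df(self):
        ds = generate_trial(GeneratorConfig(seed=2))
        with pytest.raises(ValueError):
            analyze_trial(ds, measures=["tbes"], dist="t")


class TestAnalyzeEndpoint:
    def make_endpoint(self, hmd_scores, desktop_scores, measure="sus"):
        rows = []
        for i, s in enumerate(hmd_scores):
            rows.append({"participant_id": f"H{i}", "arm": "hmd",
                         "timepoint": "T2", "measure": measure, "score": s})
        for i, s in enumerate(desktop_scores):
            rows.append({"participant_id": f"D{i}", "arm": "desktop",
                         "timepoint": "T2", "measure": measure, "score": s})
        return pd.DataFrame(rows)

    def test_identical_groups_zero_estimate(self):
        scores = [70, 80, 90, 85, 75]
        res = analyze_endpoint(self.make_endpoint(scores, scores), "sus")
        assert res.estimate == pytest.approx(0.0, abs=1e-8)

    def test_large_n_detects_difference_with_sign(self):
        from exposim.synth import generate_endpoint_scores

        cfg = GeneratorConfig(
            n_per_arm={"hmd": 2000, "desktop": 2000}, subject_sd=0.3, seed=6
        )
        df = generate_endpoint_scores(cfg, "sus")
        res = analyze_endpoint(df, "sus")
        assert res.arms == ("hmd", "desktop")
        assert res.estimate < 0  # generated usability is lower in the headset arm
        assert res.p_value < 1e-6

    def test_exactly_one_hypothesis_row(self):
        res = analyze_endpoint(
            self.make_endpoint([70, 80, 90], [75, 85, 95]), "sus"
        )
        assert len(res.hypothesis_rows()) == 1

    def test_single_arm_rejected(self):
        df = self.make_endpoint([70, 80], [])
        with pytest.raises(ValueError):
            analyze_endpoint(df, "sus")
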