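"""Nested mixed models, normality routing, EMM back-transforms."""

import json
import math
import subprocess

import numpy as np
import pandas as pd
import pytest

from aafkit.stats import (ModelSpec, choose_normality_test, emm_backtransform,
                          fit_nested_model, shapiro_francia)


def nested_dataset(rng, deltas=(0.0, 0.0, 0.0), n_animals=10, n_sites=30,
                   reps=1, animal_sd=0.3, site_sd=0.0, resid_sd=1.0,
                   transform=None):
    rows = []
    for g, delta in zip(("A", "B", "C"), deltas):
        for a in range(n_animals):
            ae = rng.normal(0.0, animal_sd)
            for s in range(n_sites):
                se = rng.normal(0.0, site_sd) if site_sd > 0 else 0.0
                for _ in range(reps):
                    y = delta + ae + se + rng.normal(0.0, resid_sd)
                    if transform:
                        y = transform(y)
                    rows.append({"group": g, "animal": f"{g}{a}",
                                 "site": f"{g}{a}s{s}", "y": y})
    return pd.DataFrame(rows)


class TestNormalityRouting:
    def test_heavy_tailed_sample_routes_to_shapiro_francia(self):
        x = np.random.default_rng(1).standard_t(3, 500)
        name, _, p, kurt = choose_normality_test(x)
        assert kurt >= 3.0
        assert name == "shapiro-francia"

    def test_type_i_error_on_normal_samples(self):
        """Each branch test is calibrated at the 5% level on normal data;
        the kurtosis-routed composite inherits a mild selection inflation
        (leptokurtic-looking samples are both routed to Shapiro-Francia and
        likelier to reject) and stays below 10%."""
        rng = np.random.default_rng(2)
        from scipy.stats import shapiro
        sw = sum(shapiro(rng.standard_normal(500))[1] < 0.05
                 for _ in range(1000)) / 1000
        sf = sum(shapiro_francia(rng.standard_normal(500))[1] < 0.05
                 for _ in range(1000)) / 1000
        assert sw == pytest.approx(0.05, abs=0.02)
        assert sf == pytest.approx(0.05, abs=0.02)
        routed = sum(choose_normality_test(rng.standard_normal(500))[2] < 0.05
                     for _ in range(1000)) / 1000
        assert routed < 0.10

    def test_power_against_lognormal(self):
        rng = np.random.default_rng(3)
        rejections = sum(
            choose_normality_test(rng.lognormal(0.0, 1.0, 500))[2] < 0.05
            for _ in range(200))
        assert rejections / 200 > 0.95

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            choose_normality_test([1.0, 2.0, 3.0])

    def test_shapiro_francia_matches_r_nortest(self):
        """Hand-rolled Shapiro-Francia agrees with R nortest::sf.test."""
        rng = np.random.default_rng(4)
        samples = [rng.standard_normal(60), rng.lognormal(0, 0.8, 120),
                   rng.uniform(0, 1, 200)]
        ours = [shapiro_francia(x) for x in samples]
        payload = ";".join(",".join(f"{v:.17g}" for v in x) for x in samples)
        rcode = f'''
        xs <- strsplit("{payload}", ";")[[1]]
        suppressMessages(library(nortest))
        out <- lapply(xs, function(s) {{
          x <- as.numeric(strsplit(s, ",")[[1]])
          r <- sf.test(x); c(r$statistic, r$p.value)
        }})
        cat(jsonlite::toJSON(out, digits=12))
        '''
        res = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=120)
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout)
        for (w, p), (w_r, p_r) in zip(ours, ref):
            assert w == pytest.approx(w_r, rel=1e-6)
            assert p == pytest.approx(p_r, rel=1e-3, abs=1e-6)


class TestModelSpec:
    def test_unsupported_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelSpec(response="y", family="poisson")

    def test_nesting_depth_enforced(self):
        with pytest.raises(ValueError, match="nesting"):
            ModelSpec(response="y", random=("animal",))


class TestNestedFit:
    def test_identical_groups_give_unit_pvalues_equal_emms(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(60)
        rows = []
        for g in ("A", "B", "C"):
            for a in range(6):
                for s in range(10):
                    rows.append({"group": g, "animal": f"{g}{a}",
                                 "site": f"{g}{a}s{s}", "y": base[a * 10 + s]})
        res = fit_nested_model(ModelSpec(response="y"), pd.DataFrame(rows))
        assert np.allclose(res.contrasts["p_tukey"], 1.0, atol=1e-6)
        emms = res.emm_table["emm"].to_numpy()
        assert np.allclose(emms, emms[0], atol=1e-8)

    def test_single_animal_per_group_rejected(self):
        rng = np.random.default_rng(6)
        d = nested_dataset(rng, n_animals=1, n_sites=10)
        with pytest.raises(ValueError, match="singular"):
            fit_nested_model(ModelSpec(response="y"), d)

    def test_recovers_injected_group_difference(self):
        rng = np.random.default_rng(7)
        d = nested_dataset(rng, deltas=(0.0, 1.0, 0.0))
        res = fit_nested_model(ModelSpec(response="y"), d)
        assert res.converged
        assert res.wald_table.loc["group", "p"] < 1e-4
        emm = res.emm_table["emm"]
        assert emm["B"] - emm["A"] == pytest.approx(1.0, abs=0.3)

    def test_cross_check_against_lme4(self):
        """Fixed effects to 1e-4 relative and Wald chi-square to 1e-3
        against R lme4 on replicated nested datasets."""
        rng = np.random.default_rng(8)
        datasets = [nested_dataset(rng, deltas=(0, 0.5, 0.2), n_animals=5,
                                   n_sites=6, reps=4, site_sd=0.3)
                    for _ in range(5)]
        rcode = '''
        suppressMessages(library(lme4))
        args <- commandArgs(trailingOnly=TRUE)
        out <- list()
        for (f in args) {
          d <- read.csv(f)
          m <- lmer(y ~ group + (1|animal) + (1|animal:site), data=d, REML=TRUE)
          fe <- fixef(m); V <- as.matrix(vcov(m))
          b <- fe[2:3]; C <- V[2:3, 2:3]
          out[[length(out)+1]] <- list(fe=as.numeric(fe),
                                       chi2=as.numeric(t(b) %*% solve(C) %*% b))
        }
        cat(jsonlite::toJSON(out, digits=12))
        '''
        import tempfile, os
        with tempfile.TemporaryDirectory() as tmp:
            files = []
            for i, d in enumerate(datasets):
                f = os.path.join(tmp, f"d{i}.csv")
                d.to_csv(f, index=False)
                files.append(f)
            res = subprocess.run(["Rscript", "-e", rcode] + files,
                                 capture_output=True, text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout)
        for d, r in zip(datasets, ref):
            fit = fit_nested_model(ModelSpec(response="y"), d)
            mine = fit.coefficients.to_numpy()
            np.testing.assert_allclose(mine, np.asarray(r["fe"]), rtol=1e-4)
            chi2 = fit.wald_table.loc["group", "chi2"]
            assert chi2 == pytest.approx(r["chi2"][0], rel=1e-3)

    def test_power_for_detectable_animal_level_shift(self):
        """1.5 between-animal-SD shift in one group is detected with power
        > 0.8 at the 10-animal/30-site cohort scale."""
        rng = np.random.default_rng(9)
        hits = 0
        n = 150
        for _ in range(n):
            d = nested_dataset(rng, deltas=(0.0, 0.45, 0.0), animal_sd=0.3)
            res = fit_nested_model(ModelSpec(response="y"), d)
            hits += res.wald_table.loc["group", "p"] < 0.05
        assert hits / n > 0.8

    def test_tukey_familywise_error_controlled(self):
        """Any-contrast false positive rate stays at the nominal 5% level
        (within Monte-Carlo error) under the null."""
        rng = np.random.default_rng(10)
        n = 250
        fw = 0
        for _ in range(n):
            d = nested_dataset(rng, n_animals=8, n_sites=15)
            res = fit_nested_model(ModelSpec(response="y"), d)
            fw += bool((res.contrasts["p_tukey"] < 0.05).any())
        se = math.sqrt(0.05 * 0.95 / n)
        assert fw / n <= 0.05 + 2 * se

    def test_tweedie_approx_log_scale_fit(self):
        rng = np.random.default_rng(11)
        d = nested_dataset(rng, deltas=(0.0, 1.5, 0.0),
                           transform=lambda y: math.exp(0.2 * y))
        res = fit_nested_model(ModelSpec(response="y", family="tweedie-approx"), d)
        assert res.metadata["link"] == "log"
        assert (res.emm_table[["emm", "lower", "upper"]] > 0).all().all()
        assert res.wald_table.loc["group", "p"] < 0.01


class TestEmmBacktransform:
    def test_identity_link_unchanged(self):
        assert emm_backtransform(2.5, 0.4, "identity") == \
            pytest.approx((2.5, 2.5 - 1.96 * 0.4, 2.5 + 1.96 * 0.4))

    def test_log_link_recovers_fixture_mean(self):
        mean, lo, hi = emm_backtransform(math.log(14.4), 1e-12, "log")
        assert mean == pytest.approx(14.4)
        assert lo == pytest.approx(14.4) and hi == pytest.approx(14.4)

    def test_log_link_ci_always_positive(self):
        _, lo, _ = emm_backtransform(-3.0, 5.0, "log")
        assert lo > 0.0

    def test_round_trip_exact_inverse(self):
        for link, fwd in (("log", math.log), ("logit",
                                              lambda p: math.log(p / (1 - p)))):
            for val in (0.2, 0.5, 0.9) if link == "logit" else (0.5, 3.0, 40.0):
                mean, _, _ = emm_backtransform(fwd(val), 0.0, link)
                assert mean == pytest.approx(val, rel=1e-10)
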