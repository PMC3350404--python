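"""ABC machinery: priors, models, statistics, tables, fitting, posteriors."""

import math

import numpy as np
import pandas as pd
import pytest

from popgenkit.abc import (
    AbcError,
    Posterior,
    Prior,
    SampleConfig,
    SdzStats,
    SfsStats,
    SNM,
    abc_fit,
    abc_sample,
    builtin_models,
    compute_stats,
    double_domestication_model,
    get_model,
    get_stat_set,
    list_models,
    posterior_predictive,
    read_table_meta,
)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

class TestPrior:
    def test_uniform_mean(self):
        rng = np.random.default_rng(1)
        p = Prior().add_uniform("theta", 1.0, 10.0)
        draws = p.draw_batch(rng, 20_000)[:, 0]
        assert draws.min() >= 1.0 and draws.max() <= 10.0
        se = 9.0 / math.sqrt(12 * 20_000)
        assert abs(draws.mean() - 5.5) < 4 * se

    def test_loguniform_log_is_uniform(self):
        rng = np.random.default_rng(2)
        p = Prior().add_loguniform("rho", 0.1, 10.0)
        logs = np.log(p.draw_batch(rng, 20_000)[:, 0])
        lo, hi = math.log(0.1), math.log(10.0)
        se = (hi - lo) / math.sqrt(12 * 20_000)
        assert abs(logs.mean() - 0.5 * (lo + hi)) < 4 * se

    def test_column_order_and_draw_dict(self):
        p = Prior().add_uniform("a", 0, 1).add_uniform("b", 5, 6)
        assert p.names == ["a", "b"]
        d = p.draw(np.random.default_rng(0))
        assert 0 <= d["a"] <= 1 and 5 <= d["b"] <= 6

    def test_validation(self):
        with pytest.raises(AbcError):
            Prior().add_uniform("x", 2, 1)
        with pytest.raises(AbcError):
            Prior().add_loguniform("x", 0.0, 1.0)
        with pytest.raises(AbcError):
            Prior().add_uniform("x", 0, 1).add_uniform("x", 0, 1)


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

class TestModels:
    def test_builtin_names(self):
        assert set(builtin_models()) == {"SNM", "SNMR", "PEMR",
                                         "BNM", "IM", "AM"}

    def test_registry_includes_example_model(self):
        assert "DOM2" in list_models()
        m = get_model("DOM2")
        assert m.parameter_names == ["theta", "date", "size",
                                     "migr1", "migr2"]

    def test_unknown_model_error_lists_registry(self):
        with pytest.raises(AbcError, match="SNM"):
            get_model("NOPE")

    def test_recomb_flag_appends_rho(self):
        assert get_model("SNM", recomb=True).parameter_names == \
            ["theta", "rho"]
        assert get_model("SNMR").parameter_names == ["theta", "rho"]

    def test_population_count_validated(self):
        with pytest.raises(AbcError, match="population"):
            get_model("IM").validate_config(SampleConfig([10]))

    def test_example_model_limiting_case_matches_single_population(self):
        """All samples in one long-isolated population behaves neutrally."""
        rng = np.random.default_rng(5)
        model = double_domestication_model()
        cfg = SampleConfig([0, 0, 10, 0])
        params = {"theta": 5.0, "date": 50.0, "size": 1.0,
                  "migr1": 1.0, "migr2": 0.0}
        from popgenkit.diversity import nucleotide_stats
        S = []
        for _ in range(400):
            aln = model.generate(cfg, params, rng)[0]
            S.append(nucleotide_stats(aln).S if aln.length else 0)
        a1 = sum(1.0 / i for i in range(1, 10))
        mean, se = np.mean(S), np.std(S, ddof=1) / math.sqrt(len(S))
        assert abs(mean - 5.0 * a1) < 3 * se

    def test_example_model_requires_wild_contact(self):
        model = double_domestication_model()
        cfg = SampleConfig([2, 2, 2, 2])
        with pytest.raises(AbcError, match="migr1"):
            model.demography(cfg, {"theta": 1.0, "date": 1.0, "size": 1.0,
                                   "migr1": 0.0, "migr2": 0.0})


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

class TestStatSets:
    def test_sdz_worked_example(self, toy4_outgroup):
        cfg = SampleConfig([4], outgroup=True)
        vals = compute_stats(SdzStats(), [toy4_outgroup], cfg)
        assert vals["S"] == 3
        assert vals["D"] == pytest.approx(0.1677, abs=5e-5)
        assert vals["H"] == pytest.approx(-2 / 3, rel=1e-9)

    def test_sdz_without_outgroup_degrades(self, toy4, caplog):
        import logging
        cfg = SampleConfig([4])
        with caplog.at_level(logging.WARNING, logger="popgenkit.abc"):
            names = SdzStats().names(cfg)
        assert names == ["S", "D"]
        assert "outgroup" in caplog.text

    def test_sfs_folded_worked_example(self, toy4):
        cfg = SampleConfig([4])
        vec = SfsStats().compute([toy4], cfg)
        expected = np.zeros(8)
        expected[3] = 2 / 3   # two singletons, minor frequency 1/4
        expected[7] = 1 / 3   # one site at minor frequency 1/2
        np.testing.assert_allclose(vec, expected, atol=1e-12)

    def test_sfs_monomorphic_zero_vector(self):
        from popgenkit.seqdata import Alignment, SequenceEntry
        aln = Alignment([SequenceEntry(f"s{i}", "AAAA") for i in range(4)])
        vec = SfsStats().compute([aln], SampleConfig([4]))
        assert np.all(vec == 0)

    def test_stat_registry(self):
        assert isinstance(get_stat_set("SDZ"), SdzStats)
        assert isinstance(get_stat_set("SFS"), SfsStats)
        with pytest.raises(AbcError, match="SDZ"):
            get_stat_set("NOPE")


# ---------------------------------------------------------------------------
# table production
# ---------------------------------------------------------------------------

def _snm_table(path, nsims, seed, lo=2.0, hi=10.0, n=10):
    prior = Prior().add_uniform("theta", lo, hi)
    abc_sample(SNM(), prior, SdzStats(), nsims, SampleConfig([n]),
               seed, path)
    return prior


class TestAbcSample:
    def test_table_shape_and_metadata(self, tmp_path):
        path = tmp_path / "t.tsv"
        _snm_table(path, 500, 11)
        info = read_table_meta(path)
        assert info["meta"] == {"model": "SNM", "nsims": "500", "seed": "11"}
        assert info["columns"] == ["theta", "S", "D"]
        df = pd.read_csv(path, sep="\t", skiprows=1)
        assert df.shape == (500, 3)
        assert df["theta"].between(2, 10).all()

    def test_mean_s_matches_watterson_expectation(self, tmp_path):
        path = tmp_path / "t.tsv"
        # near-degenerate prior pins theta at 5: E[S] = theta * a_{n-1}
        _snm_table(path, 3000, 12, lo=4.9999, hi=5.0001)
        df = pd.read_csv(path, sep="\t", skiprows=1)
        a1 = sum(1.0 / i for i in range(1, 10))
        se = df["S"].std(ddof=1) / math.sqrt(len(df))
        assert abs(df["S"].mean() - 5.0 * a1) < 3 * se

    def test_fixed_seed_determinism(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        _snm_table(p1, 200, 13)
        _snm_table(p2, 200, 13)
        assert p1.read_text() == p2.read_text()

    def test_resume_extends_to_total(self, tmp_path):
        path = tmp_path / "t.tsv"
        prior = Prior().add_uniform("theta", 2.0, 10.0)
        cfg = SampleConfig([10])
        w1 = abc_sample(SNM(), prior, SdzStats(), 60, cfg, 14, path)
        w2 = abc_sample(SNM(), prior, SdzStats(), 100, cfg, 14, path,
                        resume=True)
        assert (w1, w2) == (60, 40)
        df = pd.read_csv(path, sep="\t", skiprows=1)
        assert len(df) == 100

    def test_prior_must_cover_parameters(self, tmp_path):
        prior = Prior().add_uniform("not_theta", 0, 1)
        with pytest.raises(AbcError, match="theta"):
            abc_sample(SNM(), prior, SdzStats(), 10, SampleConfig([4]),
                       0, tmp_path / "x.tsv")

    def test_generic_path_matches_fast_path_distribution(self, tmp_path):
        """SNM with recombination flag off vs on at rho ~ 0 agree on S."""
        cfg = SampleConfig([8])
        fast_p = tmp_path / "fast.tsv"
        slow_p = tmp_path / "slow.tsv"
        _snm_table(fast_p, 1200, 21, lo=2.9999, hi=3.0001, n=8)
        prior = (Prior().add_uniform("theta", 2.9999, 3.0001)
                 .add_uniform("rho", 0.0, 1e-9))
        abc_sample(get_model("SNM", recomb=True), prior, SdzStats(),
                   1200, cfg, 22, slow_p)
        a = pd.read_csv(fast_p, sep="\t", skiprows=1)["S"]
        b = pd.read_csv(slow_p, sep="\t", skiprows=1)["S"]
        se = math.hypot(a.std(ddof=1) / math.sqrt(len(a)),
                        b.std(ddof=1) / math.sqrt(len(b)))
        assert abs(a.mean() - b.mean()) < 3 * se


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _write_table(path, columns, rows, model="TEST", seed=0):
    with open(path, "w") as fh:
        fh.write(f"# model={model} nsims={len(rows)} seed={seed}\n")
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(format(v, ".17g") for v in r) + "\n")


class TestAbcFit:
    def test_tolerance_one_rejection_keeps_everything(self, tmp_path):
        path = tmp_path / "t.tsv"
        _snm_table(path, 300, 31)
        df = pd.read_csv(path, sep="\t", skiprows=1).dropna()
        post = abc_fit(path, {"S": 10.0, "D": 0.0}, 1.0, adjust="rejection")
        assert len(post) == len(df)
        assert sorted(post.accepted["theta"]) == pytest.approx(
            sorted(df["theta"]), rel=1e-9)

    def test_acceptance_matches_independent_recomputation(self, tmp_path):
        path = tmp_path / "t.tsv"
        _snm_table(path, 2000, 32)
        obs = {"S": 12.0, "D": 0.1}
        tol = 0.05
        post = abc_fit(path, obs, tol, adjust="rejection")
        df = pd.read_csv(path, sep="\t", skiprows=1).dropna()
        sd = df[["S", "D"]].std(ddof=0).to_numpy()
        z = (df[["S", "D"]].to_numpy() - np.array([obs["S"], obs["D"]])) / sd
        d = np.sqrt((z**2).sum(axis=1))
        m = math.ceil(tol * len(df))
        assert len(post) == m
        cut = np.sort(d)[m - 1]
        assert post.distances.max() == pytest.approx(cut, rel=1e-9)
        assert np.all(np.diff(post.distances) >= 0)
        assert sorted(post.accepted["theta"]) == pytest.approx(
            sorted(df["theta"].to_numpy()[np.argsort(d)[:m]]), rel=1e-9)

    def test_nan_rows_excluded(self, tmp_path):
        path = tmp_path / "t.tsv"
        rows = [(1.0, 5.0, 0.1), (2.0, math.nan, 0.2), (3.0, 6.0, 0.3),
                (4.0, 7.0, math.nan), (5.0, 8.0, 0.5)]
        _write_table(path, ["theta", "S", "D"], rows)
        post = abc_fit(path, {"S": 6.0, "D": 0.3}, 1.0, adjust="rejection")
        assert len(post) == 3
        assert sorted(post.accepted["theta"]) == [1.0, 3.0, 5.0]

    def test_zero_variance_statistic_dropped(self, tmp_path, caplog):
        import logging
        path = tmp_path / "t.tsv"
        rows = [(float(i), float(i) + 1.0, 7.0) for i in range(20)]
        _write_table(path, ["theta", "S", "D"], rows)
        with caplog.at_level(logging.WARNING, logger="popgenkit.abc"):
            post = abc_fit(path, {"S": 10.0, "D": 7.0}, 0.5,
                           adjust="rejection")
        assert "zero-variance" in caplog.text
        assert len(post) == 10

    def test_loclinear_recovers_noiseless_linear_map(self, tmp_path):
        path = tmp_path / "t.tsv"
        thetas = np.linspace(1.0, 10.0, 40)
        rows = [(t, 2.0 * t + 1.0) for t in thetas]
        _write_table(path, ["theta", "S"], rows)
        post = abc_fit(path, {"S": 9.0}, 0.5, adjust="loclinear")
        assert post.method == "loclinear"
        # exact linear relation: every accepted draw is shifted to theta=4
        np.testing.assert_allclose(post.adjusted["theta"], 4.0, atol=1e-6)

    def test_loclinear_log_transform_respects_positivity(self, tmp_path):
        path = tmp_path / "t.tsv"
        rng = np.random.default_rng(33)
        thetas = np.exp(rng.uniform(np.log(0.05), np.log(5.0), size=400))
        S = thetas + rng.normal(0, 2.0, size=400)
        _write_table(path, ["theta", "S"],
                     list(zip(thetas, S)))
        prior = Prior().add_loguniform("theta", 0.05, 5.0)
        post = abc_fit(path, {"S": 0.1}, 0.2, adjust="loclinear",
                       prior=prior)
        assert (post.adjusted["theta"] > 0).all()

    def test_small_accepted_set_falls_back_to_rejection(self, tmp_path):
        path = tmp_path / "t.tsv"
        rows = [(float(i), float(i)) for i in range(10)]
        _write_table(path, ["theta", "S"], rows)
        post = abc_fit(path, {"S": 4.2}, 0.1, adjust="loclinear")
        assert post.method == "rejection" and len(post) == 1

    def test_tolerance_validated(self, tmp_path):
        path = tmp_path / "t.tsv"
        _write_table(path, ["theta", "S"], [(1.0, 2.0)])
        with pytest.raises(AbcError, match="tolerance"):
            abc_fit(path, {"S": 1.0}, 0.0)
        with pytest.raises(AbcError, match="observed"):
            abc_fit(path, {"nope": 1.0}, 0.5)

    def test_streaming_equals_single_chunk(self, tmp_path):
        path = tmp_path / "t.tsv"
        _snm_table(path, 1000, 34)
        obs = {"S": 14.0, "D": -0.1}
        a = abc_fit(path, obs, 0.1, adjust="loclinear", chunksize=64)
        b = abc_fit(path, obs, 0.1, adjust="loclinear", chunksize=10**6)
        np.testing.assert_allclose(a.adjusted["theta"], b.adjusted["theta"],
                                   rtol=1e-12)
        np.testing.assert_allclose(a.distances, b.distances, rtol=1e-12)


# ---------------------------------------------------------------------------
# posteriors
# ---------------------------------------------------------------------------

class TestPosterior:
    def _posterior(self, tmp_path):
        path = tmp_path / "t.tsv"
        _snm_table(path, 800, 41)
        return abc_fit(path, {"S": 14.0, "D": 0.0}, 0.1)

    def test_tsv_round_trip(self, tmp_path):
        post = self._posterior(tmp_path)
        out = tmp_path / "post.tsv"
        post.to_tsv(out)
        back = Posterior.from_tsv(out)
        assert back.method == post.method
        assert back.tolerance == post.tolerance
        np.testing.assert_allclose(back.adjusted["theta"],
                                   post.adjusted["theta"], rtol=1e-12)
        np.testing.assert_allclose(back.accepted["theta"],
                                   post.accepted["theta"], rtol=1e-12)
        np.testing.assert_allclose(back.weights, post.weights, rtol=1e-12)
        np.testing.assert_allclose(back.distances, post.distances,
                                   rtol=1e-12)

    def test_point_mass_quantiles(self):
        df = pd.DataFrame({"theta": [3.0] * 5})
        post = Posterior(accepted=df, adjusted=df.copy(),
                         weights=np.ones(5), distances=np.zeros(5),
                         tolerance=1.0, method="rejection")
        q = post.quantiles((0.025, 0.5, 0.975))
        assert (q["theta"] == 3.0).all()
        assert post.mode()["theta"] == pytest.approx(3.0, abs=0.5)

    def test_median_brackets_truth_on_calibrated_fit(self, tmp_path):
        post = self._posterior(tmp_path)
        q = post.quantiles((0.025, 0.975))
        # observed S=14 was generated at theta ~ 5 (E[S]=theta*a9)
        assert q["theta"].iloc[0] < 5.0 < q["theta"].iloc[1]

    def test_posterior_predictive_shape(self, tmp_path):
        post = self._posterior(tmp_path)
        cfg = SampleConfig([10])
        df = posterior_predictive(post, SNM(), SdzStats(), cfg, 8,
                                  rng=np.random.default_rng(42))
        assert list(df.columns) == ["S", "D"]
        assert df.shape == (8, 2)
        assert (df["S"] >= 0).all()
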