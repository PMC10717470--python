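import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import epiblup as eb
from epiblup.grm import identity_matrix
from epiblup.reml import MODEL_CATALOGUE, _reml_core


class TestModelCatalogue:
    @pytest.mark.parametrize(
        "name, terms, inbreeding",
        [
            ("MA", ("additive",), False),
            ("MAI", ("additive",), True),
            ("MAE", ("additive", "aa"), False),
            ("MADE1", ("additive", "dominance", "aa"), False),
            ("MAIDE2", ("additive", "dominance", "aa", "ad"), True),
            ("MAIDE3", ("additive", "dominance", "aa", "ad", "dd"), True),
            ("MAIpe", ("additive", "pe"), True),
            ("MAIDEpe", ("additive", "dominance", "aa", "pe"), True),
        ],
    )
    def test_term_mapping(self, name, terms, inbreeding):
        spec = eb.model_spec(name)
        assert spec.random_terms == terms
        assert spec.use_inbreeding is inbreeding

    def test_catalogue_has_all_sixteen_variants(self):
        assert len(MODEL_CATALOGUE) == 16

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            eb.model_spec("MAX")


class TestBuildDesign:
    def _pt(self, df, **kw):
        return eb.PhenotypeTable(df, **kw)

    def test_single_factor_two_levels(self, hwe_dataset):
        g, _, matrices = hwe_dataset
        df = pd.DataFrame(
            {
                "animal_id": g.sample_ids[:4],
                "y": [1.0, 2.0, 3.0, 4.0],
                "sex": ["m", "f", "m", "f"],
            }
        )
        ds = eb.build_design(self._pt(df, factors=["sex"]), eb.model_spec("MA"), matrices)
        assert ds.X.shape[1] == 2  # intercept + one dummy
        assert ds.x_names == ["intercept", "sex[m]"]

    def test_repeated_records_share_z_columns(self, hwe_dataset):
        g, _, matrices = hwe_dataset
        ids = g.sample_ids[:3]
        df = pd.DataFrame({"animal_id": ids * 2, "y": np.arange(6.0)})
        inb = eb.genomic_inbreeding(matrices["A"])
        ds = eb.build_design(self._pt(df), eb.model_spec("MAIpe"), matrices, inb)
        assert ds.Z.shape == (6, matrices["A"].n)
        cols = ds.Z.sum(axis=0)
        assert sorted(cols[cols > 0]) == [2.0, 2.0, 2.0]

    def test_factor_concatenation_cross_levels(self, hwe_dataset):
        g, _, matrices = hwe_dataset
        df = pd.DataFrame(
            {
                "animal_id": g.sample_ids[:5],
                "y": np.arange(5.0),
                "week": ["1", "1", "2", "2", "1"],
                "day": ["a", "b", "a", "c", "c"],
            }
        )
        ds = eb.build_design(
            self._pt(df, factors=["week:day"]), eb.model_spec("MA"), matrices
        )
        # 5 observed cross-levels -> intercept + 4 dummies
        assert ds.X.shape[1] == 5

    def test_single_level_factor_dropped(self, hwe_dataset):
        g, _, matrices = hwe_dataset
        df = pd.DataFrame(
            {"animal_id": g.sample_ids[:4], "y": np.arange(4.0), "farm": ["x"] * 4}
        )
        ds = eb.build_design(self._pt(df, factors=["farm"]), eb.model_spec("MA"), matrices)
        assert ds.X.shape[1] == 1

    def test_missing_inbreeding_rejected(self, hwe_dataset):
        g, _, matrices = hwe_dataset
        df = pd.DataFrame({"animal_id": g.sample_ids[:4], "y": np.arange(4.0)})
        with pytest.raises(ValueError):
            eb.build_design(self._pt(df), eb.model_spec("MAI"), matrices)

    def test_missing_matrix_rejected(self, hwe_dataset):
        g, _, matrices = hwe_dataset
        df = pd.DataFrame({"animal_id": g.sample_ids[:4], "y": np.arange(4.0)})
        with pytest.raises(ValueError):
            eb.build_design(self._pt(df), eb.model_spec("MAD"), {"A": matrices["A"]})

    def test_pe_without_repeats_rejected(self, hwe_dataset):
        g, _, matrices = hwe_dataset
        df = pd.DataFrame({"animal_id": g.sample_ids[:4], "y": np.arange(4.0)})
        inb = eb.genomic_inbreeding(matrices["A"])
        with pytest.raises(ValueError):
            eb.build_design(self._pt(df), eb.model_spec("MAIpe"), matrices, inb)

    def test_rank_deficient_columns_dropped(self, hwe_dataset):
        g, _, matrices = hwe_dataset
        df = pd.DataFrame(
            {
                "animal_id": g.sample_ids[:6],
                "y": np.arange(6.0),
                "a": ["1", "1", "1", "2", "2", "2"],
                "b": ["x", "x", "x", "y", "y", "y"],  # aliased with a
            }
        )
        ds = eb.build_design(
            self._pt(df, factors=["a", "b"]), eb.model_spec("MA"), matrices
        )
        assert np.linalg.matrix_rank(ds.X) == ds.X.shape[1] == 2


def _toy_design(n=30, m=200, seed=5, truth=None, model="MA"):
    g = eb.simulate_genotypes(n, m, seed=seed)
    ga = eb.additive_grm(g)
    truth = truth or eb.SimulationTruth({"additive": 0.5, "residual": 0.5}, seed=seed + 1)
    pt, effects = eb.simulate_phenotypes(g, truth, seed=seed + 1)
    matrices = {"A": ga}
    if model != "MA":
        gd = eb.dominance_grm(g)
        matrices.update({
            "D": gd,
            "AA": eb.epistatic_grm(ga, ga, "AA"),
            "AD": eb.epistatic_grm(ga, gd, "AD"),
            "DD": eb.epistatic_grm(gd, gd, "DD"),
        })
    ds = eb.build_design(pt, eb.model_spec(model), matrices)
    return ds, effects


class TestRemlLoglikelihood:
    def test_matches_dense_formula_oracle(self):
        # independent evaluation via slogdet and explicit inverses
        ds, _ = _toy_design(n=5, m=40, seed=3)
        theta = np.array([0.4, 0.8])
        V = theta[0] * ds.Z @ ds.G["additive"] @ ds.Z.T + theta[1] * np.eye(5)
        Vi = np.linalg.inv(V)
        XtViX = ds.X.T @ Vi @ ds.X
        P = Vi - Vi @ ds.X @ np.linalg.inv(XtViX) @ ds.X.T @ Vi
        oracle = -0.5 * (
            np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XtViX)[1]
            + float(ds.y @ P @ ds.y)
        )
        assert eb.reml_loglikelihood(ds, theta) == pytest.approx(oracle, abs=1e-8)

    def test_translation_invariance(self):
        ds, _ = _toy_design(seed=7)
        theta = [0.3, 0.7]
        base = eb.reml_loglikelihood(ds, theta)
        ds_shift = eb.reml.DesignSystem(
            ds.y + 5.0, ds.X, ds.x_names, ds.Z, ds.term_labels, ds.G, ds.animal_ids
        )
        assert eb.reml_loglikelihood(ds_shift, theta) == pytest.approx(base, abs=1e-8)

    def test_scaling_identity(self):
        # y -> c y, variances -> c^2 variances shifts ll by -(n - rank X) log c
        ds, _ = _toy_design(seed=9)
        c = 3.0
        base = eb.reml_loglikelihood(ds, [0.3, 0.7])
        ds_scaled = eb.reml.DesignSystem(
            c * ds.y, ds.X, ds.x_names, ds.Z, ds.term_labels, ds.G, ds.animal_ids
        )
        scaled = eb.reml_loglikelihood(ds_scaled, [0.3 * c**2, 0.7 * c**2])
        expected_shift = -(ds.n_records - ds.X.shape[1]) * np.log(c)
        assert scaled - base == pytest.approx(expected_shift, abs=1e-8)

    def test_wrong_length_rejected(self):
        ds, _ = _toy_design(seed=11)
        with pytest.raises(ValueError):
            eb.reml_loglikelihood(ds, [0.3, 0.3, 0.4])


class TestFitReml:
    def test_matches_derivative_free_optimizer(self):
        ds, _ = _toy_design(n=30, m=200, seed=13)
        fit = eb.fit_reml(ds, eb.model_spec("MA"))
        res = minimize(
            lambda lt: -eb.reml_loglikelihood(ds, np.exp(lt)),
            np.log([0.4, 0.6]),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 10000},
        )
        oracle = np.exp(res.x)
        assert fit.variances["additive"] == pytest.approx(oracle[0], abs=1e-4)
        assert fit.variances["residual"] == pytest.approx(oracle[1], abs=1e-4)

    def test_matches_statsmodels_random_intercept(self):
        # with an identity additive structure and repeated records the model
        # is the classical random-intercept model; MixedLM is the oracle
        import statsmodels.api as sm

        rng = np.random.default_rng(15)
        n_animals, r = 40, 5
        u = rng.normal(0, np.sqrt(0.5), n_animals)
        animal = np.repeat(np.arange(n_animals), r)
        y = 1.0 + u[animal] + rng.normal(0, np.sqrt(0.8), n_animals * r)
        ids = [f"a{i}" for i in range(n_animals)]
        df = pd.DataFrame({"animal_id": [ids[i] for i in animal], "y": y})
        matrices = {"A": identity_matrix(ids)}
        ds = eb.build_design(eb.PhenotypeTable(df), eb.model_spec("MA"), matrices)
        fit = eb.fit_reml(ds, eb.model_spec("MA"))

        sm_fit = sm.MixedLM(y, np.ones((len(y), 1)), groups=animal).fit(reml=True)
        assert fit.variances["additive"] == pytest.approx(
            float(np.asarray(sm_fit.cov_re)[0, 0]), rel=1e-3
        )
        assert fit.variances["residual"] == pytest.approx(float(sm_fit.scale), rel=1e-3)

    def test_pure_noise_pins_additive_at_boundary(self):
        # a pure-noise trait whose unconstrained additive estimate is
        # negative gets pinned at the boundary constant and flagged
        ped = eb.simulate_pedigree(40, 2, 40, 2, seed=17)
        g = eb.simulate_genotypes(ped, 400, mode="gene_drop", seed=17)
        truth = eb.SimulationTruth({"residual": 1.0}, seed=117)
        pt, _ = eb.simulate_phenotypes(g, truth)
        ds = eb.build_design(pt, eb.model_spec("MA"), {"A": eb.additive_grm(g)})
        fit = eb.fit_reml(ds, eb.model_spec("MA"))
        assert "additive" in fit.at_boundary
        assert fit.variances["additive"] <= fit.boundary * (1 + 1e-6)

    def test_invariant_to_record_order_and_level_relabeling(self, hwe_dataset):
        g, _, matrices = hwe_dataset
        rng = np.random.default_rng(19)
        truth = eb.SimulationTruth({"additive": 0.4, "residual": 0.6}, seed=20)
        pt, _ = eb.simulate_phenotypes(g, truth)
        df = pt.data.copy()
        df["batch"] = rng.choice(["u", "v"], len(df))
        pt1 = eb.PhenotypeTable(df, factors=["batch"])
        fit1 = eb.fit_reml(eb.build_design(pt1, eb.model_spec("MA"), matrices))

        df2 = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        df2["batch"] = df2["batch"].map({"u": "zz", "v": "aa"})
        pt2 = eb.PhenotypeTable(df2, factors=["batch"])
        fit2 = eb.fit_reml(eb.build_design(pt2, eb.model_spec("MA"), matrices))
        assert fit1.reml_loglik == pytest.approx(fit2.reml_loglik, abs=1e-8)

    def test_gebv_accuracy_increases_with_heritability(self):
        cors = {}
        for h2 in (0.1, 0.3, 0.6):
            reps = []
            for rep in range(20):
                g = eb.simulate_genotypes(150, 400, seed=1000 + rep)
                ga = eb.additive_grm(g)
                truth = eb.SimulationTruth(
                    {"additive": h2, "residual": 1 - h2}, seed=2000 + rep
                )
                pt, effects = eb.simulate_phenotypes(g, truth)
                ds = eb.build_design(pt, eb.model_spec("MA"), {"A": ga})
                fit = eb.fit_reml(ds, eb.model_spec("MA"))
                reps.append(np.corrcoef(fit.gebv.to_numpy(), effects["additive"])[0, 1])
            cors[h2] = np.mean(reps)
        assert cors[0.1] < cors[0.3] < cors[0.6]

    def test_too_few_records_rejected(self, hwe_dataset):
        g, _, matrices = hwe_dataset
        df = pd.DataFrame({"animal_id": g.sample_ids[:2], "y": [0.0, 1.0]})
        with pytest.raises(ValueError):
            eb.fit_reml(eb.build_design(eb.PhenotypeTable(df), eb.model_spec("MA"), matrices))


class TestVarianceRatios:
    def test_ratio_to_phenotypic_from_printed_components(self):
        # panting-score components under the epistatic repeatability model
        fit = eb.REMLFit.from_components(
            "MAIEpe",
            {"additive": 0.0298, "aa": 0.1379, "pe": 0.0137, "residual": 0.8463},
        )
        vr = eb.variance_ratios(fit, "total_genetic_extras")
        assert vr.ratios["aa"][0] == pytest.approx(0.1342, abs=5e-5)
        # the published share was computed from unrounded components; the
        # 4-decimal printed inputs limit agreement to ~2 decimals
        assert vr.aa_over_g[0] * 100 == pytest.approx(82.22, abs=0.05)

    def test_narrow_sense_heritability_worked_example(self):
        fit = eb.REMLFit.from_components(
            "MA", {"additive": 1310.62, "residual": 2190.12}
        )
        vr = eb.variance_ratios(fit)
        assert vr.ratios["additive"][0] == pytest.approx(0.3744, abs=5e-5)

    def test_boundary_component_gives_zero_ratio(self):
        fit = eb.REMLFit.from_components("MA", {"additive": 0.0, "residual": 1.0})
        vr = eb.variance_ratios(fit)
        assert vr.ratios["additive"][0] == 0.0

    def test_delta_method_ses_from_fitted_model(self, additive_fit):
        _, _, fit = additive_fit
        vr = eb.variance_ratios(fit)
        est, se = vr.ratios["additive"]
        assert 0 < est < 1
        assert np.isfinite(se) and se > 0

    def test_zero_total_variance_rejected(self):
        fit = eb.REMLFit.from_components("MA", {"additive": 0.0, "residual": 1.0})
        fit.variances = {"additive": 0.0, "residual": 0.0}
        from epiblup.errors import ComputationError

        with pytest.raises(ComputationError):
            eb.variance_ratios(fit)


class TestModelAIC:
    def test_arithmetic(self):
        fit = eb.REMLFit.from_components("MA", {"additive": 1.0, "residual": 1.0})
        fit.reml_loglik = -100.0
        assert eb.model_aic(fit) == pytest.approx(204.0)

    def test_nested_likelihood_monotonicity(self):
        ds_full, _ = _toy_design(
            n=60, m=300, seed=21,
            truth=eb.SimulationTruth(
                {"additive": 0.3, "aa": 0.3, "residual": 0.4}, seed=22
            ),
            model="MAE",
        )
        ds_red = eb.reml.DesignSystem(
            ds_full.y, ds_full.X, ds_full.x_names, ds_full.Z,
            ("additive",), {"additive": ds_full.G["additive"]}, ds_full.animal_ids,
        )
        fit_red = eb.fit_reml(ds_red, eb.model_spec("MA"))
        fit_full = eb.fit_reml(ds_full, eb.model_spec("MAE"))
        assert -2 * fit_full.reml_loglik <= -2 * fit_red.reml_loglik + 1e-6

    def test_boundary_term_costs_two_aic_units(self):
        # under a null simulated without epistasis the extra term sits at the
        # boundary: loglik barely moves, AIC rises by ~2
        ds_full, _ = _toy_design(
            n=80, m=300, seed=23,
            truth=eb.SimulationTruth({"additive": 0.5, "residual": 0.5}, seed=24),
            model="MAE",
        )
        ds_red = eb.reml.DesignSystem(
            ds_full.y, ds_full.X, ds_full.x_names, ds_full.Z,
            ("additive",), {"additive": ds_full.G["additive"]}, ds_full.animal_ids,
        )
        fit_red = eb.fit_reml(ds_red, eb.model_spec("MA"))
        fit_full = eb.fit_reml(ds_full, eb.model_spec("MAE"))
        if "aa" in fit_full.at_boundary:
            assert eb.model_aic(fit_full) - eb.model_aic(fit_red) == pytest.approx(
                2.0, abs=0.05
            )


class TestGBLUPEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = eb.GBLUP(model="MAD", max_iter=50)
        assert est.get_params()["model"] == "MAD"
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_predict(self, hwe_dataset):
        g, _, matrices = hwe_dataset
        truth = eb.SimulationTruth({"additive": 0.4, "residual": 0.6}, seed=25)
        pt, _ = eb.simulate_phenotypes(g, truth)
        est = eb.GBLUP(model="MA").fit(pt, matrices)
        assert est.converged_
        assert set(est.variances_) == {"additive", "residual"}
        pred = est.predict(g.sample_ids[:5])
        np.testing.assert_allclose(pred, est.gebv_.iloc[:5].to_numpy())

    def test_predict_before_fit_raises(self):
        with pytest.raises(AttributeError):
            eb.GBLUP().predict()
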