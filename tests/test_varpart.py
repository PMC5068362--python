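"""Partial RDA fits, fraction algebra and permutation tests."""

import numpy as np
import pandas as pd
import pytest

import commdecomp as cd
from commdecomp.errors import InputError, UndefinedStatisticError
from commdecomp.structure import StructureResponse

from conftest import predictor_blocks


def matrix_response(arr, sites=None):
    arr = np.asarray(arr, dtype=float)
    sites = sites or [f"s{i}" for i in range(arr.shape[0])]
    return StructureResponse(kind="taxonomic_composition", sites=sites,
                             matrix=pd.DataFrame(arr, index=sites))

def vector_response(vals, sites=None, weights=None):
    sites = sites or [f"s{i}" for i in range(len(vals))]
    return StructureResponse(
        kind="dispersion", sites=sites,
        values=pd.Series(np.asarray(vals, dtype=float), index=sites),
        site_weights=None if weights is None else pd.Series(weights, index=sites),
    )

def block(arr, role="environment", sites=None):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    if arr.shape[0] == 1:
        arr = arr.T
    sites = sites or [f"s{i}" for i in range(arr.shape[0])]
    return cd.PredictorSet(role=role, data=pd.DataFrame(
        arr, index=sites, columns=[f"{role[0]}{j}" for j in range(arr.shape[1])]))


class TestAdjustR2:
    @pytest.mark.parametrize("r2,n,p,want", [
        (1.0, 15, 3, 1.0),
        (0.0, 15, 1, -1.0 / 13.0),
        (0.5, 15, 2, 1.0 - 0.5 * 14 / 12),
    ])
    def test_closed_form(self, r2, n, p, want):
        assert cd.adjust_r2(r2, n, p) == pytest.approx(want, abs=1e-12)

    def test_undefined_when_saturated(self):
        with pytest.raises(InputError):
            cd.adjust_r2(0.5, 4, 3)


class TestFitR2:
    def test_exact_linear_response(self, rng):
        X = pd.DataFrame(rng.standard_normal((12, 2)))
        y = 2.0 * X[0] - X[1] + 5.0
        fit = cd.fit_r2(vector_response(y.to_numpy()), X)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_predictor(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        X = pd.DataFrame({"x": [1.0, 1.0, -1.0, -1.0]})
        fit = cd.fit_r2(vector_response(y), X)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_rda_equals_per_column_ols_oracle(self, rng):
        Y = rng.standard_normal((15, 4))
        X = pd.DataFrame(rng.standard_normal((15, 2)))
        fit = cd.fit_r2(matrix_response(Y), X)
        # independent oracle: per-column OLS fitted sums of squares
        Xc = np.column_stack([np.ones(15), X.to_numpy()])
        ss_fit = ss_tot = 0.0
        for j in range(Y.shape[1]):
            yc = Y[:, j] - Y[:, j].mean()
            beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
            ss_fit += np.sum((Xc @ beta) ** 2)
            ss_tot += yc @ yc
        assert fit.r2 == pytest.approx(ss_fit / ss_tot, abs=1e-10)

    def test_collinear_columns_dropped_with_warning(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        X["dup"] = X["a"] * 2.0
        y = rng.standard_normal(10)
        with pytest.warns(UserWarning, match="collinear"):
            fit = cd.fit_r2(vector_response(y), X)
        assert fit.p == 2 and fit.dropped_columns

    def test_saturated_design_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((6, 5)))
        with pytest.raises(InputError, match="too many"):
            cd.fit_r2(vector_response(rng.standard_normal(6)), X)

    def test_weighted_r2_uses_weights(self, rng):
        # a response linear in X only at the heavily weighted sites
        y = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        w_hi = np.array([1, 1, 1, 1, 1e-9])
        fit_w = cd.fit_r2(vector_response(y, weights=w_hi), X)
        fit_u = cd.fit_r2(vector_response(y), X)
        assert fit_w.r2 == pytest.approx(1.0, abs=1e-4)
        assert fit_u.r2 < 0.9


class TestPartition:
    def test_fraction_identities(self, rng):
        for _ in range(25):
            resp = matrix_response(rng.standard_normal((12, 5)))
            E = block(rng.standard_normal((12, 3)))
            S = block(rng.standard_normal((12, 2)), role="space")
            res = cd.partition(resp, E, S)
            f, t = res.fractions, res.totals
            assert abs(sum(f.values()) - 1.0) < 1e-10
            assert f["a"] == pytest.approx(t["abc"] - t["bc"], abs=1e-10)
            assert f["c"] == pytest.approx(t["abc"] - t["ab"], abs=1e-10)
            assert f["d"] == pytest.approx(1.0 - t["abc"], abs=1e-10)
            assert all(v >= 0 for v in res.clamped.values())

    def test_shared_variance_when_blocks_identical(self, rng):
        x = rng.standard_normal(10)
        resp = vector_response(0.5 * x + 0.1 * rng.standard_normal(10))
        with pytest.warns(UserWarning, match="collinear"):
            res = cd.partition(resp, block(x), block(x, role="space"))
        assert res.fractions["a"] == pytest.approx(0.0, abs=1e-10)
        assert res.fractions["c"] == pytest.approx(0.0, abs=1e-10)
        assert res.fractions["b"] == pytest.approx(res.totals["ab"], abs=1e-10)

    def test_swapping_blocks_swaps_unique_fractions(self, rng):
        resp = matrix_response(rng.standard_normal((12, 4)))
        E = block(rng.standard_normal((12, 2)))
        S = block(rng.standard_normal((12, 2)), role="space")
        r1 = cd.partition(resp, E, S)
        r2 = cd.partition(resp,
                          cd.PredictorSet(role="environment", data=S.data),
                          cd.PredictorSet(role="space", data=E.data))
        assert r1.fractions["a"] == pytest.approx(r2.fractions["c"], abs=1e-10)
        assert r1.fractions["c"] == pytest.approx(r2.fractions["a"], abs=1e-10)
        assert r1.fractions["b"] == pytest.approx(r2.fractions["b"], abs=1e-10)
        assert r1.fractions["d"] == pytest.approx(r2.fractions["d"], abs=1e-10)

    def test_empty_block_zero_unique_fraction(self, rng):
        resp = matrix_response(rng.standard_normal((10, 3)))
        E = block(rng.standard_normal((10, 2)))
        S = cd.PredictorSet(role="space",
                            data=pd.DataFrame(index=E.data.index))
        res = cd.partition(resp, E, S)
        assert res.fractions["c"] == pytest.approx(0.0, abs=1e-12)
        assert res.fractions["b"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(InputError, match="zero-variance"):
            block(np.ones(8))


class TestSignificanceCode:
    @pytest.mark.parametrize("p,code", [
        (0.009, "**"), (0.01, "**"), (0.02, "*"), (0.05, "*"),
        (0.07, "@"), (0.10, "@"), (0.2, ""), (1.0, ""),
    ])
    def test_thresholds(self, p, code):
        assert cd.significance_code(p) == code

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            cd.significance_code(1.5)


class TestTestTaxonomic:
    def test_deterministic_under_fixed_seed(self, null_bundle):
        E, S = predictor_blocks(null_bundle)
        Yhel = cd.hellinger(null_bundle.abundance)
        p1 = cd.test_taxonomic(Yhel, E, S, nperm=99, seed=7)
        p2 = cd.test_taxonomic(Yhel, E, S, nperm=99, seed=7)
        assert p1 == p2

    def test_power_on_environment_driven_response(self, rng):
        # response a deterministic function of E, with S pure noise
        hits = 0
        for r in range(20):
            E_data = rng.standard_normal((15, 2))
            Y = np.column_stack([E_data @ [1.0, -0.5], E_data @ [0.5, 1.0]])
            Y = Y + 0.05 * rng.standard_normal(Y.shape)
            p = cd.test_taxonomic(
                matrix_response(Y), block(E_data),
                block(rng.standard_normal(15), role="space"),
                nperm=199, seed=r)
            hits += p["a"] <= 0.01
        assert hits >= 19

    def test_min_permutation_count_enforced(self, null_bundle):
        E, S = predictor_blocks(null_bundle)
        with pytest.raises(InputError, match="nperm"):
            cd.test_taxonomic(cd.hellinger(null_bundle.abundance), E, S, nperm=10)


class TestTestTrait:
    def test_constant_scores_rejected(self, null_bundle):
        E, S = predictor_blocks(null_bundle)
        species = null_bundle.abundance.species
        u = cd.SpeciesScores(ids=species,
                             scores=pd.Series(1.0, index=species),
                             eigenvalue=1.0, provenance="functional")
        with pytest.raises(UndefinedStatisticError):
            cd.test_trait(null_bundle.abundance, u, E, S, nperm=99, seed=0)

    def test_deterministic_under_fixed_seed(self, dispersion_bundle):
        E, S = predictor_blocks(dispersion_bundle)
        u = cd.species_scores(cd.gower(dispersion_bundle.pool.traits))
        p1 = cd.test_trait(dispersion_bundle.abundance, u, E, S, nperm=99, seed=3)
        p2 = cd.test_trait(dispersion_bundle.abundance, u, E, S, nperm=99, seed=3)
        assert p1 == p2

    def test_combined_p_is_max_of_schemes(self, dispersion_bundle):
        E, S = predictor_blocks(dispersion_bundle)
        u = cd.species_scores(cd.gower(dispersion_bundle.pool.traits))
        p = cd.test_trait(dispersion_bundle.abundance, u, E, S, nperm=99, seed=3)
        for key in ("a", "c", "env_model"):
            assert p[key] == max(p[f"{key}_site"], p[f"{key}_species"])
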