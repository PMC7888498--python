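"""Sampler building blocks: incidence assembly, truncated/conditional
draws, variance-component conditionals, chain protocol and determinism."""

import numpy as np
import pandas as pd
import pytest

from ltam import (
    ChainConfig, SampleStore, ThresholdAnimalModel, TraitSpec,
    ValidationError, build_matrices, renumber, PedigreeRecord,
    sample_liability, impute_missing_continuous, sample_G, sample_R,
)
from ltam.threshold_model import (
    truncated_normal, conditional_residual, animal_full_conditional,
    DEFAULT_TRAITS,
)
from ltam.pedigree import build_a_inverse, compute_inbreeding


def _table(n, rng, cg="c1", with_missing=False):
    df = pd.DataFrame({
        "sow": [f"s{i}" for i in range(n)],
        "cg": cg,
        "aff": rng.normal(367, 26, n).round(),
        "nba1": rng.normal(10, 2.5, n),
        "nba2": rng.normal(10, 2.5, n),
        "nba3": rng.normal(10, 2.5, n),
        "stay14": (rng.random(n) < 0.75).astype(float),
    })
    if with_missing:
        df.loc[df.index[:n // 4], "nba3"] = np.nan
        df.loc[df.index[:n // 8], "stay14"] = np.nan
    return df


class TestChainConfig:
    def test_default_protocol_stores_4000(self):
        assert ChainConfig().n_stored == 4000

    def test_short_protocols(self):
        assert ChainConfig(n_cycles=1000, burn_in=0, thin=1).n_stored == 1000
        assert ChainConfig(n_cycles=1000, burn_in=200, thin=10).n_stored == 80

    @pytest.mark.parametrize("kwargs", [
        {"burn_in": 1000, "n_cycles": 1000},
        {"thin": 0},
        {"n_cycles": 1000, "burn_in": 100, "thin": 7},
    ])
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValidationError):
            ChainConfig(**kwargs).validate()


class TestBuildMatrices:
    def test_masks_mirror_missingness(self, rng):
        df = _table(16, rng, with_missing=True)
        mats = build_matrices(df, None, DEFAULT_TRAITS)
        assert not mats.obs[0, 2]          # nba3 missing
        assert mats.ybin[0] == -1          # stay14 missing
        assert mats.obs[15, 2]

    def test_z_covers_recordless_parents(self, rng):
        recs = [PedigreeRecord("SIRE"), PedigreeRecord("DAM")]
        recs += [PedigreeRecord(f"s{i}", "SIRE", "DAM") for i in range(10)]
        ped = renumber(recs)
        df = _table(10, rng)
        mats = build_matrices(df, ped, DEFAULT_TRAITS)
        assert mats.n_animals == 12        # parents included

    def test_sow_absent_from_pedigree_is_named(self, rng):
        ped = renumber([PedigreeRecord("s0")])
        df = _table(2, rng)
        with pytest.raises(ValidationError, match="s1"):
            build_matrices(df, ped, DEFAULT_TRAITS)

    def test_extreme_category_groups_pooled_for_binary_only(self, rng):
        df = _table(60, rng)
        df["cg"] = ["g1"] * 25 + ["g2"] * 20 + ["g3"] * 10 + ["g4"] * 5
        df.loc[df.cg == "g3", "stay14"] = 1.0       # extreme levels with
        df.loc[df.cg == "g4", "stay14"] = 0.0       # opposite categories
        df.loc[df.cg == "g1", "stay14"] = ([0.0, 1.0] * 13)[:25]
        df.loc[df.cg == "g2", "stay14"] = [0.0, 1.0] * 10
        mats = build_matrices(df, None, DEFAULT_TRAITS)
        assert len(mats.cg_labels[0]) == 4          # continuous: untouched
        assert len(mats.cg_labels[3]) == 3          # 2 regular + pooled
        assert mats.cg_labels[3][-1] == "_pooled"

    def test_single_extreme_level_merges_into_largest_regular(self, rng):
        df = _table(60, rng)
        df["cg"] = ["g1"] * 30 + ["g2"] * 20 + ["g3"] * 10
        df.loc[df.cg == "g3", "stay14"] = 1.0       # all-one level
        df.loc[df.cg == "g1", "stay14"] = [0.0, 1.0] * 15
        df.loc[df.cg == "g2", "stay14"] = [0.0, 1.0] * 10
        mats = build_matrices(df, None, DEFAULT_TRAITS)
        assert len(mats.cg_labels[3]) == 2          # pool re-merged into g1
        vals = mats.y[mats.cg_idx[3] == 0, 3]
        assert np.nanmin(vals) == 0.0 and np.nanmax(vals) == 1.0


class TestTruncatedNormal:
    def test_half_normal_mean(self, rng):
        x = truncated_normal(rng, np.zeros(100_000), 1.0, lower=np.zeros(100_000))
        assert x.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    def test_respects_bounds_even_in_far_tails(self, rng):
        lower = np.full(1000, 8.0)   # bound far above the mean
        x = truncated_normal(rng, np.zeros(1000), 1.0, lower=lower)
        assert np.all(x > lower - 1e-12)
        upper = np.full(1000, -8.0)
        y = truncated_normal(rng, np.zeros(1000), 1.0, upper=upper)
        assert np.all(y < upper + 1e-12)


class TestConditionals:
    def test_bivariate_conditioning_shifts_mean(self):
        # residual correlation with NBA1 only: shift = (r1t/r11) * resid1
        R = np.eye(4)
        R[0, 3] = R[3, 0] = 0.6
        Rinv = np.linalg.inv(R)
        e = np.array([1.5, 0.0, 0.0, 0.0])
        m, sd = conditional_residual(Rinv, 3, e)
        assert m == pytest.approx((0.6 / 1.0) * 1.5)
        assert sd == pytest.approx(np.sqrt(1 - 0.36))

    def test_liability_sign_contract(self, rng):
        R = np.eye(4)
        for cat, sign in ((1, 1.0), (0, -1.0)):
            draws = [sample_liability(rng, R, 3, lp=0.3, e_row=np.zeros(4),
                                      category=cat) for _ in range(200)]
            lia = 0.3 + np.array(draws)
            assert np.all(sign * lia >= 0)

    def test_imputation_regression_slope(self, rng):
        # strong residual correlation 0.9 between nba2 and nba3
        R = np.eye(4)
        R[1, 2] = R[2, 1] = 0.9
        e = np.array([0.0, 2.0, 0.0, 0.0])
        missing = np.array([False, False, True, False])
        draws = np.array([
            impute_missing_continuous(rng, R, e, missing)[2]
            for _ in range(4000)
        ])
        assert draws.mean() == pytest.approx(0.9 * 2.0, abs=0.05)

    def test_imputation_noop_on_complete_record(self, rng):
        e = np.array([1.0, 2.0, 3.0, 0.5])
        out = impute_missing_continuous(rng, np.eye(4), e, np.zeros(4, bool))
        assert np.array_equal(out, e)

    def test_recordless_animal_mean_is_parent_average(self):
        # trio: child without records; conditional mean = (a_s + a_d) / 2
        ped = renumber([PedigreeRecord("S"), PedigreeRecord("D"),
                        PedigreeRecord("C", "S", "D")])
        ainv = build_a_inverse(ped, compute_inbreeding(ped)).toarray()
        T = 2
        G = np.array([[0.4, 0.1], [0.1, 0.3]])
        a = np.array([[1.0, -1.0], [0.5, 0.2], [0.0, 0.0]])
        k = ped.code("C") - 1
        neigh = sum(ainv[k, j] * a[j] for j in range(3) if j != k)
        mean, _ = animal_full_conditional(
            k, a, e_sum=np.zeros(T), cnt=0, akk=ainv[k, k], neigh=neigh,
            Rinv=np.eye(T), Ginv=np.linalg.inv(G),
        )
        assert np.allclose(mean, 0.5 * (a[0] + a[1]))


class TestVarianceConditionals:
    def test_sample_G_prior_only_when_a_zero(self, rng):
        import scipy.sparse as sp
        n, T = 40, 2
        a = np.zeros((n, T))
        ainv = sp.identity(n, format="csr")
        S0 = np.array([[2.0, 0.3], [0.3, 1.0]])
        nu0 = 6.0
        draws = np.stack([sample_G(a, ainv, nu0, S0, rng) for _ in range(3000)])
        expected = S0 / (n + nu0 - T - 1)
        assert np.allclose(draws.mean(axis=0), expected, atol=0.01)

    def test_sample_G_flat_closed_form_founders(self, rng):
        import scipy.sparse as sp
        n = 400
        a = rng.standard_normal((n, 1)) * 2.0
        ainv = sp.identity(n, format="csr")
        draws = np.array([sample_G(a, ainv, 0.0, None, rng)[0, 0]
                          for _ in range(4000)])
        assert draws.mean() == pytest.approx(float(a[:, 0] @ a[:, 0]) / (n - 2),
                                             rel=0.05)

    def test_sample_R_pins_binary_variance_exactly(self, rng):
        n = 500
        e = rng.standard_normal((n, 4)) * np.array([2.0, 2.0, 2.0, 1.0])
        Se = e.T @ e
        R_prev = np.eye(4)
        for _ in range(50):
            R = sample_R(Se, n, DEFAULT_TRAITS, 0.0, None, R_prev, rng)
            assert R[3, 3] == 1.0
            np.linalg.cholesky(R)
            R_prev = R

    def test_sample_R_zero_cov_option(self, rng):
        n = 500
        e = rng.standard_normal((n, 4))
        R = sample_R(e.T @ e, n, DEFAULT_TRAITS, 0.0, None, np.eye(4), rng,
                     zero_resid_cov_binary=True)
        assert np.allclose(R[:3, 3], 0.0)
        assert R[3, 3] == 1.0


class TestChain:
    def test_two_trait_residual_correlation_recovery(self, rng):
        # one continuous + one binary, iid records, true residual corr 0.5
        n = 3000
        L = np.linalg.cholesky(np.array([[4.0, 0.5 * 2.0], [0.5 * 2.0, 1.0]]))
        e = rng.standard_normal((n, 2)) @ L.T
        df = pd.DataFrame({
            "sow": [f"i{k}" for k in range(n)], "cg": "c1",
            "y": 8.0 + e[:, 0], "s": ((0.5 + e[:, 1]) > 0).astype(float),
        })
        traits = (TraitSpec("y", use_aff=False),
                  TraitSpec("s", "binary", use_aff=False))
        m = ThresholdAnimalModel(traits=traits, n_cycles=4000, burn_in=1000,
                                 thin=3, seed=4).fit(df, pedigree=None)
        R = m.store_.R
        r = R[:, 0, 1] / np.sqrt(R[:, 0, 0] * R[:, 1, 1])
        assert r.mean() == pytest.approx(0.5, abs=0.1)

    def test_same_seed_is_bitwise_reproducible(self, rng):
        df = _table(40, rng)
        recs = [PedigreeRecord(f"s{i}") for i in range(40)]
        kw = dict(n_cycles=300, burn_in=100, thin=10, seed=11)
        m1 = ThresholdAnimalModel(**kw).fit(df, pedigree=recs)
        m2 = ThresholdAnimalModel(**kw).fit(df, pedigree=recs)
        assert np.array_equal(m1.store_.G, m2.store_.G)
        assert np.array_equal(m1.store_.R, m2.store_.R)

    def test_store_roundtrip(self, rng, tmp_path):
        df = _table(30, rng)
        m = ThresholdAnimalModel(n_cycles=200, burn_in=100, thin=10,
                                 seed=5).fit(df, pedigree=None)
        path = tmp_path / "samples.csv"
        m.store_.save(path)
        back = SampleStore.load(path)
        assert np.allclose(back.G, m.store_.G)
        assert np.allclose(back.R, m.store_.R)
        assert back.trait_names == m.store_.trait_names
        assert np.array_equal(back.cycles, m.store_.cycles)

    def test_stored_count_matches_protocol(self, rng):
        df = _table(30, rng)
        m = ThresholdAnimalModel(n_cycles=1000, burn_in=200, thin=10,
                                 seed=5).fit(df, pedigree=None)
        assert m.n_stored_ == 80
        assert m.store_.cycles[0] == 210
        assert m.store_.cycles[-1] == 1000

    def test_invariants_hold_along_chain(self, rng):
        # PD covariances, pinned liability variance, liability/category
        # consistency, checked inside the chain every 50 cycles
        df = _table(120, rng, with_missing=True)
        recs = [PedigreeRecord(f"s{i}") for i in range(120)]
        m = ThresholdAnimalModel(n_cycles=500, burn_in=100, thin=10, seed=9,
                                 validate_every=50).fit(df, pedigree=recs)
        assert np.all(m.store_.R[:, 3, 3] == 1.0)
        for s in range(m.store_.n_samples):
            np.linalg.cholesky(m.store_.G[s])
            np.linalg.cholesky(m.store_.R[s])
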