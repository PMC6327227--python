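"""Negative-binomial interaction testing, loop detection, differential testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

import loopshift as ls
from loopshift.contact import BiasVector, ExpectedModel, NormalizedMatrix
from loopshift.loops import (
    LoopRecord,
    NeighborhoodAggregate,
    UntestablePixel,
    aggregate_neighborhood,
    call_loops,
    detect_loops,
    estimate_dispersions,
    nb_fit_intercept,
    neighborhood_sum,
    test_differential_loops as differential_loop_test,
    test_interactions as interaction_test,
)
from tests.test_contact import make_matrix


def flat_model(n, e_const=1.0, bias=None):
    b = BiasVector(np.ones(n) if bias is None else bias)
    return ExpectedModel("chrT", 10_000, np.full(n, e_const), b)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


class TestAggregation:
    def test_constant_matrix_sums_nine_pixels(self):
        dense = np.full((12, 12), 5)
        m = make_matrix(np.triu(dense))
        agg = aggregate_neighborhood(m, flat_model(12), (2, 8))
        assert agg.c_prime[0] == 45
        assert agg.neighborhood_size == 9

    def test_toy_block_hand_sum(self):
        dense = np.zeros((9, 9), dtype=int)
        block = np.arange(1, 10).reshape(3, 3)
        dense[1:4, 5:8] = block
        m = make_matrix(np.triu(dense))
        agg = aggregate_neighborhood(m, flat_model(9), (2, 6))
        assert agg.c_prime[0] == 45  # 1 + 2 + ... + 9

    def test_center_near_diagonal_untestable(self):
        dense = np.full((10, 10), 3)
        m = make_matrix(np.triu(dense))
        with pytest.raises(UntestablePixel):
            aggregate_neighborhood(m, flat_model(10), (4, 5))

    def test_band_sum_matches_brute_force(self):
        rng = np.random.default_rng(0)
        n, D = 30, 12
        band = rng.poisson(4.0, (n, D + 1)).astype(float)
        for d in range(D + 1):
            band[n - d :, d] = np.nan
        out = neighborhood_sum(band)
        dense = np.full((n, n), np.nan)
        for i in range(n):
            for d in range(min(D + 1, n - i)):
                dense[i, i + d] = band[i, d]
        for i in range(n):
            for d in range(3, D - 1):
                j = i + d
                if j + 1 >= n:
                    continue
                sub = [dense[i + a, j + b] for a in (-1, 0, 1) for b in (-1, 0, 1)]
                assert np.isclose(out[i, d], np.sum(sub), equal_nan=True)


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------


def cml_oracle(counts):
    """Scalar conditional-ML dispersion over all pixels (scipy brute force)."""

    def nll(la):
        theta = np.exp(-la)
        z = counts.sum(axis=1)
        R = counts.shape[1]
        return -float(
            np.sum(special.gammaln(counts + theta))
            - counts.size * special.gammaln(theta)
            + counts.shape[0]
            * (special.gammaln(R * theta))
            - np.sum(special.gammaln(z + R * theta))
        )

    res = optimize.minimize_scalar(nll, bounds=(np.log(1e-8), np.log(30)), method="bounded")
    return float(np.exp(res.x))


class TestDispersions:
    def test_poisson_replicates_give_near_zero_alpha(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(100.0, (2000, 2))
        est = estimate_dispersions(counts)
        assert np.median(est.alpha) <= 0.02

    def test_nb_alpha_recovered_within_band_and_matches_oracle(self):
        rng = np.random.default_rng(11)
        mu, alpha = 100.0, 0.1
        lam = rng.gamma(1 / alpha, alpha * mu, (2000, 2))
        counts = rng.poisson(lam)
        est = estimate_dispersions(counts)
        med = float(np.median(est.alpha))
        assert 0.05 <= med <= 0.2
        assert np.isclose(med, cml_oracle(counts.astype(float)), rtol=0.5)

    def test_identical_replicates_hit_floor(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 2)).astype(float)
        est = estimate_dispersions(counts)
        assert np.all(est.alpha <= 1e-6)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(np.ones((10, 1)))


# ---------------------------------------------------------------------------
# Interaction testing
# ---------------------------------------------------------------------------


def nb_oracle_fit(counts, s_prime, alpha):
    """Brute-force NB ML for a single pixel + Wald p (independent of the package)."""
    theta = 1.0 / alpha

    def nll(beta):
        mu = np.exp(beta) * s_prime
        return -float(
            np.sum(
                special.gammaln(counts + theta)
                - special.gammaln(theta)
                - special.gammaln(counts + 1)
                + counts * np.log(mu / (mu + theta))
                + theta * np.log(theta / (mu + theta))
            )
        )

    res = optimize.minimize_scalar(nll, bounds=(-20, 20), method="bounded",
                                   options={"xatol": 1e-12})
    beta = res.x
    h = 1e-5
    d2 = (nll(beta + h) - 2 * nll(beta) + nll(beta - h)) / h**2
    se = 1.0 / np.sqrt(d2)
    z = beta / se
    return beta, float(stats.norm.sf(z))


class TestInteractionTesting:
    def test_null_identity_produces_no_calls(self):
        aggs = [
            NeighborhoodAggregate((i, i + 20), np.array([50.0, 50.0]), np.array([50.0, 50.0]))
            for i in range(50)
        ]
        disp = ls.DispersionEstimate(alpha=np.full(50, 0.05))
        df = interaction_test(aggs, disp)
        assert np.all(np.abs(df["beta"]) < 1e-6)
        assert np.all(df["wald_p"] >= 0.5 - 1e-9)
        assert not df["significant"].any()

    def test_single_pixel_matches_brute_force_oracle(self):
        agg = NeighborhoodAggregate((0, 20), np.array([50.0, 50.0]), np.array([10.0, 10.0]))
        disp = ls.DispersionEstimate(alpha=np.array([0.05]))
        df = interaction_test([agg], disp)
        beta_o, p_o = nb_oracle_fit(np.array([50.0, 50.0]), 10.0, 0.05)
        assert df["beta"].iloc[0] == pytest.approx(np.log(5.0), rel=1e-8)
        assert df["beta"].iloc[0] == pytest.approx(beta_o, rel=1e-6)
        assert df["wald_p"].iloc[0] == pytest.approx(p_o, rel=1e-4)

    def test_fit_matches_oracle_on_random_pixels(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            counts = rng.poisson(rng.uniform(5, 200), 2).astype(float) + 1
            s = rng.uniform(2, 100)
            alpha = rng.uniform(1e-4, 0.3)
            beta, se = nb_fit_intercept(
                counts[None, :], np.log(np.full((1, 2), s)), np.array([alpha])
            )
            beta_o, _ = nb_oracle_fit(counts, s, alpha)
            assert beta[0] == pytest.approx(beta_o, rel=1e-6, abs=1e-8)

    def test_planted_fivefold_pixels_recovered_with_fdr_control(self):
        rng = np.random.default_rng(13)
        n_null, n_sig = 5000, 20
        s = 100.0
        c_null = rng.poisson(s, (n_null, 2)).astype(float)
        c_sig = rng.poisson(5 * s, (n_sig, 2)).astype(float)
        aggs = [
            NeighborhoodAggregate((0, k), c, np.array([s, s]))
            for k, c in enumerate(np.vstack([c_null, c_sig]))
        ]
        disp = estimate_dispersions(np.vstack([c_null, c_sig]))
        df = interaction_test(aggs, disp)
        called = df["significant"].to_numpy()
        assert called[n_null:].sum() >= 18
        fdr = called[:n_null].sum() / max(called.sum(), 1)
        assert fdr <= 0.25


# ---------------------------------------------------------------------------
# Loop detection
# ---------------------------------------------------------------------------


def _norm_from_dense(dense):
    n = dense.shape[0]
    rows, cols = np.triu_indices(n)
    return NormalizedMatrix(
        "chrT", 10_000, n, rows, cols, dense[rows, cols].astype(float),
        BiasVector(np.ones(n)),
    )


def _calls_frame(pixels, p=1e-9):
    return pd.DataFrame(
        {
            "i": [a for a, _ in pixels],
            "j": [b for _, b in pixels],
            "beta": 1.0,
            "se": 0.1,
            "wald_p": p,
            "adj_p": p,
            "fold_change": 5.0,
            "significant": True,
        }
    )


class TestLoopDetection:
    def test_no_significant_pixels_gives_empty_set(self):
        norm = _norm_from_dense(np.full((40, 40), 2.0))
        assert detect_loops(_calls_frame([]), norm) == []

    def test_adjacent_pixels_merge_into_single_loop(self):
        dense = np.full((60, 60), 2.0)
        dense[20, 40] = dense[20, 41] = 60.0
        norm = _norm_from_dense(dense)
        loops = detect_loops(_calls_frame([(20, 40), (20, 41)]), norm)
        assert len(loops) == 1
        assert loops[0].anchor3 == (40 * 10_000 - 10_000, 42 * 10_000 + 10_000)
        assert loops[0].anchor5 == (20 * 10_000 - 10_000, 21 * 10_000 + 10_000)

    def test_short_separation_excluded(self):
        dense = np.full((60, 60), 2.0)
        dense[20, 26] = dense[20, 27] = 60.0
        norm = _norm_from_dense(dense)
        assert detect_loops(_calls_frame([(20, 26), (20, 27)]), norm) == []

    def test_background_filter_rejects_non_focal_pixel(self):
        # smoothly elevated region, no focal peak: pixel only 1.2x its donut
        dense = np.full((60, 60), 10.0)
        dense[18:23, 38:44] = 12.0
        norm = _norm_from_dense(dense)
        assert detect_loops(_calls_frame([(20, 40), (20, 41)]), norm) == []


# ---------------------------------------------------------------------------
# Differential loop strength
# ---------------------------------------------------------------------------


def _loop_records(loops, bs=10_000):
    return [
        LoopRecord(
            chromosome="chrS",
            anchor5=((i - 1) * bs, (i + 2) * bs),
            anchor3=((j - 1) * bs, (j + 2) * bs),
            pixel_cluster=frozenset({(i, j)}),
        )
        for i, j, _ in loops
    ]


@pytest.fixture(scope="module")
def differential_setup(planted_maps):
    maps, truth = planted_maps
    raws = {1: [maps[(0, 0)], maps[(0, 1)]], 2: [maps[(1, 0)], maps[(1, 1)]]}
    models = {
        c: [ls.fit_expected(ls.ipf_normalize(m)[1]) for m in raws[c]] for c in raws
    }
    return raws, models, truth


class TestDifferentialLoops:
    def test_identical_conditions_yield_null_classes(self, differential_setup):
        raws, models, truth = differential_setup
        same = {1: raws[1], 2: raws[1]}
        same_models = {1: models[1], 2: models[1]}
        res = differential_loop_test(_loop_records(truth.loops), same, same_models)
        assert np.all(np.abs(res["gamma"]) < 0.05)
        assert not np.any(np.isin(res["class"], ["induced", "reduced"]))
        assert np.all(res.loc[2.0 ** np.abs(res["gamma"]) < 1.25, "class"] == "common")

    def test_planted_induction_detected_and_condition_swap_negates(
        self, differential_setup
    ):
        raws, models, truth = differential_setup
        recs = _loop_records(truth.loops)
        res = differential_loop_test(recs, raws, models, fdr=0.05)
        induced_members = set()
        for _, row in res[res["class"] == "induced"].iterrows():
            induced_members.update(row["loop_members"])
        planted = {k for k, f in enumerate(truth.loop_condition_factors) if f > 1}
        assert planted <= induced_members
        # label swap: gamma negated, induced <-> reduced
        swapped = differential_loop_test(
            recs, {1: raws[2], 2: raws[1]}, {1: models[2], 2: models[1]}, fdr=0.05
        )
        assert np.allclose(swapped["gamma"], -res["gamma"], atol=1e-8)
        assert np.all(
            (res["class"] == "induced") == (swapped["class"] == "reduced")
        )

    def test_overlapping_areas_merge(self, differential_setup):
        raws, models, _ = differential_setup
        recs = _loop_records([(100, 150, 1.0), (101, 151, 1.0), (300, 400, 1.0)])
        res = differential_loop_test(recs, raws, models)
        assert len(res) == 2
        merged = [m for m in res["loop_members"] if len(m) == 2]
        assert merged and sorted(merged[0]) == [0, 1]

    def test_replicate_mismatch_rejected(self, differential_setup):
        raws, models, truth = differential_setup
        bad = {1: raws[1], 2: raws[2][:1]}
        with pytest.raises(ValueError, match="replicate count"):
            differential_loop_test(_loop_records(truth.loops), bad, models)

    def test_monotonicity_of_gamma_in_condition2_counts(self):
        # raising condition-2 counts at one area never decreases gamma
        base = np.array([[40.0, 44.0]])
        s = np.log(np.full((1, 2), 40.0))
        alpha = np.array([0.05])
        prev = -np.inf
        for bump in (0, 10, 25, 60, 140):
            b2, _ = nb_fit_intercept(base + bump, s, alpha)
            assert b2[0] >= prev - 1e-12
            prev = b2[0]


def test_end_to_end_loop_calling_recovers_planted_loops(planted_maps):
    maps, truth = planted_maps
    recs, calls = call_loops([maps[(0, 0)], maps[(0, 1)]])
    recovered = sum(
        1
        for a, b, _ in truth.loops
        if any(
            any(abs(i - a) <= 1 and abs(j - b) <= 1 for (i, j) in lp.pixel_cluster)
            for lp in recs
        )
    )
    assert recovered >= 0.8 * len(truth.loops)
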