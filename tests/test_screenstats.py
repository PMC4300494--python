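import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sensikit.quant import CountMatrix, SampleSheet
from sensikit.screenstats import (
    DISPERSION_FLOOR,
    Contrast,
    estimate_dispersions,
    estimate_size_factors,
    nbinom_test,
    screen_differential,
    treated_vs_dmso,
)
from sensikit.simulate import PlantedSensitizer, ScreenSimConfig, simulate_screen


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def size_factors_oracle(counts: pd.DataFrame) -> pd.Series:
    """Brute-force median-of-ratios, coded straight from the definition."""
    rows = [
        i
        for i in counts.index
        if all(counts.loc[i, c] > 0 for c in counts.columns)
    ]
    out = {}
    for col in counts.columns:
        ratios = []
        for i in rows:
            geo = math.prod(float(counts.loc[i, c]) for c in counts.columns) ** (
                1.0 / counts.shape[1]
            )
            ratios.append(float(counts.loc[i, col]) / geo)
        out[col] = float(np.median(ratios))
    return pd.Series(out)


def nbinom_test_oracle(ka, kb, sa, sb, alpha):
    """Direct enumeration of the conditioned exact test in plain Python."""
    ka, kb = list(ka), list(kb)
    K_a, K_b = sum(ka), sum(kb)
    K = K_a + K_b
    S_a, S_b = sum(sa), sum(sb)
    q0 = K / (S_a + S_b)

    def pmf(x, mu, var):
        if var > mu:
            r = mu * mu / (var - mu)
            return stats.nbinom.pmf(x, r, r / (r + mu))
        return stats.poisson.pmf(x, mu)

    mu_a, mu_b = q0 * S_a, q0 * S_b
    var_a = mu_a + alpha * q0**2 * sum(s * s for s in sa)
    var_b = mu_b + alpha * q0**2 * sum(s * s for s in sb)
    probs = [pmf(a, mu_a, var_a) * pmf(K - a, mu_b, var_b) for a in range(K + 1)]
    obs = probs[K_a]
    total = sum(probs)
    return sum(p for p in probs if p <= obs * (1 + 1e-7)) / total


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_column(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = estimate_size_factors(counts)
        assert sf["a"] == pytest.approx(1 / math.sqrt(2), abs=1e-12)
        assert sf["b"] == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(50, size=(50, 6)), columns=[f"s{i}" for i in range(6)]
        )
        sf = estimate_size_factors(counts)
        oracle = size_factors_oracle(counts)
        assert np.allclose(sf, oracle[sf.index], atol=1e-10)

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(rng.poisson(30, size=(40, 4)), columns=list("abcd"))
        perm = counts.sample(frac=1.0, random_state=1)
        assert np.allclose(estimate_size_factors(counts), estimate_size_factors(perm))

    def test_all_zero_row_matrix_errors(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            estimate_size_factors(counts)


class TestDispersions:
    @staticmethod
    def _sf(cols):
        return pd.Series(1.0, index=cols)

    def test_underdispersed_clamped_to_floor(self):
        counts = pd.DataFrame({"a": [10], "b": [14]}, index=["h1"])
        model = estimate_dispersions(
            counts, self._sf(counts.columns), groups=[["a", "b"]]
        )
        # mu=12, var=8 < mu → raw clamped
        assert model.raw["h1"] == DISPERSION_FLOOR

    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.poisson(100, size=(2000, 6)), columns=[f"s{i}" for i in range(6)]
        )
        model = estimate_dispersions(
            counts,
            self._sf(counts.columns),
            groups=[["s0", "s1", "s2"], ["s3", "s4", "s5"]],
        )
        # Poisson → raw alphas scattered around 0, half clamped at the floor
        assert np.median(model.final) < 0.01
        a0, _ = model.trend_coef
        assert abs(a0) < 0.01

    def test_nb_simulated_dispersion_recovered(self):
        rng = np.random.default_rng(8)
        alpha, mu = 0.2, 200.0
        r = 1 / alpha
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(1000, 3)),
            columns=["a", "b", "c"],
        )
        model = estimate_dispersions(
            counts, self._sf(counts.columns), groups=[["a", "b", "c"]]
        )
        assert 0.1 < np.median(model.raw) < 0.3

    def test_single_replicate_errors(self):
        counts = pd.DataFrame({"a": [10]}, index=["h1"])
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(counts, self._sf(["a"]), groups=[["a"]])

    def test_fit_only_uses_trend(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 4)), columns=list("abcd"))
        m = estimate_dispersions(
            counts, self._sf(counts.columns), groups=[list("ab"), list("cd")],
            sharing="fit-only",
        )
        assert np.allclose(m.final, m.fitted)


class TestNbinomTest:
    def test_symmetric_split(self):
        fc, p = nbinom_test([10, 10], [10, 10], [1, 1], [1, 1], 0.1)
        assert fc == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_spec_case_zero_vs_twenty(self):
        fc, p = nbinom_test([0], [20], [1.0], [1.0], 0.1)
        oracle = nbinom_test_oracle([0], [20], [1.0], [1.0], 0.1)
        assert p == pytest.approx(oracle, abs=1e-12)
        assert fc == np.inf

    def test_matches_enumeration_oracle_randomized(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            ka = rng.integers(0, 30, size=3)
            kb = rng.integers(0, 30, size=3)
            if ka.sum() + kb.sum() == 0:
                continue
            sa = rng.uniform(0.5, 2.0, size=3)
            sb = rng.uniform(0.5, 2.0, size=3)
            alpha = rng.uniform(0.0, 0.5)
            _, p = nbinom_test(ka, kb, sa, sb, alpha)
            oracle = nbinom_test_oracle(list(ka), list(kb), list(sa), list(sb), alpha)
            assert p == pytest.approx(oracle, abs=1e-9)

    def test_poisson_limit_matches_conditioned_binomial(self):
        """At alpha → floor the test converges to a conditioned binomial."""
        ka, kb = [40, 52, 47], [61, 58, 70]
        sa = sb = [1.0, 1.0, 1.0]
        _, p = nbinom_test(ka, kb, sa, sb, DISPERSION_FLOOR)
        K_a, K = sum(ka), sum(ka) + sum(kb)
        probs = stats.binom.pmf(np.arange(K + 1), K, 0.5)
        p_binom = probs[probs <= probs[K_a] * (1 + 1e-7)].sum()
        assert p == pytest.approx(p_binom, abs=1e-3)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ka = rng.integers(1, 50, size=3)
            kb = rng.integers(1, 50, size=3)
            sa = rng.uniform(0.5, 2, size=3)
            sb = rng.uniform(0.5, 2, size=3)
            fc1, p1 = nbinom_test(ka, kb, sa, sb, 0.1)
            fc2, p2 = nbinom_test(kb, ka, sb, sa, 0.1)
            assert fc2 == pytest.approx(1 / fc1, rel=1e-12)
            assert p2 == pytest.approx(p1, abs=1e-12)

    def test_both_zero_sentinel(self):
        fc, p = nbinom_test([0, 0], [0, 0], [1, 1], [1, 1], 0.1)
        assert np.isnan(fc)
        assert p == 1.0

    def test_column_scaling_leaves_fold_change_unchanged(self):
        """Scaling a column together with its size factor preserves normalized
        means (hence fold changes) exactly; the conditioned p-value moves only
        slightly because it is computed on raw group sums."""
        ka, kb = np.array([80, 75, 90]), np.array([60, 66, 58])
        sa = sb = np.ones(3)
        fc1, p1 = nbinom_test(ka, kb, sa, sb, 0.05)
        ka2, sa2 = ka.copy(), sa.copy()
        ka2[0] *= 2
        sa2[0] = 2.0
        fc2, p2 = nbinom_test(ka2, kb, sa2, sb, 0.05)
        assert fc2 == pytest.approx(fc1, rel=1e-12)
        assert p2 == pytest.approx(p1, abs=0.2)


class TestScreenDifferential:
    def test_planted_gene_ranks_first(self, planted_screen):
        _, lib, _, cm, _ = planted_screen
        res = screen_differential(cm, treated_vs_dmso("PLX", 7), library=lib)
        assert res.iloc[0]["gene"] == "HIT1"
        hit = res[res["gene"] == "HIT1"]
        assert (hit["fold_change"] < 0.66).all()

    def test_all_zero_hairpin_dropped(self, planted_screen):
        _, lib, sheet, cm, _ = planted_screen
        counts = cm.counts.copy()
        counts.iloc[0] = 0
        cm0 = CountMatrix(counts, sheet)
        res = screen_differential(cm0, treated_vs_dmso("PLX", 7), library=lib)
        assert counts.index[0] not in set(res["hairpin_id"])
        assert len(res) == len(counts) - 1

    def test_empty_contrast_group_errors(self, planted_screen):
        _, lib, _, cm, _ = planted_screen
        bad = Contrast("x", {"condition": "treated", "treatment": "PLX", "day": 0}, {"condition": "DMSO", "day": 7})
        with pytest.raises(ValueError, match="empty group"):
            screen_differential(cm, bad)

    def test_deterministic_ordering(self, planted_screen):
        _, lib, _, cm, _ = planted_screen
        r1 = screen_differential(cm, treated_vs_dmso("SCH", 7), library=lib)
        r2 = screen_differential(cm, treated_vs_dmso("SCH", 7), library=lib)
        pd.testing.assert_frame_equal(r1, r2)
        assert (r1["p_value"].diff().dropna() >= 0).all()

    def test_bh_column_ge_raw(self, planted_screen):
        _, lib, _, cm, _ = planted_screen
        res = screen_differential(cm, treated_vs_dmso("PLX", 4), library=lib)
        assert (res["bh_adjusted_p"] >= res["p_value"] - 1e-15).all()
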