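"""Type-1 SDT estimates and the meta-d' maximum-likelihood fit."""

import numpy as np
import pandas as pd
import pytest

from metacog.metad import (
    CELL_PAD,
    counts_from_trials,
    fit_meta_d,
    fit_type1,
    mean_confidence,
    pad_counts,
)
from metacog.observers import simulate_sdt_trials


def _counts_from_rates(hit_rate, fa_rate, n=100000):
    """Exact type-1 count table (confidence collapsed into level 1)."""
    c = np.zeros((2, 2, 4))
    c[1, 1, 0] = hit_rate * n
    c[1, 0, 0] = (1 - hit_rate) * n
    c[0, 1, 0] = fa_rate * n
    c[0, 0, 0] = (1 - fa_rate) * n
    return c


class TestCounts:
    def test_tabulation_totals(self, rng):
        df = simulate_sdt_trials(123, 1.0, rng=rng)
        counts = counts_from_trials(df)
        assert counts.sum() == 123

    def test_order_invariance(self, rng):
        df = simulate_sdt_trials(200, 1.0, rng=rng)
        shuffled = df.sample(frac=1.0, random_state=0)
        assert (counts_from_trials(df) == counts_from_trials(shuffled)).all()

    def test_all_correct_leaves_error_cells_empty(self):
        df = pd.DataFrame(
            {"true_class": [0, 1, 1], "response": [0, 1, 1], "confidence": [2, 3, 4]}
        )
        counts = counts_from_trials(df)
        assert counts[0, 1].sum() == 0 and counts[1, 0].sum() == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            counts_from_trials(pd.DataFrame({"true_class": [], "response": [], "confidence": []}))

    def test_padding_adds_uniform_constant(self):
        c = np.zeros((2, 2, 4), dtype=int)
        assert (pad_counts(c) == CELL_PAD).all()


class TestType1:
    def test_chance_rates_give_zero_dprime(self):
        d, c = fit_type1(_counts_from_rates(0.5, 0.5))
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_rates_give_zero_criterion(self):
        d, c = fit_type1(_counts_from_rates(0.7, 0.3))
        assert c == pytest.approx(0.0, abs=1e-9)

    def test_unit_z_rates_give_dprime_two(self):
        # z(0.8413) = 1 = -z(0.1587)
        d, c = fit_type1(_counts_from_rates(0.8413, 0.1587))
        assert d == pytest.approx(2.0, abs=0.01)

    def test_degenerate_rates_rejected(self):
        with pytest.raises(ValueError):
            fit_type1(_counts_from_rates(1.0, 0.0))


class TestMetaDFit:
    def test_ideal_observer_ratio_near_one(self, rng):
        df = simulate_sdt_trials(10000, 1.5, 0.0, meta_ratio=None, rng=rng)
        fit = fit_meta_d(counts_from_trials(df))
        assert 0.9 <= fit.ratio <= 1.1
        assert fit.converged

    def test_recovers_half_efficiency(self, rng):
        df = simulate_sdt_trials(20000, 2.0, 0.0, meta_ratio=0.5, rng=rng)
        fit = fit_meta_d(counts_from_trials(df))
        assert fit.meta_d_prime == pytest.approx(1.0, abs=0.12)

    def test_recovery_band_at_moderate_n(self, rng):
        df = simulate_sdt_trials(20000, 1.5, 0.0, meta_ratio=0.7, rng=rng)
        fit = fit_meta_d(counts_from_trials(df))
        assert 0.63 <= fit.ratio <= 0.77

    def test_shuffled_confidence_destroys_type2_information(self, rng):
        df = simulate_sdt_trials(8000, 1.5, 0.0, meta_ratio=None, rng=rng)
        # permute confidence within each response, breaking its link to accuracy
        for r in (0, 1):
            idx = df.index[df.response == r]
            df.loc[idx, "confidence"] = rng.permutation(df.loc[idx, "confidence"].to_numpy())
        fit = fit_meta_d(counts_from_trials(df))
        assert abs(fit.meta_d_prime) < 0.15

    def test_scale_invariance_of_mle(self, rng):
        df = simulate_sdt_trials(500, 1.2, 0.1, meta_ratio=0.8, rng=rng)
        counts = counts_from_trials(df)
        f1 = fit_meta_d(pad_counts(counts), pad=False)
        f5 = fit_meta_d(pad_counts(counts) * 5.0, pad=False)
        assert f1.meta_d_prime == pytest.approx(f5.meta_d_prime, abs=1e-3)
        assert f5.neg_log_likelihood == pytest.approx(5 * f1.neg_log_likelihood, rel=1e-6)

    def test_fit_beats_efficiency_one_hypothesis(self, rng):
        """The fitted optimum's likelihood is at least that of the
        meta-d' = d' model with the same optimised criteria."""
        from metacog.metad import _nll

        df = simulate_sdt_trials(2000, 1.5, 0.0, meta_ratio=0.6, rng=rng)
        counts = pad_counts(counts_from_trials(df))
        fit = fit_meta_d(counts, pad=False)
        c_rel = fit.criterion / fit.d_prime
        # same optimiser applied with meta-d' pinned at d' cannot do better
        from scipy.optimize import minimize

        res = minimize(
            lambda t: _nll(np.concatenate(([fit.d_prime], t)), counts, c_rel),
            np.log(np.full(6, 0.4)),
            method="L-BFGS-B",
        )
        assert fit.neg_log_likelihood <= res.fun + 1e-6

    def test_negative_meta_d_yields_nan_log_ratio(self):
        # confidence anticorrelated with accuracy: high confidence on errors
        rows = []
        rng = np.random.default_rng(0)
        df = simulate_sdt_trials(4000, 1.5, 0.0, meta_ratio=None, rng=rng)
        df["confidence"] = 5 - df["confidence"]  # invert the scale
        fit = fit_meta_d(counts_from_trials(df))
        assert fit.meta_d_prime < 0
        assert np.isnan(fit.log_ratio)

    def test_median_recovery_tracks_generating_ratio(self, rng):
        """Parameter recovery across simulated observers (reduced-n version
        of the full recovery suite)."""
        for m in (0.5, 1.0):
            ratios = [
                fit_meta_d(
                    counts_from_trials(
                        simulate_sdt_trials(1000, 1.5, 0.0, meta_ratio=m, rng=rng)
                    )
                ).ratio
                for _ in range(30)
            ]
            assert np.median(ratios) == pytest.approx(m, abs=0.1)


class TestMeanConfidence:
    @pytest.mark.parametrize(
        "ratings,expected",
        [([4, 4, 4], 4.0), ([1, 3, 1, 3], 2.0), ([1, 2, 3, 4], 2.5)],
    )
    def test_values(self, ratings, expected):
        assert mean_confidence(np.array(ratings)) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_confidence(np.array([]))
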