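"""The three fitting algorithms: contracts, determinism, baseline orderings."""

import numpy as np
import pytest

import scalefit as sf
from scalefit._errors import UnimputableColumnError

from .conftest import manual_masked


def cell_rmse(truth: np.ndarray, fitted: np.ndarray, pattern: np.ndarray) -> float:
    """RMSE over the deleted cells only (debug-level, not the total-score metric)."""
    return float(np.sqrt(np.mean((fitted[pattern] - truth[pattern]) ** 2)))


class TestMeanSubstitution:
    def test_column_mean_fills_missing(self):
        items = np.array([[1, 2], [2, 2], [3, 2], [4, 2]])
        pattern = np.zeros((4, 2), dtype=bool)
        pattern[3, 0] = True  # observed column values {1, 2, 3}
        fitted = sf.impute_mean(manual_masked(items, pattern))
        assert fitted.completions[0][3, 0] == pytest.approx(2.0)

    def test_two_cells_one_column_get_identical_value(self, small_masked):
        fitted = sf.impute_mean(small_masked).completions[0]
        x = small_masked.observed_items()
        for j in range(x.shape[1]):
            miss = small_masked.mask.pattern[:, j]
            if miss.sum() >= 2:
                vals = fitted[miss, j]
                assert np.all(vals == vals[0])
                assert vals[0] == pytest.approx(np.nanmean(x[:, j]))

    def test_zero_deletions_is_identity(self, small_cohort):
        masked = sf.MaskedDataset(
            base=small_cohort,
            mask=sf.Mask(pattern=np.zeros_like(small_cohort.items, dtype=bool)),
        )
        fitted = sf.impute_mean(masked)
        assert np.array_equal(fitted.completions[0], small_cohort.items)

    def test_fully_missing_column_names_it(self):
        items = np.ones((5, 3), dtype=int)
        pattern = np.zeros((5, 3), dtype=bool)
        pattern[:, 1] = True
        with pytest.raises(UnimputableColumnError, match="item_2"):
            sf.impute_mean(manual_masked(items, pattern))


@pytest.mark.parametrize("method", ["MS", "PMM", "RFR"])
class TestSharedContracts:
    def test_observed_cells_preserved_and_complete(self, method, small_masked):
        cfg = sf.ImputerConfig(method=method, pmm_m=3, seed=11)
        fitted = sf.impute(small_masked, cfg)
        obs = small_masked.observed_items()
        keep = ~small_masked.mask.pattern
        for comp in fitted.completions:
            assert not np.isnan(comp).any()
            assert np.array_equal(comp[keep], obs[keep])
            assert comp.min() >= 1.0 and comp.max() <= 4.0

    def test_deterministic_under_fixed_seed(self, method, small_masked):
        cfg = sf.ImputerConfig(method=method, pmm_m=2, seed=5)
        a = sf.impute(small_masked, cfg)
        b = sf.impute(small_masked, cfg)
        for ca, cb in zip(a.completions, b.completions):
            assert np.array_equal(ca, cb)


class TestPmm:
    def test_donor_property_integer_levels(self, small_masked):
        fitted = sf.impute_pmm(small_masked, sf.ImputerConfig(method="PMM", pmm_m=4, seed=2))
        x = small_masked.observed_items()
        for comp in fitted.completions:
            for j in range(x.shape[1]):
                miss = small_masked.mask.pattern[:, j]
                observed_vals = set(x[~np.isnan(x[:, j]), j])
                assert set(comp[miss, j]).issubset(observed_vals)
            assert np.all(comp == np.round(comp))

    def test_zero_deletions_gives_m_identical_copies(self, small_cohort):
        masked = sf.MaskedDataset(
            base=small_cohort,
            mask=sf.Mask(pattern=np.zeros_like(small_cohort.items, dtype=bool)),
        )
        fitted = sf.impute_pmm(masked, sf.ImputerConfig(method="PMM", pmm_m=3, seed=0))
        assert fitted.m == 3
        for comp in fitted.completions:
            assert np.array_equal(comp, small_cohort.items)

    def test_singular_design_falls_back_to_ridge(self):
        # a constant column makes the design collinear with the intercept
        rng = np.random.default_rng(0)
        items = rng.integers(1, 5, size=(30, 4))
        items[:, 2] = 2
        pattern = np.zeros((30, 4), dtype=bool)
        pattern[rng.choice(30, 6, replace=False), 0] = True
        fitted = sf.impute_pmm(
            manual_masked(items, pattern), sf.ImputerConfig(method="PMM", pmm_m=2, seed=1)
        )
        assert fitted.diagnostics["ridged_fits"] > 0
        for comp in fitted.completions:
            assert not np.isnan(comp).any()

    def test_small_donor_pool_shrinks_with_diagnostic(self):
        # column 0 has only 3 observed values, fewer than the 5-donor default
        items = np.tile([1, 2, 3, 4], (8, 1))
        pattern = np.zeros((8, 4), dtype=bool)
        pattern[:5, 0] = True
        fitted = sf.impute_pmm(
            manual_masked(items, pattern), sf.ImputerConfig(method="PMM", pmm_m=1, seed=0)
        )
        assert fitted.diagnostics["shrunk_donor_pools"] > 0

    def test_beats_uniform_random_baseline(self, spec):
        """Cell-level RMSE of PMM under 10% MCAR must beat drawing uniform
        random levels, averaged over 5 seeds."""
        pmm_err, unif_err = [], []
        for s in range(5):
            cohort = sf.generate_cohort(spec, 1)
            masked = sf.ampute(cohort, sf.MissingnessSpec("MCAR", 0.10, seed=s))
            truth = cohort.items.astype(float)
            pat = masked.mask.pattern
            fitted = sf.impute_pmm(
                masked, sf.ImputerConfig(method="PMM", pmm_m=5, seed=s)
            )
            pmm_err.append(
                np.mean([cell_rmse(truth, c, pat) for c in fitted.completions])
            )
            rng = np.random.default_rng(s)
            rand = truth.copy()
            rand[pat] = rng.integers(1, 5, size=int(pat.sum()))
            unif_err.append(cell_rmse(truth, rand, pat))
        assert np.mean(pmm_err) < np.mean(unif_err)


class TestRfr:
    def test_zero_deletions_is_identity_zero_iterations(self, small_cohort):
        masked = sf.MaskedDataset(
            base=small_cohort,
            mask=sf.Mask(pattern=np.zeros_like(small_cohort.items, dtype=bool)),
        )
        fitted = sf.impute_rfr(masked, sf.ImputerConfig(seed=0))
        assert fitted.diagnostics["iterations"] == 0
        assert np.array_equal(fitted.completions[0], small_cohort.items)

    def test_single_observed_row_gives_constant_forest(self):
        """Every tree grown on one observed row predicts that row's value."""
        rng = np.random.default_rng(1)
        items = rng.integers(1, 5, size=(12, 4))
        items[0, 0] = 3
        pattern = np.zeros((12, 4), dtype=bool)
        pattern[1:, 0] = True  # column 0: only row 0 observed
        fitted = sf.impute_rfr(
            manual_masked(items, pattern), sf.ImputerConfig(seed=0, rfr_max_iter=2)
        )
        assert np.all(fitted.completions[0][1:, 0] == 3.0)

    def test_delta_trace_finite_and_stops_on_increase(self, small_masked):
        fitted = sf.impute_rfr(small_masked, sf.ImputerConfig(seed=3))
        deltas = fitted.diagnostics["deltas"]
        assert len(deltas) >= 1
        assert np.all(np.isfinite(deltas))
        if len(deltas) < 10:  # stopped before the cap: last step increased
            assert deltas[-1] > deltas[-2]
            assert min(deltas[:-1]) == deltas[-2]

    def test_not_worse_than_mean_substitution(self, spec):
        """Cell-level RMSE of the forest imputer <= mean substitution at
        MCAR 20%, averaged over 10 seeds."""
        rfr_err, ms_err = [], []
        for s in range(10):
            cohort = sf.generate_cohort(spec, s)
            masked = sf.ampute(cohort, sf.MissingnessSpec("MCAR", 0.20, seed=s))
            truth = cohort.items.astype(float)
            pat = masked.mask.pattern
            rfr = sf.impute_rfr(masked, sf.ImputerConfig(seed=s)).completions[0]
            ms = sf.impute_mean(masked).completions[0]
            rfr_err.append(cell_rmse(truth, rfr, pat))
            ms_err.append(cell_rmse(truth, ms, pat))
        assert np.mean(rfr_err) <= np.mean(ms_err)
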