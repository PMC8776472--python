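import numpy as np
import pytest

import scalefit as sf


@pytest.fixture(scope="session")
def spec():
    return sf.default_spec()


@pytest.fixture(scope="session")
def cohort(spec):
    """The reference 507-subject cohort used by cross-module tests."""
    return sf.generate_cohort(spec, 1)


def make_small_spec(n_items: int = 8, n_male: int = 40, n_female: int = 20) -> sf.CohortSpec:
    """A scaled-down cohort spec for fast imputer/grid mechanics tests."""
    base = sf.CohortSpec(
        n_total=n_male + n_female,
        n_male=n_male,
        n_female=n_female,
        n_items=n_items,
        item_loadings=np.ones(n_items),
        item_thresholds=np.tile(
            sf.latent_cutpoints((0.15, 0.50, 0.85), n_male=n_male, n_female=n_female),
            (n_items, 1),
        ),
    )
    base.validate()
    return base


@pytest.fixture(scope="session")
def small_spec():
    return make_small_spec()


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return sf.generate_cohort(small_spec, 3)


@pytest.fixture()
def small_masked(small_cohort):
    return sf.ampute(
        small_cohort, sf.MissingnessSpec("MCAR", overall_rate=0.15, seed=9)
    )


def manual_masked(items: np.ndarray, pattern: np.ndarray) -> sf.MaskedDataset:
    """Wrap a hand-built item matrix and deletion pattern as a MaskedDataset."""
    n = items.shape[0]
    base = sf.ScaleDataset(
        subject_id=np.arange(1, n + 1),
        sex=np.array(["M"] * n),
        age=np.full(n, 60.0),
        items=np.asarray(items, dtype=np.int64),
    )
    return sf.MaskedDataset(base=base, mask=sf.Mask(pattern=np.asarray(pattern, bool)))
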