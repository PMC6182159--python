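import numpy as np
import pytest

import sirnafit as sf


@pytest.fixture
def toy_dataset():
    """Two length-3 oligos with hand-checkable positional means."""
    return sf.ScreenDataset(
        [
            sf.SiRNARecord("a", "ACG", 1.0),
            sf.SiRNARecord("b", "AAA", 3.0),
        ]
    )


@pytest.fixture
def random_dataset():
    """300 random 19-mers with standard-normal phenotypes."""
    rng = np.random.default_rng(42)
    nts = np.array(list("ACGT"))
    recs = [
        sf.SiRNARecord(
            f"o{i}", "".join(nts[rng.integers(0, 4, 19)]), float(rng.standard_normal())
        )
        for i in range(300)
    ]
    return sf.ScreenDataset(recs)


@pytest.fixture(scope="session")
def small_screen():
    """One modest synthetic screen (n=6000) with ground truth, shared across tests."""
    cfg = sf.ScreenSimConfig(n_oligos=6000, rng_seed=3)
    return sf.generate_screen(cfg)


@pytest.fixture(scope="session")
def fitted_linear_model(small_screen):
    screen, _ = small_screen
    train, _ = sf.split_dataset(screen, 0.9, rng_seed=0)
    return sf.fit_positional_model(train)


def make_uniform_screen(n, noise_sd=1.0, positional_weight_sd=0.1, rng_seed=0, **kw):
    """Screen with uniform background and positional effects only."""
    cfg = sf.ScreenSimConfig(
        n_oligos=n,
        background="uniform",
        positional_weight_sd=positional_weight_sd,
        seed_effect_sd=0.0,
        gene_effect_sd=0.0,
        noise_sd=noise_sd,
        rng_seed=rng_seed,
        **kw,
    )
    return sf.generate_screen(cfg)
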