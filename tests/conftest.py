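import numpy as np
import pytest

from strudel.synthetic import SignalSpec, generate_labeled_dataset

#: Three planted informative features (one sequence, two structure) used
#: across classifier tests; effect size in noise-sd units.
PLANTED = {"pssm_diff": 2.0, "ddg_fa_rep": 2.0, "relax_fa_rep_mean_shift": 2.0}


@pytest.fixture(scope="session")
def planted_dataset():
    """200 proteins x 5 variants with signal in 3 of the 106 features."""
    spec = SignalSpec(n_proteins=200, variants_per_protein=(5, 5),
                      informative_features=PLANTED, seed=7)
    return generate_labeled_dataset(spec)


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale dataset for fast classifier/evaluation unit tests."""
    spec = SignalSpec(n_proteins=40, variants_per_protein=(4, 6),
                      informative_features=PLANTED, seed=11)
    return generate_labeled_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
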