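"""Shared fixtures: expensive simulated fits are session-scoped."""

import numpy as np
import pytest

from raschpcm import PartialCreditModel, pss_like_preset, simulate_pcm
from raschpcm.synthetic_data import DIFSpec, inject_dif


@pytest.fixture(scope="session")
def uni_fit():
    """Unidimensional (rho=1) PSS-like sample, n=2000, fitted by CML."""
    spec = pss_like_preset(n_persons=2000, rho=1.0, seed=3)
    rm, truth = simulate_pcm(spec)
    res = PartialCreditModel(rm).fit(compute_se=False)
    return rm, truth, res


@pytest.fixture(scope="session")
def uni_persons(uni_fit):
    _, _, res = uni_fit
    return res.person_estimates()


@pytest.fixture(scope="session")
def bi_fit():
    """Two-trait (rho=0.3) PSS-like sample, n=2000, fitted by CML."""
    spec = pss_like_preset(n_persons=2000, rho=0.3, seed=4)
    rm, truth = simulate_pcm(spec)
    res = PartialCreditModel(rm).fit(compute_se=False)
    return rm, truth, res


@pytest.fixture(scope="session")
def dif_fit():
    """Sample with a +0.6 logit shift injected on item q7 for persons > 31."""
    spec = inject_dif(
        pss_like_preset(n_persons=2000, rho=1.0, seed=5),
        DIFSpec(item="q7", shift=0.6, group="age", covariate_cut=31),
    )
    rm, truth = simulate_pcm(spec)
    return rm, truth


def centered_true_thresholds(truth, item_ids):
    """Generating thresholds re-anchored to the sum-zero location metric."""
    shift = np.mean([truth["thresholds"][i].mean() for i in item_ids])
    return [truth["thresholds"][i] - shift for i in item_ids]
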