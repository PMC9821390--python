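import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from histest.anova import AnovaParams, DesignXi
from histest.pooling import HistoricalStudy, build_historical_set


@pytest.fixture
def anova_params():
    return AnovaParams(eta0=1.0, eta1=0.5, eta2=0.5, theta=0.25, sigma2=1.0)


@pytest.fixture
def balanced_design():
    return DesignXi.balanced()


@pytest.fixture
def balanced_hist():
    """Historical set whose sqrt(m)-scale covariance is the balanced matrix."""

    def make(m=100, eta_hat=(1.0, 0.5, 0.5), sigma2=1.0):
        from histest.anova import sigma_balanced

        Sigma = sigma_balanced(sigma2)
        study = HistoricalStudy(label="pooled", eta_hat=np.asarray(eta_hat),
                                cov=Sigma / m, m=m)
        return build_historical_set([study])

    return make


def random_pd(rng, d, scale=1.0):
    """Random positive-definite matrix with a controlled condition number."""
    G = rng.normal(size=(d, d))
    return scale * (G @ G.T + d * np.eye(d))
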