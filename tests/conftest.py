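import numpy as np
import pytest

from gedi import (
    CellEmbeddings,
    GediModel,
    ObservationSet,
    ReferenceManifold,
    SampleTransformSet,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_model(
    rng,
    G=12,
    K=3,
    N=20,
    Q=2,
    with_prior=False,
    with_covariates=False,
    P=4,
    L=2,
    mode="gaussian",
):
    """Random but dimensionally consistent model for unit tests."""
    from gedi import CovariateBlock, GenePriorBlock

    manifold = ReferenceManifold(
        o_r=rng.normal(size=G), Z_r=rng.normal(size=(G, K)), orthogonal_axes=False
    )
    transforms = SampleTransformSet(
        delta_o=rng.normal(size=(G, Q)) * 0.2,
        delta_Z=rng.normal(size=(Q, G, K)) * 0.1,
    )
    B = rng.normal(size=(K, N))
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    embeddings = CellEmbeddings(B=B, s=rng.normal(size=N) * 0.1)
    prior = None
    if with_prior:
        prior = GenePriorBlock(
            C=rng.normal(size=(G, P)), A=rng.normal(size=(P, K)), S_Z=2.0, S_A=3.0
        )
    covariates = None
    if with_covariates:
        covariates = CovariateBlock(
            H=rng.normal(size=(L, Q)),
            R_o=rng.normal(size=(G, L)) * 0.3,
            R=rng.normal(size=(K, G, L)) * 0.3,
        )
    return GediModel(
        manifold=manifold,
        transforms=transforms,
        embeddings=embeddings,
        sigma2=0.5,
        sample_map=np.arange(N) % Q,
        observation_mode=mode,
        prior=prior,
        covariates=covariates,
    )


@pytest.fixture
def small_model(rng):
    return make_model(rng)


def gaussian_observations(rng, G=40, N=120, K=3, Q=3, noise=0.3):
    Z = rng.normal(size=(G, K))
    B = rng.normal(size=(K, N))
    smap = np.arange(N) % Q
    Y = Z @ B + noise * rng.normal(size=(G, N))
    return ObservationSet("gaussian", smap, Y=Y)


def quad_oracle(logpost, lo=-25.0, hi=25.0, n=4000):
    """Trapezoid-quadrature posterior moments on a fixed wide grid."""
    y = np.linspace(lo, hi, n)
    lp = logpost(y)
    w = np.exp(lp - lp.max())
    norm = np.trapezoid(w, y)
    ey = np.trapezoid(w * y, y) / norm
    vy = np.trapezoid(w * (y - ey) ** 2, y) / norm
    return ey, vy
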