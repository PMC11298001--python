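"""MAP fitting by block coordinate descent (gaussian) or EM (count modes).

Every parameter block has a closed-form ridge / least-squares update given
the others, because all priors are Gaussian with variances proportional to
the model variance ``sigma2``.  In the count modes the per-entry posterior
moments ``(Ey, Vy)`` of the latent profile replace the data in those
updates, with ``sum(Vy)`` entering the ``sigma2`` update.

Sweep order: E-step, B, s, delta_o, delta_Z, o_r, Z_r, A, R_o, R_k,
sigma2, then constraints (axis orthogonalization via an exact change of
basis, gauge renormalization, optional ellipsoid projection).  Cell-level
blocks come first so that sample-level blocks see stabilized residuals.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .model import (
    CellEmbeddings,
    CovariateBlock,
    DimensionError,
    GediError,
    GediModel,
    GenePriorBlock,
    ReferenceManifold,
    SampleTransformSet,
    decode_all,
    project_ellipsoid,
    renormalize_gauge,
)
from .observations import (
    LatentPosterior,
    ObservationSet,
    compute_posterior,
    loglik_observed,
)

__all__ = ["FitConfig", "FitTrace", "initialize", "update_block", "objective", "fit"]

_BLOCKS = ("B", "s", "delta_o", "delta_Z", "o_r", "Z_r", "A", "R_o", "R_k", "sigma2")


@dataclass
class FitConfig:
    """Settings for one fit."""

    K: int
    mode: str = "gaussian"
    max_sweeps: int = 200
    tol: float = 1e-6
    seed: int = 0
    orthogonalize: bool = True
    ellipsoid: bool = False
    # Applying the gauge/orthogonality projection inside every sweep fights
    # the axis priors (the projection is not a conditional maximizer) and
    # produces a slowly decreasing objective; by default the constraints are
    # therefore imposed exactly once at finalization, which leaves every
    # decoded mean unchanged.  Set True to project after the cell-level
    # updates of every sweep instead.
    project_every_sweep: bool = False
    # Prior-variance ratios.  Defaults (None) are resolved at fit time to
    # match the scale the gauge constraint imposes: with unit-norm B rows,
    # axis-column entries grow like sqrt(N), so S_Z = S_A = N,
    # S_delta_Z = S_Rk = N/Q, while center-level blocks stay O(1):
    # S_delta_o = S_Ro = 1.
    S_Z: Optional[float] = None
    S_A: Optional[float] = None
    S_delta_o: Optional[float] = None
    S_delta_Z: Optional[float] = None
    S_Ro: float = 1.0
    S_Rk: Optional[float] = None
    update_s: bool = True
    e_step_points: int = 65  # mode-centred quadrature nodes per E-step entry
    fixed_embeddings: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.K < 1:
            raise GediError("K must be >= 1")
        if not self.tol > 0:
            raise GediError("tol must be > 0")
        for name in ("S_Z", "S_A", "S_delta_o", "S_delta_Z", "S_Ro", "S_Rk"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise GediError(f"hyperparameter {name} must be > 0")
        if self.mode not in ("gaussian", "poisson", "binomial"):
            raise GediError(f"unknown mode {self.mode!r}")


@dataclass
class FitTrace:
    """Per-sweep objective values, block update norms and wall-clock times."""

    objective: List[float] = field(default_factory=list)
    block_norms: List[dict] = field(default_factory=list)
    seconds: List[float] = field(default_factory=list)

    @property
    def n_sweeps(self) -> int:
        return len(self.objective)

    def to_rows(self) -> List[dict]:
        rows = []
        for i, (obj, norms, sec) in enumerate(
            zip(self.objective, self.block_norms, self.seconds)
        ):
            row = {"sweep": i + 1, "objective": obj, "seconds": sec}
            row.update(norms)
            rows.append(row)
        return rows


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _solve_spd(M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve ``M x = rhs`` for symmetric positive definite ``M``.

    Falls back to a ridge-stabilized solve (with a warning) if the
    factorization fails.
    """
    try:
        return cho_solve(cho_factor(M), rhs)
    except LinAlgError:
        warnings.warn("singular normal equations; applying ridge stabilization")
        eps = 1e-8 * max(np.trace(M) / M.shape[0], 1.0)
        return cho_solve(cho_factor(M + eps * np.eye(M.shape[0])), rhs)


def _sample_indices(sample_map: np.ndarray, Q: int) -> List[np.ndarray]:
    return [np.flatnonzero(sample_map == i) for i in range(Q)]


def _hyper(model: GediModel) -> dict:
    """Collect the active prior-variance ratios from the model blocks."""
    h = {"S_Z": model.S_Z, "S_delta_o": model.S_delta_o, "S_delta_Z": model.S_delta_Z}
    if model.prior is not None:
        h["S_Z"] = model.prior.S_Z
        h["S_A"] = model.prior.S_A
    if model.covariates is not None:
        h["S_delta_o"] = model.covariates.S_delta_o
        h["S_delta_Z"] = model.covariates.S_delta_Z
        h["S_Ro"] = model.covariates.S_Ro
        h["S_Rk"] = model.covariates.S_Rk
    return h


def _delta_o_prior_mean(model: GediModel) -> np.ndarray:
    if model.covariates is None:
        return np.zeros_like(model.transforms.delta_o)
    return model.covariates.R_o @ model.covariates.H


def _delta_Z_prior_mean(model: GediModel) -> np.ndarray:
    """(Q, G, K) prior means of the axis distortions."""
    if model.covariates is None:
        return np.zeros_like(model.transforms.delta_Z)
    # R is (K, G, L), H is (L, Q) -> (Q, G, K)
    return np.einsum("kgl,lq->qgk", model.covariates.R, model.covariates.H)


def prior_quadratic(model: GediModel) -> Tuple[float, int]:
    """Sum of prior quadratic forms (each divided by its S) and their df."""
    h = _hyper(model)
    G, K, Q = model.G, model.K, model.Q
    CA = (
        model.prior.C @ model.prior.A
        if model.prior is not None
        else np.zeros_like(model.manifold.Z_r)
    )
    quad = float(np.sum((model.manifold.Z_r - CA) ** 2)) / h["S_Z"]
    df = G * K
    quad += float(np.sum((model.transforms.delta_o - _delta_o_prior_mean(model)) ** 2)) / h[
        "S_delta_o"
    ]
    df += G * Q
    quad += float(
        np.sum((model.transforms.delta_Z - _delta_Z_prior_mean(model)) ** 2)
    ) / h["S_delta_Z"]
    df += G * K * Q
    if model.prior is not None:
        quad += float(np.sum(model.prior.A**2)) / h["S_A"]
        df += model.prior.P * K
    if model.covariates is not None:
        L = model.covariates.L
        quad += float(np.sum(model.covariates.R_o**2)) / h["S_Ro"]
        quad += float(np.sum(model.covariates.R**2)) / h["S_Rk"]
        df += G * L + K * G * L
    return quad, df


def objective(
    model: GediModel,
    observations: ObservationSet,
    posterior: Optional[LatentPosterior] = None,
) -> float:
    """Penalized log-posterior (data layer + priors), up to additive constants."""
    ll = loglik_observed(model, observations, posterior)
    quad, df = prior_quadratic(model)
    return ll - quad / (2.0 * model.sigma2) - 0.5 * df * np.log(model.sigma2)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _naive_latent(observations: ObservationSet) -> Tuple[np.ndarray, np.ndarray]:
    """Mode-appropriate rough transform of the data plus initial intercepts."""
    if observations.mode == "gaussian":
        return observations.Y.copy(), np.zeros(observations.Y.shape[1])
    if observations.mode == "poisson":
        M = observations.M
        depth = M.sum(axis=0)
        depth = np.maximum(depth, 1.0)
        ref = np.median(depth)
        X = np.log1p(M / depth[None, :] * ref)
        s = np.log(depth) - np.log(ref)
        return X, s
    M1, M2 = observations.M1, observations.M2
    p = (M1 + 0.5) / (M1 + M2 + 1.0)
    return np.log(p / (1.0 - p)), np.zeros(M1.shape[1])


def initialize(
    observations: ObservationSet,
    config: FitConfig,
    prior: Optional[GenePriorBlock] = None,
    covariates: Optional[CovariateBlock] = None,
) -> GediModel:
    """Deterministic starting point from a truncated SVD of transformed data.

    The transform is the identity (gaussian), ``log1p`` of depth-normalized
    counts (poisson), or a smoothed empirical logit (binomial).  Embeddings
    are the top-K right singular vectors (unit rows, so the gauge constraint
    holds at the start), axes carry the singular values, sample transforms
    start at zero, and ``sigma2`` is the initial mean squared residual.
    """
    G, N = observations.shape
    K = config.K
    if K > min(G, N):
        raise GediError(f"K={K} exceeds min(G, N) = {min(G, N)}")
    if observations.mode != config.mode:
        raise GediError("config.mode does not match observations.mode")
    Q = observations.n_samples
    X, s = _naive_latent(observations)
    if not np.all(np.isfinite(X)):
        raise GediError("non-finite values in the observation matrix")
    o_r = X.mean(axis=1)
    Xc = X - o_r[:, None]
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each axis positive
    for k in range(K):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k, :] = -Vt[k, :]
    if config.fixed_embeddings is not None:
        B = np.asarray(config.fixed_embeddings, dtype=float).copy()
        if B.shape != (K, N):
            raise DimensionError(
                f"fixed_embeddings has shape {B.shape}, expected ({K}, {N})"
            )
    else:
        B = Vt[:K].copy()
    Z_r = U[:, :K] * sv[:K][None, :]
    resid = Xc - Z_r @ Vt[:K]
    sigma2 = max(float(np.mean(resid**2)), 1e-8)

    S_Z = config.S_Z if config.S_Z is not None else float(N)
    S_A = config.S_A if config.S_A is not None else float(N)
    S_do = config.S_delta_o if config.S_delta_o is not None else 1.0
    S_dZ = config.S_delta_Z if config.S_delta_Z is not None else float(N) / Q
    S_Rk = config.S_Rk if config.S_Rk is not None else float(N) / Q
    if prior is not None:
        prior = GenePriorBlock(
            C=prior.C,
            A=np.zeros((prior.P, K)),
            S_Z=S_Z,
            S_A=S_A,
            set_names=prior.set_names,
        )
    if covariates is not None:
        L = covariates.H.shape[0]
        covariates = CovariateBlock(
            H=covariates.H,
            R_o=np.zeros((G, L)),
            R=np.zeros((K, G, L)),
            S_delta_o=S_do,
            S_delta_Z=S_dZ,
            S_Ro=config.S_Ro,
            S_Rk=S_Rk,
            covariate_names=covariates.covariate_names,
        )

    model = GediModel(
        manifold=ReferenceManifold(o_r, Z_r, orthogonal_axes=config.orthogonalize),
        transforms=SampleTransformSet(np.zeros((G, Q)), np.zeros((Q, G, K))),
        embeddings=CellEmbeddings(B, s),
        sigma2=sigma2,
        sample_map=np.asarray(observations.sample_map),
        observation_mode=config.mode,
        prior=prior,
        covariates=covariates,
        gene_ids=observations.gene_ids,
        cell_ids=observations.cell_ids,
        sample_ids=observations.sample_ids,
        S_Z=S_Z,
        S_delta_o=S_do,
        S_delta_Z=S_dZ,
    )
    if prior is not None:
        _update_A(model)
    return model


# ---------------------------------------------------------------------------
# block updates (each is the exact minimizer given the other blocks)
# ---------------------------------------------------------------------------

def _factor_penalties(model: GediModel) -> np.ndarray:
    """Per-factor prior quadratic ``V_k`` of all axis-scaled blocks.

    The gauge rescaling (B row k by 1/c, matching columns by c) leaves the
    likelihood invariant but scales the axis-side prior quadratics of factor
    k by c^2 = ||B_k||^2.  Evaluating the priors at the gauge-canonical
    representative therefore turns them into the row-wise ridge
    ``sum_k V_k ||B_k||^2`` on the embeddings, which makes the MAP problem
    well posed (otherwise the optimizer drifts forever along the gauge).
    """
    h = _hyper(model)
    CA = (
        model.prior.C @ model.prior.A
        if model.prior is not None
        else np.zeros_like(model.manifold.Z_r)
    )
    V = np.sum((model.manifold.Z_r - CA) ** 2, axis=0) / h["S_Z"]
    V += (
        np.sum((model.transforms.delta_Z - _delta_Z_prior_mean(model)) ** 2, axis=(0, 1))
        / h["S_delta_Z"]
    )
    if model.prior is not None:
        V += np.sum(model.prior.A**2, axis=0) / h["S_A"]
    if model.covariates is not None:
        V += np.sum(model.covariates.R**2, axis=(1, 2)) / h["S_Rk"]
    return V


def _update_B(
    model: GediModel,
    Ey: np.ndarray,
    idx: Sequence[np.ndarray],
    with_s: bool = False,
) -> None:
    """Embedding update; with ``with_s`` the per-cell intercept is solved
    jointly (augmented design ``[Z, 1_G]``), which avoids the slow
    alternation between the intercept and any constant-gene component of
    the axes."""
    K = model.K
    V = np.zeros((K + 1, K + 1))
    V[:K, :K] = np.diag(_factor_penalties(model))
    ones = np.ones((model.G, 1))
    for i, cells in enumerate(idx):
        if cells.size == 0:
            continue
        Z = model.manifold.Z_r + model.transforms.delta_Z[i]
        rhs = (
            Ey[:, cells]
            - (model.manifold.o_r + model.transforms.delta_o[:, i])[:, None]
        )
        if with_s:
            D = np.hstack([Z, ones])
            sol = _solve_spd(D.T @ D + V, D.T @ rhs)
            model.embeddings.B[:, cells] = sol[:K]
            model.embeddings.s[cells] = sol[K]
        else:
            rhs = rhs - model.embeddings.s[cells][None, :]
            model.embeddings.B[:, cells] = _solve_spd(
                Z.T @ Z + V[:K, :K], Z.T @ rhs
            )


def _update_s(model: GediModel, Ey: np.ndarray, idx: Sequence[np.ndarray]) -> None:
    for i, cells in enumerate(idx):
        if cells.size == 0:
            continue
        Z = model.manifold.Z_r + model.transforms.delta_Z[i]
        r = (
            Ey[:, cells]
            - (model.manifold.o_r + model.transforms.delta_o[:, i])[:, None]
            - Z @ model.embeddings.B[:, cells]
        )
        model.embeddings.s[cells] = r.mean(axis=0)


def _update_delta_o(model: GediModel, Ey: np.ndarray, idx: Sequence[np.ndarray]) -> None:
    S = _hyper(model)["S_delta_o"]
    pm = _delta_o_prior_mean(model)
    for i, cells in enumerate(idx):
        if cells.size == 0:
            model.transforms.delta_o[:, i] = pm[:, i]
            continue
        Z = model.manifold.Z_r + model.transforms.delta_Z[i]
        r = (
            Ey[:, cells]
            - model.manifold.o_r[:, None]
            - Z @ model.embeddings.B[:, cells]
            - model.embeddings.s[cells][None, :]
        )
        model.transforms.delta_o[:, i] = (r.sum(axis=1) + pm[:, i] / S) / (
            cells.size + 1.0 / S
        )


def _update_delta_Z(model: GediModel, Ey: np.ndarray, idx: Sequence[np.ndarray]) -> None:
    S = _hyper(model)["S_delta_Z"]
    pm = _delta_Z_prior_mean(model)
    K = model.K
    for i, cells in enumerate(idx):
        if cells.size == 0:
            model.transforms.delta_Z[i] = pm[i]
            continue
        Bi = model.embeddings.B[:, cells]
        r = (
            Ey[:, cells]
            - (model.manifold.o_r + model.transforms.delta_o[:, i])[:, None]
            - model.manifold.Z_r @ Bi
            - model.embeddings.s[cells][None, :]
        )
        M = Bi @ Bi.T + np.eye(K) / S
        model.transforms.delta_Z[i] = _solve_spd(M, Bi @ r.T + pm[i].T / S).T


def _update_gene_side(model: GediModel, Ey: np.ndarray, idx: Sequence[np.ndarray]) -> None:
    """Joint exact update of ``o_r``, ``delta_o``, ``Z_r`` and ``delta_Z``.

    Given the embeddings, every gene solves the same ridge regression with
    features ``[1, b_n]`` (reference blocks) plus their per-sample copies
    (distortion blocks); the normal matrix is shared across genes, so one
    Cholesky factorization serves all G right-hand sides.  Updating these
    four blocks jointly avoids the near-collinear alternation between the
    reference manifold and the per-sample distortions, which otherwise
    converges at a glacial rate.
    """
    h = _hyper(model)
    G, K, Q = model.G, model.K, model.Q
    K1 = K + 1
    D = K1 * (Q + 1)
    M = np.zeros((D, D))
    rhs = np.zeros((D, G))
    Ey_s = Ey - model.embeddings.s[None, :]
    for i, cells in enumerate(idx):
        gmat = np.vstack(
            [np.ones(cells.size), model.embeddings.B[:, cells]]
        )  # (K1, N_i)
        A_ii = gmat @ gmat.T
        r_i = gmat @ Ey_s[:, cells].T  # (K1, G)
        blk = slice(K1 * (i + 1), K1 * (i + 2))
        M[:K1, :K1] += A_ii
        M[:K1, blk] = A_ii
        M[blk, :K1] = A_ii
        M[blk, blk] = A_ii
        rhs[:K1] += r_i
        rhs[blk] = r_i
    pen = np.zeros(D)
    pen[1:K1] = 1.0 / h["S_Z"]
    CA = (
        model.prior.C @ model.prior.A
        if model.prior is not None
        else np.zeros((G, K))
    )
    rhs[1:K1] += CA.T / h["S_Z"]
    pm_o = _delta_o_prior_mean(model)
    pm_Z = _delta_Z_prior_mean(model)
    for i in range(Q):
        blk = slice(K1 * (i + 1), K1 * (i + 2))
        pen[blk.start] = 1.0 / h["S_delta_o"]
        pen[blk.start + 1 : blk.stop] = 1.0 / h["S_delta_Z"]
        rhs[blk.start] += pm_o[:, i] / h["S_delta_o"]
        rhs[blk.start + 1 : blk.stop] += pm_Z[i].T / h["S_delta_Z"]
    M[np.diag_indices(D)] += pen
    coef = _solve_spd(M, rhs)  # (D, G)
    model.manifold.o_r = coef[0]
    model.manifold.Z_r = coef[1:K1].T
    for i in range(Q):
        blk = slice(K1 * (i + 1), K1 * (i + 2))
        model.transforms.delta_o[:, i] = coef[blk.start]
        model.transforms.delta_Z[i] = coef[blk.start + 1 : blk.stop].T


def _recenter_intercepts(model: GediModel, idx: Sequence[np.ndarray]) -> None:
    """Move constant-gene components of the axes into the cell intercepts.

    The decoder is invariant under ``Z <- Z - 1_G u^T`` with
    ``s_n <- s_n + u . b_n`` (and the per-sample analogues for ``delta_Z_i``
    and ``delta_o_i``).  The intercepts are unpenalized while the axis
    blocks are not, so the shift that minimizes the prior quadratics is an
    exact ascent step; without it the optimizer creeps along this flat
    direction for hundreds of sweeps.
    """
    CA = (
        model.prior.C @ model.prior.A
        if model.prior is not None
        else np.zeros_like(model.manifold.Z_r)
    )
    u = (model.manifold.Z_r - CA).mean(axis=0)
    model.manifold.Z_r -= u[None, :]
    model.embeddings.s += model.embeddings.B.T @ u
    pm_Z = _delta_Z_prior_mean(model)
    pm_o = _delta_o_prior_mean(model)
    for i, cells in enumerate(idx):
        ui = (model.transforms.delta_Z[i] - pm_Z[i]).mean(axis=0)
        model.transforms.delta_Z[i] -= ui[None, :]
        ai = (model.transforms.delta_o[:, i] - pm_o[:, i]).mean()
        model.transforms.delta_o[:, i] -= ai
        if cells.size:
            model.embeddings.s[cells] += model.embeddings.B[:, cells].T @ ui + ai


def _recenter_embeddings(model: GediModel, idx: Sequence[np.ndarray]) -> None:
    """Move per-sample embedding means into the sample center translations.

    ``b_n <- b_n - t_i`` with ``delta_o_i <- delta_o_i + Z_i t_i`` leaves the
    decoder unchanged; ``t_i`` is chosen to minimize the prior quadratics
    (the ``delta_o`` prior plus the gauge-invariant embedding ridge).  This
    resolves the degeneracy in which the embeddings soak up sample-level
    offsets that belong to the center translations.
    """
    h = _hyper(model)
    V = _factor_penalties(model)
    pm_o = _delta_o_prior_mean(model)
    for i, cells in enumerate(idx):
        if cells.size == 0:
            continue
        Z = model.manifold.Z_r + model.transforms.delta_Z[i]
        M = Z.T @ Z / h["S_delta_o"] + cells.size * np.diag(V)
        rhs = (
            -Z.T @ (model.transforms.delta_o[:, i] - pm_o[:, i]) / h["S_delta_o"]
            + V * model.embeddings.B[:, cells].sum(axis=1)
        )
        t = _solve_spd(M, rhs)
        model.embeddings.B[:, cells] -= t[:, None]
        model.transforms.delta_o[:, i] += Z @ t


def _update_o_r(model: GediModel, Ey: np.ndarray, idx: Sequence[np.ndarray]) -> None:
    total = np.zeros(model.G)
    for i, cells in enumerate(idx):
        if cells.size == 0:
            continue
        Z = model.manifold.Z_r + model.transforms.delta_Z[i]
        r = (
            Ey[:, cells]
            - model.transforms.delta_o[:, i][:, None]
            - Z @ model.embeddings.B[:, cells]
            - model.embeddings.s[cells][None, :]
        )
        total += r.sum(axis=1)
    model.manifold.o_r = total / model.N


def _update_Z_r(model: GediModel, Ey: np.ndarray, idx: Sequence[np.ndarray]) -> None:
    h = _hyper(model)
    K = model.K
    S1 = np.zeros((model.G, K))
    S2 = np.zeros((K, K))
    for i, cells in enumerate(idx):
        if cells.size == 0:
            continue
        Bi = model.embeddings.B[:, cells]
        r = (
            Ey[:, cells]
            - (model.manifold.o_r + model.transforms.delta_o[:, i])[:, None]
            - model.transforms.delta_Z[i] @ Bi
            - model.embeddings.s[cells][None, :]
        )
        S1 += r @ Bi.T
        S2 += Bi @ Bi.T
    CA = (
        model.prior.C @ model.prior.A
        if model.prior is not None
        else np.zeros((model.G, K))
    )
    M = S2 + np.eye(K) / h["S_Z"]
    model.manifold.Z_r = _solve_spd(M, (S1 + CA / h["S_Z"]).T).T


def _update_A(model: GediModel) -> None:
    pr = model.prior
    M = pr.C.T @ pr.C + (pr.S_Z / pr.S_A) * np.eye(pr.P)
    pr.A = _solve_spd(M, pr.C.T @ model.manifold.Z_r)


def _update_R_o(model: GediModel) -> None:
    cov = model.covariates
    M = cov.H @ cov.H.T + (cov.S_delta_o / cov.S_Ro) * np.eye(cov.L)
    cov.R_o = _solve_spd(M, cov.H @ model.transforms.delta_o.T).T


def _update_R_k(model: GediModel) -> None:
    cov = model.covariates
    M = cov.H @ cov.H.T + (cov.S_delta_Z / cov.S_Rk) * np.eye(cov.L)
    for k in range(model.K):
        Dz = model.transforms.delta_Z[:, :, k].T  # (G, Q)
        cov.R[k] = _solve_spd(M, cov.H @ Dz.T).T


def _update_sigma2(model: GediModel, Ey: np.ndarray, Vy: Optional[np.ndarray]) -> None:
    mu = decode_all(model)
    quad = float(np.sum((Ey - mu) ** 2))
    df = Ey.size
    if Vy is not None:
        quad += float(np.sum(Vy))
    pq, pdf = prior_quadratic(model)
    model.sigma2 = max((quad + pq) / (df + pdf), 1e-12)


def update_block(
    model: GediModel,
    observations: ObservationSet,
    block_name: str,
    posterior: Optional[LatentPosterior] = None,
) -> GediModel:
    """Refresh one parameter block, holding all others fixed.

    In the count modes, ``posterior`` (the current E-step result) is used as
    the working data; it is computed on the fly when omitted.
    """
    if block_name not in _BLOCKS:
        raise GediError(f"unknown block {block_name!r}; expected one of {_BLOCKS}")
    out = model.copy()
    if observations.mode == "gaussian":
        Ey, Vy = observations.Y, None
    else:
        if posterior is None:
            posterior = compute_posterior(out, observations)
        Ey, Vy = posterior.Ey, posterior.Vy
    idx = _sample_indices(out.sample_map, out.Q)
    if block_name == "B":
        _update_B(out, Ey, idx)
    elif block_name == "s":
        _update_s(out, Ey, idx)
    elif block_name == "delta_o":
        _update_delta_o(out, Ey, idx)
    elif block_name == "delta_Z":
        _update_delta_Z(out, Ey, idx)
    elif block_name == "o_r":
        _update_o_r(out, Ey, idx)
    elif block_name == "Z_r":
        _update_Z_r(out, Ey, idx)
    elif block_name == "A":
        if out.prior is None:
            raise GediError("model has no gene-level prior block")
        _update_A(out)
    elif block_name == "R_o":
        if out.covariates is None:
            raise GediError("model has no covariate block")
        _update_R_o(out)
    elif block_name == "R_k":
        if out.covariates is None:
            raise GediError("model has no covariate block")
        _update_R_k(out)
    else:
        _update_sigma2(out, Ey, Vy)
    return out


# ---------------------------------------------------------------------------
# constraints during fitting
# ---------------------------------------------------------------------------

def _orthogonalize_in_fit(model: GediModel) -> GediModel:
    """Make ``Z_r`` columns orthogonal by an exact change of basis.

    ``Z_r <- Z_r T``, ``delta_Z_i <- delta_Z_i T``, ``B <- T^-1 B`` leaves
    every decoded mean unchanged; the transform ``T`` is chosen so the new
    ``Z_r`` has orthogonal columns with norms redistributed proportionally
    to the originals (total Frobenius norm preserved).
    """
    Z = model.manifold.Z_r
    if Z.shape[1] < 2:
        return model
    U, sv, Vt = np.linalg.svd(Z, full_matrices=False)
    if sv[-1] <= 1e-12 * sv[0]:
        warnings.warn("Z_r nearly rank deficient; skipping orthogonalization")
        return model
    col_norms = np.linalg.norm(Z, axis=0)
    target = col_norms * (np.linalg.norm(Z) / np.linalg.norm(col_norms))
    T = Vt.T @ np.diag(1.0 / sv) @ np.diag(target)
    Tinv = np.diag(1.0 / target) @ np.diag(sv) @ Vt
    out = model.copy()
    out.manifold.Z_r = U * target[None, :]
    out.transforms.delta_Z = np.einsum("qgj,jk->qgk", out.transforms.delta_Z, T)
    out.embeddings.B = Tinv @ out.embeddings.B
    if out.prior is not None:
        out.prior.A = out.prior.A @ T
    if out.covariates is not None:
        out.covariates.R = np.einsum("jgl,jk->kgl", out.covariates.R, T)
    return out


def _apply_constraints(model: GediModel, config: FitConfig) -> GediModel:
    if config.fixed_embeddings is not None:
        return model
    if config.orthogonalize:
        model = _orthogonalize_in_fit(model)
    pre_rms = np.sqrt(np.mean(model.embeddings.B**2, axis=1))
    model = renormalize_gauge(model)
    if config.ellipsoid:
        v = np.maximum(pre_rms, 1e-12)
        d = v * np.sqrt(np.sum(1.0 / v**2) / model.N)
        try:
            model.embeddings.B = project_ellipsoid(model.embeddings.B, d)
            model.manifold.d = d
        except GediError as exc:  # keep fitting; constraint reported, not fatal
            warnings.warn(f"ellipsoid projection failed this sweep: {exc}")
    return model


def _finalize(model: GediModel, config: FitConfig) -> GediModel:
    """Exact final constraints plus a reproducible factor order.

    Re-applies the (likelihood-invariant) orthogonalization and gauge so the
    returned model satisfies them exactly, then sorts axes by decreasing
    norm and fixes signs (largest-magnitude loading positive).
    """
    if config.fixed_embeddings is not None:
        model.meta["fitted"] = True
        return model
    model = _apply_constraints(model, config)
    order = np.argsort(-np.linalg.norm(model.manifold.Z_r, axis=0), kind="stable")
    model.manifold.Z_r = model.manifold.Z_r[:, order]
    model.transforms.delta_Z = model.transforms.delta_Z[:, :, order]
    model.embeddings.B = model.embeddings.B[order, :]
    if model.prior is not None:
        model.prior.A = model.prior.A[:, order]
    if model.covariates is not None:
        model.covariates.R = model.covariates.R[order]
    if model.manifold.d is not None:
        model.manifold.d = model.manifold.d[order]
    for k in range(model.K):
        j = int(np.argmax(np.abs(model.manifold.Z_r[:, k])))
        if model.manifold.Z_r[j, k] < 0:
            model.manifold.Z_r[:, k] *= -1
            model.transforms.delta_Z[:, :, k] *= -1
            model.embeddings.B[k, :] *= -1
            if model.prior is not None:
                model.prior.A[:, k] *= -1
            if model.covariates is not None:
                model.covariates.R[k] *= -1
    model.meta["fitted"] = True
    return model


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def fit(
    observations: ObservationSet,
    config: FitConfig,
    prior: Optional[GenePriorBlock] = None,
    covariates: Optional[CovariateBlock] = None,
) -> Tuple[GediModel, FitTrace]:
    """Fit the full model; returns the fitted model and the sweep trace.

    ``prior`` only needs its ``C`` matrix populated (coefficients are
    re-initialized); ``covariates`` only needs ``H``.  When
    ``config.fixed_embeddings`` is given, ``B`` is held constant and no
    gauge/orthogonality transform is applied.
    """
    model = initialize(observations, config, prior=prior, covariates=covariates)
    latent = config.mode != "gaussian"
    idx = _sample_indices(model.sample_map, model.Q)
    trace = FitTrace()
    prev = None
    for _sweep in range(config.max_sweeps):
        t0 = time.perf_counter()
        if latent:
            post = compute_posterior(model, observations, n_points=config.e_step_points)
            Ey, Vy = post.Ey, post.Vy
        else:
            post, Ey, Vy = None, observations.Y, None
        norms = {}
        snapshot = {
            "B": model.embeddings.B.copy(),
            "delta_o": model.transforms.delta_o.copy(),
            "Z_r": model.manifold.Z_r.copy(),
        }
        if config.fixed_embeddings is None:
            _update_B(model, Ey, idx, with_s=config.update_s)
        elif config.update_s:
            _update_s(model, Ey, idx)
        if config.fixed_embeddings is None:
            # exactly objective-neutral under the gauge-invariant priors,
            # so the remaining block updates run at unit-norm B rows where
            # the standard ridge forms are the exact conditional maximizers
            model = renormalize_gauge(model)
        if config.project_every_sweep:
            model = _apply_constraints(model, config)
        _update_gene_side(model, Ey, idx)
        if config.fixed_embeddings is None:
            _recenter_embeddings(model, idx)
            if config.update_s:
                _recenter_intercepts(model, idx)
        if model.prior is not None:
            _update_A(model)
        if model.covariates is not None:
            _update_R_o(model)
            _update_R_k(model)
        _update_sigma2(model, Ey, Vy)
        norms["dB"] = float(np.linalg.norm(model.embeddings.B - snapshot["B"]))
        norms["ddelta_o"] = float(
            np.linalg.norm(model.transforms.delta_o - snapshot["delta_o"])
        )
        norms["dZ_r"] = float(np.linalg.norm(model.manifold.Z_r - snapshot["Z_r"]))
        obj = objective(model, observations, post)
        if not np.isfinite(obj):
            raise GediError(
                f"non-finite objective at sweep {_sweep + 1}; trace: {trace.objective}"
            )
        trace.objective.append(obj)
        trace.block_norms.append(norms)
        trace.seconds.append(time.perf_counter() - t0)
        if prev is not None and abs(obj - prev) <= config.tol * (abs(prev) + 1.0):
            break
        prev = obj
    model = _finalize(model, config)
    model.meta["config"] = {
        "K": config.K,
        "mode": config.mode,
        "orthogonalize": config.orthogonalize,
        "ellipsoid": config.ellipsoid,
        "seed": config.seed,
        "tol": config.tol,
        "max_sweeps": config.max_sweeps,
    }
    return model, trace
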