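"""Core model container: reference manifold, per-sample transforms, embeddings.

The model approximates the (latent) expression profile of cell ``n`` from
sample ``i = i(n)`` as an affine image of its low-dimensional state ``b_n``::

    mu_n = o_r + delta_o_i + (Z_r + delta_Z_i) @ b_n + s_n * 1_G

where ``o_r`` (length G) and ``Z_r`` (G x K) define a shared reference
hyperplane, ``delta_o_i`` / ``delta_Z_i`` are sample-specific distortions,
and ``s_n`` is a scalar per-cell intercept.  Scale redundancy between the
axis matrix and the embeddings is resolved by constraining each row of
``B`` (K x N) to unit L2 norm; optionally the columns of ``B`` are further
restricted to a hyperellipsoid with semi-axes ``d``.

Optional blocks:

* a gene-level prior ``C`` (G x P) with coefficients ``A`` (P x K), pulling
  each axis column toward ``C @ a_k`` and enabling per-cell "activity"
  projection ``A @ b_n``;
* a sample-level covariate block ``H`` (L x Q) with effect matrices ``R_o``
  (G x L) and ``R_k`` (G x L per factor), which model the distortions as
  noisy linear functions of sample covariates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GediError",
    "DimensionError",
    "ReferenceManifold",
    "SampleTransformSet",
    "CellEmbeddings",
    "GenePriorBlock",
    "CovariateBlock",
    "GediModel",
    "decode",
    "decode_all",
    "decode_at",
    "renormalize_gauge",
    "enforce_orthogonality",
    "project_ellipsoid",
    "activities",
    "activity_gradient",
]


class GediError(Exception):
    """Base class for errors raised by this package."""


class DimensionError(GediError, ValueError):
    """Inconsistent dimensions between model blocks; names the offender."""


def _as_1d(x, name: str, length: Optional[int] = None) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise DimensionError(f"{name} must be 1-D, got shape {a.shape}")
    if length is not None and a.shape[0] != length:
        raise DimensionError(f"{name} has length {a.shape[0]}, expected {length}")
    return a


@dataclass
class ReferenceManifold:
    """Shared center ``o_r`` (G,) and axis matrix ``Z_r`` (G, K)."""

    o_r: np.ndarray
    Z_r: np.ndarray
    orthogonal_axes: bool = True
    d: Optional[np.ndarray] = None  # ellipsoid semi-axes, length K, > 0

    def __post_init__(self):
        self.o_r = _as_1d(self.o_r, "o_r")
        self.Z_r = np.asarray(self.Z_r, dtype=float)
        if self.Z_r.ndim != 2 or self.Z_r.shape[0] != self.o_r.shape[0]:
            raise DimensionError(
                f"Z_r has shape {self.Z_r.shape}, expected ({self.o_r.shape[0]}, K)"
            )
        if self.d is not None:
            self.d = _as_1d(self.d, "d", self.Z_r.shape[1])
            if np.any(self.d <= 0):
                raise GediError("ellipsoid semi-axes d must be strictly positive")

    @property
    def G(self) -> int:
        return self.o_r.shape[0]

    @property
    def K(self) -> int:
        return self.Z_r.shape[1]


@dataclass
class SampleTransformSet:
    """Per-sample center translations (G, Q) and axis distortions (Q, G, K)."""

    delta_o: np.ndarray
    delta_Z: np.ndarray

    def __post_init__(self):
        self.delta_o = np.asarray(self.delta_o, dtype=float)
        self.delta_Z = np.asarray(self.delta_Z, dtype=float)
        if self.delta_o.ndim != 2:
            raise DimensionError(f"delta_o must be (G, Q), got {self.delta_o.shape}")
        if self.delta_Z.ndim != 3:
            raise DimensionError(f"delta_Z must be (Q, G, K), got {self.delta_Z.shape}")
        if self.delta_Z.shape[0] != self.delta_o.shape[1]:
            raise DimensionError(
                f"delta_Z has {self.delta_Z.shape[0]} samples, delta_o has "
                f"{self.delta_o.shape[1]}"
            )
        if self.delta_Z.shape[1] != self.delta_o.shape[0]:
            raise DimensionError("delta_Z gene dimension does not match delta_o")

    @property
    def Q(self) -> int:
        return self.delta_o.shape[1]


@dataclass
class CellEmbeddings:
    """Embeddings ``B`` (K, N) and per-cell intercepts ``s`` (N,)."""

    B: np.ndarray
    s: np.ndarray

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 2:
            raise DimensionError(f"B must be (K, N), got {self.B.shape}")
        self.s = _as_1d(self.s, "s", self.B.shape[1])

    @property
    def K(self) -> int:
        return self.B.shape[0]

    @property
    def N(self) -> int:
        return self.B.shape[1]


@dataclass
class GenePriorBlock:
    """Gene-level prior matrix ``C`` (G, P) and coefficients ``A`` (P, K).

    ``S_Z`` and ``S_A`` are the variance ratios (relative to the model
    variance) of the axis-column prior ``z_k ~ N(C a_k, sigma2 * S_Z * I)``
    and the coefficient prior ``a_k ~ N(0, sigma2 * S_A * I)``.
    """

    C: np.ndarray
    A: np.ndarray
    S_Z: float = 1.0
    S_A: float = 1.0
    set_names: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.C.ndim != 2 or self.C.shape[1] < 1:
            raise DimensionError(f"C must be (G, P) with P >= 1, got {self.C.shape}")
        if self.A.ndim != 2 or self.A.shape[0] != self.C.shape[1]:
            raise DimensionError(
                f"A has shape {self.A.shape}, expected ({self.C.shape[1]}, K)"
            )
        if not (self.S_Z > 0 and self.S_A > 0):
            raise GediError("prior variance ratios S_Z, S_A must be > 0")

    @property
    def P(self) -> int:
        return self.C.shape[1]


@dataclass
class CovariateBlock:
    """Sample covariates ``H`` (L, Q) and their effect matrices.

    ``R_o`` (G, L) acts on the per-sample center translations; ``R`` (K, G, L)
    stacks the per-factor effect matrices acting on the axis distortions.
    """

    H: np.ndarray
    R_o: np.ndarray
    R: np.ndarray
    S_delta_o: float = 1.0
    S_delta_Z: float = 1.0
    S_Ro: float = 1.0
    S_Rk: float = 1.0
    covariate_names: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float)
        self.R_o = np.asarray(self.R_o, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.H.ndim != 2:
            raise DimensionError(f"H must be (L, Q), got {self.H.shape}")
        L = self.H.shape[0]
        if self.R_o.ndim != 2 or self.R_o.shape[1] != L:
            raise DimensionError(f"R_o has shape {self.R_o.shape}, expected (G, {L})")
        if self.R.ndim != 3 or self.R.shape[2] != L or self.R.shape[1] != self.R_o.shape[0]:
            raise DimensionError(
                f"R has shape {self.R.shape}, expected (K, {self.R_o.shape[0]}, {L})"
            )
        for name in ("S_delta_o", "S_delta_Z", "S_Ro", "S_Rk"):
            if not getattr(self, name) > 0:
                raise GediError(f"prior variance ratio {name} must be > 0")

    @property
    def L(self) -> int:
        return self.H.shape[0]


@dataclass
class GediModel:
    """Full parameter set plus the cell-to-sample map."""

    manifold: ReferenceManifold
    transforms: SampleTransformSet
    embeddings: CellEmbeddings
    sigma2: float
    sample_map: np.ndarray  # (N,) integer sample index per cell
    observation_mode: str = "gaussian"
    prior: Optional[GenePriorBlock] = None
    covariates: Optional[CovariateBlock] = None
    gene_ids: Optional[Sequence[str]] = None
    cell_ids: Optional[Sequence[str]] = None
    sample_ids: Optional[Sequence[str]] = None
    # hyperparameters used when the optional blocks are absent
    S_Z: float = 1.0
    S_delta_o: float = 1.0
    S_delta_Z: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_map = np.asarray(self.sample_map)
        if self.sample_map.ndim != 1:
            raise DimensionError("sample_map must be 1-D")
        self.validate()

    # -- consistency ----------------------------------------------------
    def validate(self) -> None:
        G, K = self.manifold.G, self.manifold.K
        if self.transforms.delta_o.shape != (G, self.transforms.Q):
            raise DimensionError("delta_o does not match manifold gene dimension")
        if self.transforms.delta_Z.shape[1:] != (G, K):
            raise DimensionError(
                f"delta_Z trailing dims {self.transforms.delta_Z.shape[1:]} "
                f"do not match manifold (G={G}, K={K})"
            )
        if self.embeddings.K != K:
            raise DimensionError(
                f"B has K={self.embeddings.K}, manifold has K={K}"
            )
        if self.sample_map.shape[0] != self.embeddings.N:
            raise DimensionError("sample_map length does not match number of cells")
        if self.sample_map.size and (
            self.sample_map.min() < 0 or self.sample_map.max() >= self.transforms.Q
        ):
            raise DimensionError("sample_map indexes samples outside delta blocks")
        if not np.isfinite(self.sigma2) or self.sigma2 <= 0:
            raise GediError(f"sigma2 must be positive and finite, got {self.sigma2}")
        if self.prior is not None and self.prior.C.shape[0] != G:
            raise DimensionError("prior matrix C does not match gene dimension")
        if self.prior is not None and self.prior.A.shape[1] != K:
            raise DimensionError("prior coefficients A do not match factor dimension")
        if self.covariates is not None:
            cov = self.covariates
            if cov.H.shape[1] != self.transforms.Q:
                raise DimensionError("covariate table H does not match sample count")
            if cov.R_o.shape[0] != G or cov.R.shape[0] != K:
                raise DimensionError("covariate effect matrices do not match model dims")
        if self.observation_mode not in ("gaussian", "poisson", "binomial"):
            raise GediError(f"unknown observation_mode {self.observation_mode!r}")

    @property
    def G(self) -> int:
        return self.manifold.G

    @property
    def K(self) -> int:
        return self.manifold.K

    @property
    def N(self) -> int:
        return self.embeddings.N

    @property
    def Q(self) -> int:
        return self.transforms.Q

    def copy(self) -> "GediModel":
        return GediModel(
            manifold=ReferenceManifold(
                self.manifold.o_r.copy(),
                self.manifold.Z_r.copy(),
                self.manifold.orthogonal_axes,
                None if self.manifold.d is None else self.manifold.d.copy(),
            ),
            transforms=SampleTransformSet(
                self.transforms.delta_o.copy(), self.transforms.delta_Z.copy()
            ),
            embeddings=CellEmbeddings(self.embeddings.B.copy(), self.embeddings.s.copy()),
            sigma2=self.sigma2,
            sample_map=self.sample_map.copy(),
            observation_mode=self.observation_mode,
            prior=None
            if self.prior is None
            else dataclasses.replace(self.prior, C=self.prior.C.copy(), A=self.prior.A.copy()),
            covariates=None
            if self.covariates is None
            else dataclasses.replace(
                self.covariates,
                H=self.covariates.H.copy(),
                R_o=self.covariates.R_o.copy(),
                R=self.covariates.R.copy(),
            ),
            gene_ids=None if self.gene_ids is None else list(self.gene_ids),
            cell_ids=None if self.cell_ids is None else list(self.cell_ids),
            sample_ids=None if self.sample_ids is None else list(self.sample_ids),
            S_Z=self.S_Z,
            S_delta_o=self.S_delta_o,
            S_delta_Z=self.S_delta_Z,
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------------

def decode_at(model: GediModel, b, sample_index: int, s: float = 0.0) -> np.ndarray:
    """Decode an arbitrary state ``b`` through the manifold of one sample."""
    b = _as_1d(b, "b", model.K)
    if not 0 <= sample_index < model.Q:
        raise DimensionError(
            f"sample_index {sample_index} out of range for Q={model.Q} samples"
        )
    Z = model.manifold.Z_r + model.transforms.delta_Z[sample_index]
    return (
        model.manifold.o_r
        + model.transforms.delta_o[:, sample_index]
        + Z @ b
        + float(s)
    )


def decode(model: GediModel, cell_index: int) -> np.ndarray:
    """Mean profile ``mu_n`` of one cell (length G)."""
    n = int(cell_index)
    if not 0 <= n < model.N:
        raise DimensionError(f"cell_index {n} out of range for N={model.N}")
    return decode_at(
        model,
        model.embeddings.B[:, n],
        int(model.sample_map[n]),
        model.embeddings.s[n],
    )


def decode_all(model: GediModel) -> np.ndarray:
    """Mean matrix (G, N) for all cells, computed sample by sample."""
    out = np.empty((model.G, model.N))
    B, s = model.embeddings.B, model.embeddings.s
    for i in range(model.Q):
        idx = np.flatnonzero(model.sample_map == i)
        if idx.size == 0:
            continue
        Z = model.manifold.Z_r + model.transforms.delta_Z[i]
        out[:, idx] = (
            (model.manifold.o_r + model.transforms.delta_o[:, i])[:, None]
            + Z @ B[:, idx]
            + s[idx][None, :]
        )
    return out


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

def renormalize_gauge(model: GediModel) -> GediModel:
    """Rescale so each row of ``B`` has unit norm, leaving decodes unchanged.

    Row ``k`` of ``B`` is divided by its norm ``c_k`` and column ``k`` of
    ``Z_r`` and of every ``delta_Z_i`` is multiplied by ``c_k``; the
    likelihood is invariant under this rescaling.  Coefficient columns
    ``a_k`` and effect matrices ``R_k``, whose priors are tied to the axis
    columns, are rescaled consistently.
    """
    out = model.copy()
    c = np.linalg.norm(out.embeddings.B, axis=1)
    if np.any(c == 0):
        k = int(np.flatnonzero(c == 0)[0])
        raise GediError(f"cannot renormalize gauge: B row {k} is all zero")
    out.embeddings.B /= c[:, None]
    out.manifold.Z_r *= c[None, :]
    out.transforms.delta_Z *= c[None, None, :]
    if out.prior is not None:
        out.prior.A *= c[None, :]
    if out.covariates is not None:
        out.covariates.R *= c[:, None, None]
    if out.manifold.d is not None:
        out.manifold.d = out.manifold.d / c
    return out


def enforce_orthogonality(Z: np.ndarray, rel_tol: float = 1e-12) -> np.ndarray:
    """Symmetric (Loewdin) orthogonalization of the columns of ``Z``.

    The closest orthonormal basis ``U V^T`` (from the SVD ``Z = U S V^T``) is
    rescaled so that column norms are proportional to the input column norms
    and the total Frobenius norm is preserved.  The column span is unchanged.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise DimensionError(f"Z must be 2-D, got shape {Z.shape}")
    G, K = Z.shape
    if K > G:
        raise DimensionError(f"K={K} exceeds G={G}")
    U, sv, Vt = np.linalg.svd(Z, full_matrices=False)
    if sv[0] == 0:
        raise GediError("Z is entirely zero")
    if sv[-1] <= rel_tol * sv[0]:
        bad = np.flatnonzero(sv <= rel_tol * sv[0])
        # column-pivoted QR names the columns most involved in the deficiency
        from scipy.linalg import qr

        _, _, piv = qr(Z, pivoting=True, mode="economic")
        dep = sorted(int(j) for j in piv[K - bad.size :])
        raise GediError(f"Z is rank deficient; dependent columns: {dep}")
    ortho = U @ Vt
    col_norms = np.linalg.norm(Z, axis=0)
    target = col_norms * (np.linalg.norm(Z) / np.linalg.norm(col_norms))
    return ortho * target[None, :]


def project_ellipsoid(
    B: np.ndarray,
    d: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Alternate row (unit-norm) and column (ellipsoid) normalizations.

    Rows of ``B`` are scaled to unit L2 norm; columns are scaled so that
    ``sum_k (b_kn / d_k)^2 = 1``.  Iterates until both residuals fall below
    ``tol`` or raises after ``max_iter`` iterations (the two constraints are
    not jointly feasible for every ``d``).
    """
    B = np.asarray(B, dtype=float).copy()
    d = _as_1d(d, "d", B.shape[0])
    if np.any(d <= 0):
        raise GediError("ellipsoid semi-axes d must be strictly positive")
    for _ in range(max_iter):
        row = np.linalg.norm(B, axis=1)
        if np.any(row == 0):
            raise GediError("cannot project: zero row in B")
        B /= row[:, None]
        col = np.sqrt(np.sum((B / d[:, None]) ** 2, axis=0))
        if np.any(col == 0):
            raise GediError("cannot project: zero column in B")
        B /= col[None, :]
        row_res = np.abs(np.linalg.norm(B, axis=1) - 1.0).max()
        col_res = np.abs(np.sqrt(np.sum((B / d[:, None]) ** 2, axis=0)) - 1.0).max()
        if row_res < tol and col_res < tol:
            return B
    raise GediError(
        f"ellipsoid projection did not converge in {max_iter} iterations "
        f"(row residual {row_res:.3g}, column residual {col_res:.3g})"
    )


# ---------------------------------------------------------------------------
# gene-level prior algebra
# ---------------------------------------------------------------------------

def activities(model: GediModel) -> np.ndarray:
    """Projected per-cell activities ``A @ B`` (P, N) of the prior sets."""
    if model.prior is None:
        raise GediError("model has no gene-level prior block")
    return model.prior.A @ model.embeddings.B


def activity_gradient(model: GediModel, p: int) -> np.ndarray:
    """Direction of steepest activity increase in expression space: Z_r a_p^T."""
    if model.prior is None:
        raise GediError("model has no gene-level prior block")
    p = int(p)
    if not 0 <= p < model.prior.P:
        raise GediError(f"prior set index {p} out of range for P={model.prior.P}")
    return model.manifold.Z_r @ model.prior.A[p, :]
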