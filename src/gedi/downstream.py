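"""Post-fit analyses: vector fields, group summaries, sample featurization.

The decoder is affine in the sample covariates, so the per-cell change in
expected expression for a unit step in covariate ``l`` is exact::

    v_n = R_o[:, l] + sum_k R_k[:, l] * b_{k,n}

These per-cell differential-expression vectors form a field over the cell
state continuum; summarizing them within any grouping of cells reproduces
cluster-level differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .model import GediError, GediModel

__all__ = [
    "VectorField",
    "SampleFeatureMatrix",
    "vector_field",
    "field_group_summary",
    "field_vs_gradient",
    "sample_features",
    "residualize_features",
]


@dataclass
class VectorField:
    """Per-cell DE vectors (G, N) for one sample-level covariate."""

    covariate: int
    V: np.ndarray
    magnitudes: np.ndarray
    step: float = 1.0


@dataclass
class SampleFeatureMatrix:
    """Samples-by-features matrix built from the sample-specific transforms."""

    F: np.ndarray
    feature_names: Sequence[str]
    sample_ids: Optional[Sequence[str]] = None


def vector_field(model: GediModel, l: int, step: float = 1.0) -> VectorField:
    """Transcriptomic vector field of covariate ``l`` (exactly linear in step)."""
    if model.covariates is None:
        raise GediError("model has no covariate block; refit with covariates")
    cov = model.covariates
    l = int(l)
    if not 0 <= l < cov.L:
        raise GediError(f"covariate index {l} out of range for L={cov.L}")
    V = step * (
        cov.R_o[:, l][:, None]
        + np.einsum("kg,kn->gn", cov.R[:, :, l], model.embeddings.B)
    )
    return VectorField(l, V, np.linalg.norm(V, axis=0), step)


def field_group_summary(
    field: VectorField, labels: Sequence
) -> Tuple[dict, dict]:
    """Mean DE vector and mean magnitude per group of cells.

    Returns ``(mean_vectors, mean_magnitudes)`` keyed by group label.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != field.V.shape[1]:
        raise GediError(
            f"labels length {labels.shape[0]} does not match {field.V.shape[1]} cells"
        )
    vectors, magnitudes = {}, {}
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size == 0:
            raise GediError(f"empty group {g!r}")
        vectors[g] = field.V[:, idx].mean(axis=1)
        magnitudes[g] = float(field.magnitudes[idx].mean())
    return vectors, magnitudes


def field_vs_gradient(
    field: VectorField, model: GediModel
) -> Tuple[np.ndarray, np.ndarray]:
    """Cosine similarity (P, N) of each DE vector with each activity gradient.

    Zero-norm vectors yield similarity 0; the returned boolean mask flags
    those entries.
    """
    if model.prior is None:
        raise GediError("model has no gene-level prior block")
    grads = model.manifold.Z_r @ model.prior.A.T  # (G, P)
    gn = np.linalg.norm(grads, axis=0)
    vn = field.magnitudes
    dots = grads.T @ field.V  # (P, N)
    denom = gn[:, None] * vn[None, :]
    mask = denom == 0
    cos = np.zeros_like(dots)
    np.divide(dots, denom, out=cos, where=~mask)
    np.clip(cos, -1.0, 1.0, out=cos)
    return cos, mask


def sample_features(
    model: GediModel, include_delta_o: bool = False
) -> SampleFeatureMatrix:
    """Row ``i`` = vectorized ``delta_Z_i``, columns stacked (gene fastest).

    Feature order is ``dZ[k=0][g=0..G-1], dZ[k=1][...], ...`` and, when
    requested, ``delta_o_i`` appended after all axis columns.  This order is
    part of the archive contract.
    """
    Q, G, K = model.transforms.delta_Z.shape
    F = model.transforms.delta_Z.transpose(0, 2, 1).reshape(Q, G * K)
    names = [f"dZ[k={k}][g={g}]" for k in range(K) for g in range(G)]
    if include_delta_o:
        F = np.hstack([F, model.transforms.delta_o.T])
        names += [f"do[g={g}]" for g in range(G)]
    return SampleFeatureMatrix(F, names, model.sample_ids)


def residualize_features(
    F: np.ndarray, nuisance: np.ndarray, top: int = 20
) -> Tuple[np.ndarray, np.ndarray]:
    """Remove the least-squares projection of ``F`` on nuisance covariates.

    Returns ``(residuals, top_variance_indices)``; residual columns are
    orthogonal to every nuisance column.
    """
    F = np.asarray(F, dtype=float)
    nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuisance.shape[0] != F.shape[0]:
        raise GediError(
            f"nuisance has {nuisance.shape[0]} rows, features have {F.shape[0]}"
        )
    if nuisance.shape[1] >= F.shape[0]:
        raise GediError("nuisance must have fewer columns than there are samples")
    if np.linalg.matrix_rank(nuisance) < nuisance.shape[1]:
        raise GediError("nuisance matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(nuisance, F, rcond=None)
    resid = F - nuisance @ coef
    var = resid.var(axis=0)
    top_idx = np.argsort(-var, kind="stable")[: min(top, F.shape[1])]
    return resid, top_idx
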