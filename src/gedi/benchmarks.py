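"""Self-contained benchmark routines used by the acceptance suite.

Each function generates its own data (deterministically from a seed), runs
the relevant part of the pipeline, and returns plain numbers.  They are the
desk-scale analogues of the cohort-level differential-expression and
ratio-imputation evaluations.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy.linalg import subspace_angles
from scipy.stats import rankdata

from .downstream import vector_field
from .fit import FitConfig, fit
from .model import CovariateBlock
from .observations import ObservationSet, impute
from .simulate import default_paired_params, default_params, simulate, simulate_paired

__all__ = [
    "auroc",
    "estep_grid_error",
    "pca_limit_max_angle",
    "cohort_de_recovery",
    "paired_imputation_benchmark",
]


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum statistic."""
    labels = np.asarray(labels, dtype=bool)
    pos = int(labels.sum())
    neg = labels.size - pos
    if pos == 0 or neg == 0:
        return np.nan
    ranks = rankdata(scores)
    return (ranks[labels].sum() - pos * (pos + 1) / 2) / (pos * neg)


def estep_grid_error(counts=(0, 1, 5, 50, 500), mus=(-5.0, 0.0, 5.0),
                     sigma2s=(0.1, 1.0, 4.0)) -> Dict[str, float]:
    """Worst-case |posterior moment - trapezoid oracle| over the grid."""
    from .observations import binomial_estep, poisson_estep

    y = np.linspace(-25.0, 25.0, 4000)

    def oracle(logpost):
        w = np.exp(logpost - logpost.max())
        norm = np.trapezoid(w, y)
        ey = np.trapezoid(w * y, y) / norm
        vy = np.trapezoid(w * (y - ey) ** 2, y) / norm
        return ey, vy

    worst_p = worst_b = 0.0
    counts = list(counts)
    for i, m in enumerate(counts):
        m2 = counts[len(counts) - 1 - i]
        for mu in mus:
            for s2 in sigma2s:
                ey, vy = poisson_estep(m, mu, s2)
                oe, ov = oracle(m * y - np.exp(y) - (y - mu) ** 2 / (2 * s2))
                worst_p = max(worst_p, abs(ey - oe), abs(vy - ov))
                ey, vy = binomial_estep(m, m2, mu, s2)
                oe, ov = oracle(
                    m * y - (m + m2) * np.logaddexp(0, y) - (y - mu) ** 2 / (2 * s2)
                )
                worst_b = max(worst_b, abs(ey - oe), abs(vy - ov))
    return {"poisson": worst_p, "binomial": worst_b}


def pca_limit_max_angle(G=200, N=500, K=5, seed=0) -> float:
    """Max principal angle between the fitted axes and the top-K SVD subspace.

    Single sample, effectively prior-free; the data are column-centred so
    the per-cell intercepts vanish at the optimum and the model reduces to
    penalized PCA of the row-centred matrix.
    """
    rng = np.random.default_rng(seed)
    Y0 = rng.normal(size=(G, N))
    Y0 -= Y0.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Y0, full_matrices=False)
    S[:K] *= 6.0
    Y = (U * S) @ Vt
    obs = ObservationSet("gaussian", np.zeros(N, int), Y=Y)
    cfg = FitConfig(
        K=K, S_Z=1e12, S_A=1e12, S_delta_o=1e-8, S_delta_Z=1e-8,
        tol=1e-12, max_sweeps=300,
    )
    model, _ = fit(obs, cfg)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Uk = np.linalg.svd(Yc, full_matrices=False)[0][:, :K]
    return float(np.max(subspace_angles(Uk, model.manifold.Z_r)))


def cohort_de_recovery(
    seed=1, G=300, N=2000, Q=12, K_arch=5, L=2, K_fit=8, max_sweeps=40
) -> Dict[str, float]:
    """Fit the count model on a simulated cohort; score the DE vector field.

    Returns the median per-cell Pearson correlation between the inferred
    vector field of the planted condition covariate and the ground-truth
    per-cell DE vectors, plus median per-cell AUROCs for classifying
    up-/down-regulated genes (|log2 truth| > 0.3).
    """
    params = default_params(G=G, N=N, Q=Q, K_arch=K_arch, L=L, seed=seed)
    cohort = simulate(params)
    obs = ObservationSet("poisson", cohort.sample_map, M=cohort.counts)
    H = params.H[1:2]  # the planted 0/1 condition covariate
    cov = CovariateBlock(
        H=H, R_o=np.zeros((G, 1)), R=np.zeros((K_fit, G, 1))
    )
    cfg = FitConfig(K=K_fit, mode="poisson", max_sweeps=max_sweeps, tol=1e-5, seed=seed)
    model, trace = fit(obs, cfg, covariates=cov)
    V = vector_field(model, 0).V  # natural-log units; scale-free metrics below
    delta = cohort.delta[:, :, 1].T  # log2 truth, (G, N)

    Vc = V - V.mean(axis=0)
    Dc = delta - delta.mean(axis=0)
    rs = (Vc * Dc).sum(axis=0) / np.sqrt(
        (Vc**2).sum(axis=0) * (Dc**2).sum(axis=0)
    )
    up, dn = [], []
    for n in range(N):
        lab_up = delta[:, n] > 0.3
        lab_dn = delta[:, n] < -0.3
        if 0 < lab_up.sum() < G:
            up.append(auroc(lab_up, V[:, n]))
        if 0 < lab_dn.sum() < G:
            dn.append(auroc(lab_dn, -V[:, n]))
    drops = np.diff(trace.objective) / (np.abs(np.asarray(trace.objective[:-1])) + 1)
    return {
        "median_pearson": float(np.median(rs)),
        "median_auroc_up": float(np.median(up)),
        "median_auroc_down": float(np.median(dn)),
        "worst_relative_objective_drop": float(drops.min()) if drops.size else 0.0,
        "n_cells": N,
    }


def paired_imputation_benchmark(
    seed=7, G=350, N=1500, Q=6, K_arch=3, depth=0.6, event_scale=0.6,
    cell_sd=0.04, K_fit=2, max_sweeps=40
) -> Dict[str, float]:
    """Latent-ratio imputation at sparse per-event depth vs. a naive ratio.

    Per-event Pearson correlation (across cells) between the true logit
    field and (a) the model's posterior-mean logit, (b) the smoothed
    empirical logit ``log((m1 + 0.5) / (m2 + 0.5))``.
    """
    params = default_paired_params(
        G=G, N=N, Q=Q, K_arch=K_arch, seed=seed,
        event_scale=event_scale, cell_sd=cell_sd,
    )
    paired = simulate_paired(params, depth=depth)
    obs = ObservationSet("binomial", paired.sample_map, M1=paired.M1, M2=paired.M2)
    cfg = FitConfig(K=K_fit, mode="binomial", max_sweeps=max_sweeps, tol=1e-6, seed=seed)
    model, _ = fit(obs, cfg)
    post, _ = impute(model, obs)
    naive = np.log((paired.M1 + 0.5) / (paired.M2 + 0.5))
    truth = paired.truth_logit

    def per_event_corr(est):
        ec = est - est.mean(axis=1, keepdims=True)
        tc = truth - truth.mean(axis=1, keepdims=True)
        return (ec * tc).sum(axis=1) / np.sqrt(
            (ec**2).sum(axis=1) * (tc**2).sum(axis=1)
        )

    model_r = per_event_corr(post.Ey)
    naive_r = per_event_corr(naive)
    return {
        "model_median_pearson": float(np.median(model_r)),
        "naive_median_pearson": float(np.median(naive_r)),
        "fraction_model_beats_naive": float(np.mean(model_r > naive_r)),
        "n_events": G,
    }
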