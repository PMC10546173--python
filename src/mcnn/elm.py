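"""Closed-form extreme-learning-machine training of the output layer.

In an ELM the hidden layers are random and fixed; only the linear output
layer is trained, by ridge-regularized least squares with +-1 targets:

    beta = argmin ||H beta - t||^2 + lam ||beta||^2

where ``H`` is the (N, d) matrix of extracted features (bias column
appended) and ``t`` in {-1, +1}^N.  The solution is the regularized
normal-equation solve ``beta = (H'H + lam I)^-1 H't``; when N < d — the
usual regime here, with a few hundred images against d = 20,481 — the
algebraically identical dual form ``beta = H'(HH' + lam I)^-1 t`` is used
instead, which only ever factorizes an N x N matrix.

The regularization strength ``lam`` is the model's single tunable training
parameter.  No validation set is needed: the solve is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve
from scipy.special import expit

from .channel_network import ChannelNetwork

__all__ = ["ELMSolution", "solve_ridge", "score_to_probability", "fit_channel"]

#: default ridge strength, exposed through every fitting entry point
DEFAULT_LAM = 1.0


@dataclass(frozen=True)
class ELMSolution:
    """Ridge solution ``beta`` plus the training residual ``||H beta - t||``."""

    beta: np.ndarray
    train_residual: float


def solve_ridge(H: np.ndarray, t: np.ndarray, lam: float) -> ELMSolution:
    """Solve the ridge-regularized least-squares problem for beta.

    Dispatches automatically between the primal form (N >= d) and the dual
    form (N < d); the two agree up to numerical round-off.

    Raises
    ------
    ValueError
        On non-finite inputs or a non-positive ``lam`` (the unregularized
        normal equations are singular whenever N < d).
    """
    H = np.asarray(H, dtype=float)
    t = np.asarray(t, dtype=float)
    if H.ndim != 2 or t.shape != (H.shape[0],):
        raise ValueError(f"incompatible shapes H {H.shape}, t {t.shape}")
    if not np.isfinite(H).all() or not np.isfinite(t).all():
        raise ValueError("design matrix and targets must be finite")
    if lam <= 0:
        raise ValueError("lam must be > 0 (the ridge term makes the system well-posed)")
    n, d = H.shape
    eye = np.eye(min(n, d))
    if n >= d:
        beta = solve(H.T @ H + lam * eye, H.T @ t, assume_a="pos")
    else:
        beta = H.T @ solve(H @ H.T + lam * eye, t, assume_a="pos")
    res = float(np.linalg.norm(H @ beta - t))
    return ELMSolution(beta=beta, train_residual=res)


def score_to_probability(score: np.ndarray | float) -> np.ndarray | float:
    """Map a linear output score to a positive-class probability.

    The logistic map ``p = 1 / (1 + exp(-s))`` — strictly increasing, 0.5
    at zero score, saturating smoothly at the extremes.
    """
    return expit(score)


def fit_channel(
    network: ChannelNetwork,
    images: np.ndarray,
    labels: np.ndarray,
    lam: float = DEFAULT_LAM,
) -> ChannelNetwork:
    """Fit one channel network's output weights by the ELM solve.

    Builds the design matrix from ``extract_features`` (bias column
    appended), codes the binary labels {0, 1} as targets {-1, +1}, solves
    the ridge system, and stores the weights on the network.  Deterministic:
    the only randomness is the network's construction seed.

    Raises
    ------
    ValueError
        If only one class is present in ``labels``.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training set must contain both classes")
    features = network.extract_features_batch(np.asarray(images, dtype=float))
    H = np.hstack([features, np.ones((features.shape[0], 1))])
    t = 2.0 * (labels > 0) - 1.0
    network.output_weights = solve_ridge(H, t, lam).beta
    return network


def normal_equation_residual(H: np.ndarray, t: np.ndarray, lam: float, beta: np.ndarray) -> float:
    """Relative residual of the regularized normal equations at ``beta``.

    Used as a post-fit correctness check: a valid solution from either the
    primal or the dual form drives this to numerical round-off.
    """
    H = np.asarray(H, dtype=float)
    lhs = H.T @ (H @ beta) + lam * beta
    rhs = H.T @ np.asarray(t, dtype=float)
    return float(np.linalg.norm(lhs - rhs) / max(np.linalg.norm(rhs), 1e-300))
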