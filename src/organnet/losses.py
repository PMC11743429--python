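"""Asymmetric (focal-style) loss for imbalanced multi-label organ status.

For a predicted probability ``p`` and binary label ``y`` the per-organ loss is

    L(p, 1) = -(1 - p)^gamma * log(p)
    L(p, 0) = -(p)^gamma     * log(1 - p)

with ``gamma >= 0`` the focusing exponent: gamma = 0 recovers plain binary
cross-entropy, larger gamma down-weights easy examples so the many
easy negatives of an imbalanced cohort do not dominate the gradient.  The
batch objective is the mean over samples of the sum over the five organs.

Probabilities are clamped to ``[eps, 1 - eps]`` before the logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ASLConfig", "asl_single", "asl_batch", "asl_grad"]

N_ORGANS = 5


@dataclass(frozen=True)
class ASLConfig:
    """Configuration of the asymmetric loss.

    Parameters
    ----------
    gamma : float
        Focusing exponent applied to both the positive and negative branch
        (>= 0).  Default 2.0, the common focal-loss setting.
    gamma_neg : float or None
        Optional separate exponent for the negative (y = 0) branch; when
        None, ``gamma`` is used for both branches.
    epsilon : float
        Probability clamp applied before the logarithms; must lie in
        (0, 0.01).
    """

    gamma: float = 2.0
    gamma_neg: float | None = None
    epsilon: float = 1e-7

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.gamma_neg is not None and self.gamma_neg < 0:
            raise ValueError("gamma_neg must be >= 0")
        if not (0.0 < self.epsilon < 0.01):
            raise ValueError("epsilon must lie in (0, 0.01)")

    @property
    def effective_gamma_neg(self) -> float:
        return self.gamma if self.gamma_neg is None else self.gamma_neg


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0 or 1)")
    return y.astype(np.float64)


def _asl_elementwise(p: np.ndarray, y: np.ndarray, config: ASLConfig) -> np.ndarray:
    pc = np.clip(p, config.epsilon, 1.0 - config.epsilon)
    pos = -((1.0 - pc) ** config.gamma) * np.log(pc)
    neg = -(pc ** config.effective_gamma_neg) * np.log(1.0 - pc)
    return np.where(y == 1.0, pos, neg)


def asl_single(p: float, y: int, config: ASLConfig = ASLConfig()) -> float:
    """Asymmetric loss for one probability/label pair.  Always >= 0."""
    p_arr = _check_probs(p)
    y_arr = _check_labels(y)
    return float(_asl_elementwise(p_arr, y_arr, config))


def asl_batch(probs: np.ndarray, labels: np.ndarray,
              config: ASLConfig = ASLConfig()) -> float:
    """Mean over samples of the summed five-organ asymmetric loss.

    ``probs`` and ``labels`` are ``n x 5`` arrays (one row per sample, one
    column per organ in canonical order).
    """
    p = _check_probs(probs)
    y = _check_labels(labels)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {y.shape}")
    if p.ndim != 2 or p.shape[1] != N_ORGANS or p.shape[0] < 1:
        raise ValueError(f"expected an n x {N_ORGANS} array with n >= 1, got {p.shape}")
    per_elem = _asl_elementwise(p, y, config)
    return float(per_elem.sum(axis=1).mean())


def asl_grad(probs: np.ndarray, labels: np.ndarray,
             config: ASLConfig = ASLConfig()) -> np.ndarray:
    """dL/dp of the elementwise asymmetric loss (no batch averaging).

    Used by the trainer, which chains it with the sigmoid derivative.
    Gradients are zero where the clamp is active, matching the clamped
    forward value.
    """
    p = _check_probs(probs)
    y = _check_labels(labels)
    eps = config.epsilon
    pc = np.clip(p, eps, 1.0 - eps)
    g_pos = config.gamma
    g_neg = config.effective_gamma_neg
    one_m = 1.0 - pc
    # d/dp [-(1-p)^g log p] = g (1-p)^(g-1) log p - (1-p)^g / p
    # (the clamp keeps pc and 1-pc >= eps, so the g-1 power stays finite)
    dpos = g_pos * one_m ** (g_pos - 1.0) * np.log(pc) - one_m ** g_pos / pc
    # d/dp [-(p)^g log(1-p)] = -g p^(g-1) log(1-p) + p^g / (1-p)
    dneg = -g_neg * pc ** (g_neg - 1.0) * np.log(one_m) + pc ** g_neg / one_m
    grad = np.where(y == 1.0, dpos, dneg)
    grad[(p < eps) | (p > 1.0 - eps)] = 0.0
    return grad
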