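"""Stage-2 logit distillation: temperature softening and per-sample normalization.

Vanilla logit distillation softens teacher and student logits with one
global temperature ``T``.  Normalized logit distillation instead rescales
every sample's logit vector by its own dispersion: row ``i`` is softened at
the effective temperature ``sigma_i * T_norm``, where ``sigma_i`` is the
population standard deviation of that row's logits.  Samples with confident,
spread-out logits are softened more, and flat logit rows less, which removes
the single-temperature compromise.

Logit batches are arrays shaped ``(N, K)``: ``N`` samples, ``K >= 2`` classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, softmax

__all__ = [
    "NormKDConfig",
    "soften",
    "logit_sigma",
    "normalize_logits",
    "normkd_loss",
    "vanilla_kd_loss",
]


@dataclass
class NormKDConfig:
    """Settings of the normalized softening.

    t_norm
        Global scale multiplying each row's standard deviation to form the
        per-sample temperature (default 2.0).
    sigma_floor
        Lower bound on the per-row standard deviation, guarding constant
        logit rows (default 1e-6).
    direction
        KL direction of the distillation loss; ``"teacher||student"``
        (default, the conventional choice) or ``"student||teacher"``.
    """

    t_norm: float = 2.0
    sigma_floor: float = 1e-6
    direction: str = "teacher||student"

    def __post_init__(self):
        if not self.t_norm > 0 or not np.isfinite(self.t_norm):
            raise ValueError("t_norm must be a finite positive number")
        if not self.sigma_floor > 0:
            raise ValueError("sigma_floor must be positive")
        if self.direction not in ("teacher||student", "student||teacher"):
            raise ValueError("direction must be 'teacher||student' or 'student||teacher'")


def _as_batch(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    if z.ndim == 1:
        z = z[None, :]
    if z.ndim != 2 or z.shape[1] < 2:
        raise ValueError("expected logits shaped (N, K) with K >= 2")
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    return z


def soften(z: np.ndarray, temperature: float) -> np.ndarray:
    """Row-wise softmax of ``z / T``; each row sums to 1."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    return softmax(_as_batch(z) / temperature, axis=1)


def logit_sigma(z: np.ndarray) -> np.ndarray:
    """Per-sample population standard deviation of the K logits."""
    return _as_batch(z).std(axis=1)


def normalize_logits(z: np.ndarray, cfg: NormKDConfig) -> np.ndarray:
    """Soften each row at its own temperature ``max(sigma_i, floor) * T_norm``."""
    z = _as_batch(z)
    sigma = np.maximum(z.std(axis=1), cfg.sigma_floor)
    return softmax(z / (sigma[:, None] * cfg.t_norm), axis=1)


def _kl_rows(z_p: np.ndarray, z_q: np.ndarray) -> np.ndarray:
    """Row-wise KL(p || q) for two pre-softmax (already scaled) logit batches."""
    log_p = log_softmax(z_p, axis=1)
    log_q = log_softmax(z_q, axis=1)
    p = np.exp(log_p)
    return np.sum(p * (log_p - log_q), axis=1)


def normkd_loss(z_s: np.ndarray, z_t: np.ndarray, cfg: NormKDConfig | None = None) -> float:
    """Normalized-logit distillation loss.

    Each side is softened at its own per-row temperature; row ``i`` of the
    KL divergence is weighted by ``(t_norm * sigma_i^teacher)^2`` (the
    squared effective teacher temperature, the usual gradient-scale
    compensation), and the result is averaged over the batch:

        (1/N) * sum_i (t_norm * sigma_i^t)^2 * KL(p~_i^t || p~_i^s)

    Zero exactly when the normalized predictions coincide row-wise.
    """
    cfg = cfg or NormKDConfig()
    z_s, z_t = _as_batch(z_s), _as_batch(z_t)
    if z_s.shape != z_t.shape:
        raise ValueError(f"shape mismatch: student {z_s.shape} vs teacher {z_t.shape}")
    sig_t = np.maximum(z_t.std(axis=1), cfg.sigma_floor)
    sig_s = np.maximum(z_s.std(axis=1), cfg.sigma_floor)
    zt_scaled = z_t / (sig_t[:, None] * cfg.t_norm)
    zs_scaled = z_s / (sig_s[:, None] * cfg.t_norm)
    if cfg.direction == "teacher||student":
        kl = _kl_rows(zt_scaled, zs_scaled)
    else:
        kl = _kl_rows(zs_scaled, zt_scaled)
    return float(np.mean((cfg.t_norm * sig_t) ** 2 * kl))


def vanilla_kd_loss(z_s: np.ndarray, z_t: np.ndarray, temperature: float) -> float:
    """Classic soft-label distillation: T^2-weighted mean KL at temperature T."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    z_s, z_t = _as_batch(z_s), _as_batch(z_t)
    if z_s.shape != z_t.shape:
        raise ValueError(f"shape mismatch: student {z_s.shape} vs teacher {z_t.shape}")
    kl = _kl_rows(z_t / temperature, z_s / temperature)
    return float(temperature ** 2 * np.mean(kl))


# ---------------------------------------------------------------------------
# Gradients (used by the trainer; sigma of the student row is treated as a
# constant within each update, a standard stabilization)
# ---------------------------------------------------------------------------

def normkd_grad(z_s: np.ndarray, z_t: np.ndarray, cfg: NormKDConfig | None = None) -> np.ndarray:
    """d normkd_loss / d z_s for the teacher||student direction."""
    cfg = cfg or NormKDConfig()
    z_s, z_t = _as_batch(z_s), _as_batch(z_t)
    sig_t = np.maximum(z_t.std(axis=1), cfg.sigma_floor)
    sig_s = np.maximum(z_s.std(axis=1), cfg.sigma_floor)
    p_t = softmax(z_t / (sig_t[:, None] * cfg.t_norm), axis=1)
    p_s = softmax(z_s / (sig_s[:, None] * cfg.t_norm), axis=1)
    n = z_s.shape[0]
    weight = (cfg.t_norm * sig_t) ** 2 / (sig_s * cfg.t_norm)
    return weight[:, None] * (p_s - p_t) / n


def vanilla_kd_grad(z_s: np.ndarray, z_t: np.ndarray, temperature: float) -> np.ndarray:
    """d vanilla_kd_loss / d z_s."""
    z_s, z_t = _as_batch(z_s), _as_batch(z_t)
    p_t = softmax(z_t / temperature, axis=1)
    p_s = softmax(z_s / temperature, axis=1)
    return temperature * (p_s - p_t) / z_s.shape[0]
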