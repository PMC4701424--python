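"""Vectorized kernels over stacks of contingency tables.

These power the Monte Carlo and bootstrap machinery: every formula here is
the batched twin of a scalar public function (`core.population_rho`,
`asymptotics.grad_rho`, `asymptotics.asymptotic_variance`) and the test
suite pins the two routes to each other.

Gradients are computed in "unconstrained" form over all I*J cells.  The
delta-method variance g' (diag(h) - h h') g is invariant to adding a
constant to the gradient, so the reduced gradient used in the analytic
derivation (last cell eliminated) is recovered simply as
``D - D[..., -1, -1]``; the variance can be evaluated from either form.
Tables with a flat margin yield NaN here; scalar entry points turn that
into a typed error.
"""

from __future__ import annotations

import numpy as np

_DEGEN_TOL = 1e-12


def batch_rho(counts_or_probs: np.ndarray) -> np.ndarray:
    """Spearman rho for a (..., I, J) stack of count or probability tables.

    Returns an array of shape (...); NaN where a margin is degenerate.
    """
    rho, _ = _rho_core(np.asarray(counts_or_probs, dtype=float))
    return rho


def _rho_core(t: np.ndarray):
    """Shared normalization + rho; returns (rho, internals dict)."""
    total = t.sum(axis=(-2, -1), keepdims=True)
    h = t / total
    p = h.sum(axis=-1)
    q = h.sum(axis=-2)
    bp = 1.0 - (p**3).sum(axis=-1)
    bq = 1.0 - (q**3).sum(axis=-1)
    degen = (bp <= _DEGEN_TOL) | (bq <= _DEGEN_TOL)
    bp_safe = np.where(degen, 1.0, bp)
    bq_safe = np.where(degen, 1.0, bq)
    F = np.cumsum(p, axis=-1)
    G = np.cumsum(q, axis=-1)
    vF = 2.0 * F - p  # F_i + F_{i-1}
    vG = 2.0 * G - q
    A = np.einsum("...ij,...i,...j->...", h, vF, vG)
    B = np.sqrt(bp_safe * bq_safe)
    rho = np.clip(3.0 * (A - 1.0) / B, -1.0, 1.0)
    rho = np.where(degen, np.nan, rho)
    internals = dict(h=h, p=p, q=q, bp=bp_safe, bq=bq_safe, vF=vF, vG=vG, B=B,
                     degen=degen)
    return rho, internals


def batch_grad_rho_full(counts_or_probs: np.ndarray):
    """Unconstrained gradient of rho over all I*J cells, batched.

    Returns (rho, D) where D has the same (..., I, J) shape.  The chain
    rule through the margins gives, for the numerator term A,

        dA/dh_rs = (F_r+F_{r-1})(G_s+G_{s-1})
                   + sum_j (G_j+G_{j-1}) [h_rj + 2 sum_{i>r} h_ij]
                   + sum_i (F_i+F_{i-1}) [h_is + 2 sum_{j>s} h_ij]

    and for the denominator B = sqrt(bp * bq),

        dB/dh_rs = -(3B/2) (p_r^2 / bp + q_s^2 / bq).
    """
    t = np.asarray(counts_or_probs, dtype=float)
    rho, c = _rho_core(t)
    h, p, q = c["h"], c["p"], c["q"]
    vF, vG, B = c["vF"], c["vG"], c["B"]
    # suffix sums over strictly larger indices
    over_i = np.flip(np.cumsum(np.flip(h, axis=-2), axis=-2), axis=-2)
    over_i = np.concatenate(
        [over_i[..., 1:, :], np.zeros_like(over_i[..., :1, :])], axis=-2
    )
    over_j = np.flip(np.cumsum(np.flip(h, axis=-1), axis=-1), axis=-1)
    over_j = np.concatenate(
        [over_j[..., :, 1:], np.zeros_like(over_j[..., :, :1])], axis=-1
    )
    row = np.einsum("...j,...rj->...r", vG, h + 2.0 * over_i)
    col = np.einsum("...i,...is->...s", vF, h + 2.0 * over_j)
    dA = vF[..., :, None] * vG[..., None, :] + row[..., :, None] + col[..., None, :]
    dB = -1.5 * B[..., None, None] * (
        (p**2 / c["bp"][..., None])[..., :, None]
        + (q**2 / c["bq"][..., None])[..., None, :]
    )
    D = (3.0 * dA - rho[..., None, None] * dB) / B[..., None, None]
    D = np.where(c["degen"][..., None, None], np.nan, D)
    return rho, D


def batch_rho_avar(counts_or_probs: np.ndarray):
    """rho and the asymptotic variance factor avar = g' Sigma g, batched.

    Uses the shift-invariant identity
    ``g' Sigma g = sum_k D_k^2 h_k - (sum_k D_k h_k)^2`` over all cells,
    which equals the reduced-gradient quadratic form with
    Sigma = diag(h) - h h'.
    """
    t = np.asarray(counts_or_probs, dtype=float)
    rho, D = batch_grad_rho_full(t)
    total = t.sum(axis=(-2, -1), keepdims=True)
    h = t / total
    m1 = np.einsum("...ij,...ij->...", D, h)
    m2 = np.einsum("...ij,...ij->...", D**2, h)
    avar = m2 - m1**2
    return rho, np.maximum(avar, 0.0)
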