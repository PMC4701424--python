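"""Delta-method asymptotics for the discrete Spearman correlation.

The observed cell proportions of an I x J table are a scaled multinomial
with covariance ``Sigma = diag(h) - h h'`` (rank I*J - 1; full rank after
dropping one cell).  Since rho_s is a smooth function of the cell
probabilities, the delta method yields

    sqrt(n) (rho_hat - rho_s)  ->  N(0, grad_rho' Sigma grad_rho)

irrespective of dependence between the two variables — no independence or
continuity assumption is needed.  Inference plugs the observed proportions
into both the gradient and Sigma.

The parameter vector is the flattened table in row-major order with the
last cell h_IJ dropped (it is 1 minus the rest, and keeping it would make
Sigma singular).  Analytic gradients are derived by the chain rule through
the marginal CDFs; the test suite checks them against central finite
differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CountTable, ProbabilityTable, population_rho
from .errors import DegenerateMarginError, ValidationError

__all__ = [
    "FlatProbVector",
    "DeltaVariance",
    "TestResult",
    "RhoInference",
    "flatten",
    "unflatten",
    "multinomial_cov",
    "grad_A",
    "grad_B",
    "grad_rho",
    "asymptotic_variance",
    "z_test",
]


@dataclass(frozen=True)
class FlatProbVector:
    """Length-(IJ-1) free parameter vector of an I x J probability table.

    Row-major cell order with cell (I, J) removed; the removed cell is
    implied as one minus the sum and must be nonnegative.
    """

    hvec: np.ndarray
    I: int  # noqa: E741
    J: int

    def __post_init__(self):
        v = np.asarray(self.hvec, dtype=float)
        if v.shape != (self.I * self.J - 1,):
            raise ValidationError(
                f"expected length {self.I * self.J - 1} for a "
                f"{self.I}x{self.J} table, got {v.shape}"
            )
        if np.any(v < -1e-12):
            raise ValidationError("negative entry in flattened probabilities")
        if v.sum() > 1 + 1e-12:
            raise ValidationError(
                f"implied last cell is negative: 1 - sum = {1 - v.sum()!r}"
            )
        object.__setattr__(self, "hvec", v)
        self.hvec.setflags(write=False)

    @property
    def h_last(self) -> float:
        return max(1.0 - float(self.hvec.sum()), 0.0)


@dataclass(frozen=True)
class DeltaVariance:
    """Delta-method variance decomposition of the sample rho.

    ``avar`` is the asymptotic variance factor grad' Sigma grad; the
    finite-sample variance estimate is ``avar / n``.
    """

    gradient: np.ndarray
    sigma: np.ndarray
    avar: float
    n: int

    @property
    def variance(self) -> float:
        return self.avar / self.n


@dataclass(frozen=True)
class TestResult:
    """Two-sided z-test of H0: rho = rho_null with a symmetric normal CI."""

    rho_hat: float
    rho_null: float
    variance: float
    z: float
    p_value: float
    alpha: float
    reject: bool
    ci_low: float
    ci_high: float
    method: str = "asymptotic"


@dataclass(frozen=True)
class RhoInference:
    """Point estimate with one or more variance estimates and optional test."""

    rho: float
    n: int
    shape: tuple[int, int]
    variances: dict[str, float]
    cis: dict[str, tuple[float, float]]
    tests: dict[str, TestResult]

    def to_dict(self) -> dict:
        out: dict = {
            "rho": self.rho,
            "n": self.n,
            "table_shape": list(self.shape),
            "variances": {k: v for k, v in sorted(self.variances.items())},
            "ci": {k: list(v) for k, v in sorted(self.cis.items())},
        }
        out["tests"] = {
            m: {
                "rho": t.rho_hat,
                "null": t.rho_null,
                "variance": t.variance,
                "z": t.z,
                "p": t.p_value,
                "ci": [t.ci_low, t.ci_high],
                "alpha": t.alpha,
                "reject": bool(t.reject),
                "method": t.method,
            }
            for m, t in sorted(self.tests.items())
        }
        return out


def flatten(table: ProbabilityTable) -> FlatProbVector:
    """Drop cell (I, J) and flatten row-major."""
    return FlatProbVector(
        hvec=table.h.ravel()[:-1], I=table.I, J=table.J
    )


def unflatten(v: FlatProbVector) -> ProbabilityTable:
    """Reconstruct the table, implying the last cell as one minus the sum."""
    full = np.concatenate([v.hvec, [v.h_last]])
    return ProbabilityTable(full.reshape(v.I, v.J))


def multinomial_cov(v: FlatProbVector) -> np.ndarray:
    """Multinomial covariance ``diag(h) - h h'`` of the free cell vector."""
    h = v.hvec
    return np.diag(h) - np.outer(h, h)


def _check_margins(table: ProbabilityTable) -> None:
    p = table.h.sum(axis=1)
    q = table.h.sum(axis=0)
    if 1.0 - np.sum(p**3) <= 1e-12:
        raise DegenerateMarginError(
            "margin of X is degenerate; gradient undefined", margin="x"
        )
    if 1.0 - np.sum(q**3) <= 1e-12:
        raise DegenerateMarginError(
            "margin of Y is degenerate; gradient undefined", margin="y"
        )


def _reduced(full: np.ndarray) -> np.ndarray:
    """Reduce an unconstrained I*J gradient to the free IJ-1 coordinates.

    Eliminating h_IJ = 1 - sum makes d/dh_rs of the constrained function
    equal the unconstrained partial minus the partial w.r.t. the last cell.
    """
    return (full - full[-1, -1]).ravel()[:-1]


def _dA_full(h: np.ndarray) -> np.ndarray:
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    vF = 2.0 * np.cumsum(p) - p
    vG = 2.0 * np.cumsum(q) - q
    # suffix sums over strictly larger row/column index
    below = np.flipud(np.flipud(h).cumsum(axis=0))  # sum_{i >= r}
    below = np.vstack([below[1:], np.zeros((1, h.shape[1]))])  # sum_{i > r}
    right = np.fliplr(np.fliplr(h).cumsum(axis=1))
    right = np.hstack([right[:, 1:], np.zeros((h.shape[0], 1))])
    row = (h + 2.0 * below) @ vG  # length I
    col = vF @ (h + 2.0 * right)  # length J
    return np.outer(vF, vG) + row[:, None] + col[None, :]


def grad_A(table: ProbabilityTable) -> np.ndarray:
    """Gradient of the numerator term A w.r.t. the free cell vector."""
    return _reduced(_dA_full(table.h))


def grad_B(table: ProbabilityTable) -> np.ndarray:
    """Gradient of the denominator B = sqrt(bp*bq) w.r.t. the free cells.

    Entry (r, s) equals ``(3B/2) [ (p_I^2 - p_r^2)/bp + (q_J^2 - q_s^2)/bq ]``;
    it vanishes identically when both margins are uniform.
    """
    _check_margins(table)
    h = table.h
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    bp = 1.0 - np.sum(p**3)
    bq = 1.0 - np.sum(q**3)
    B = math.sqrt(bp * bq)
    full = -1.5 * B * ((p**2 / bp)[:, None] + (q**2 / bq)[None, :])
    return _reduced(full)


def grad_rho(table: ProbabilityTable) -> np.ndarray:
    """Analytic gradient of rho_s: ``(3 grad_A - rho grad_B) / B``."""
    _check_margins(table)
    h = table.h
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    B = math.sqrt((1.0 - np.sum(p**3)) * (1.0 - np.sum(q**3)))
    rho = population_rho(table)
    return (3.0 * grad_A(table) - rho * grad_B(table)) / B


def asymptotic_variance(
    table: CountTable | ProbabilityTable, n: int | None = None
) -> DeltaVariance:
    """Delta-method variance of the sample rho.

    Given a :class:`CountTable`, the gradient and covariance are evaluated
    at the observed proportions (plug-in) and ``n`` defaults to the total
    count.  Given a :class:`ProbabilityTable`, ``n`` must be supplied.
    """
    if isinstance(table, CountTable):
        if n is None:
            n = table.n
        prob = table.to_probability()
    else:
        prob = table
        if n is None:
            raise ValidationError(
                "n is required when computing the variance from probabilities"
            )
    if n < 1:
        raise ValidationError(f"sample size must be >= 1, got {n}")
    g = grad_rho(prob)
    sigma = multinomial_cov(flatten(prob))
    avar = float(g @ sigma @ g)
    return DeltaVariance(gradient=g, sigma=sigma, avar=max(avar, 0.0), n=int(n))


def z_test(
    rho_hat: float,
    rho_null: float,
    variance: float,
    alpha: float = 0.05,
    method: str = "asymptotic",
) -> TestResult:
    """Two-sided z-test of H0: rho = rho_null using a supplied variance.

    The confidence interval is the symmetric normal interval
    ``rho_hat +- z_{1-alpha/2} sqrt(variance)`` at level 1 - alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if variance <= 0.0:
        raise ValidationError(f"variance must be positive, got {variance}")
    se = math.sqrt(variance)
    z = (rho_hat - rho_null) / se
    p = 2.0 * stats.norm.sf(abs(z))
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return TestResult(
        rho_hat=float(rho_hat),
        rho_null=float(rho_null),
        variance=float(variance),
        z=float(z),
        p_value=float(min(p, 1.0)),
        alpha=float(alpha),
        reject=bool(p < alpha),
        ci_low=float(rho_hat - crit * se),
        ci_high=float(rho_hat + crit * se),
        method=method,
    )
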