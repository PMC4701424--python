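"""Bootstrap variance estimation and the classical independence comparator.

The empirical bootstrap resamples the n observed pairs with replacement and
recomputes the sample rho per resample.  Because the estimator depends on
the data only through the contingency table, resampling pairs is carried
out as a multinomial redraw of cell counts at the observed proportions —
distributionally identical to index resampling, much cheaper, and exactly
invariant to the order of the input pairs.

The "naive" comparator is the classical large-sample null variance of
Spearman's rho for continuous data under independence, 1/(n-1).  It ignores
ties and dependence by construction and is provided purely as the widely
(mis)used baseline to compare against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._batch import batch_rho
from .core import CountTable, PairedSample, table_from_pairs
from .errors import DegenerateMarginError, ValidationError

__all__ = ["BootstrapResult", "bootstrap_rho", "independence_approx_variance"]

DEFAULT_B = 1000


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap replicates of the sample rho and derived summaries.

    ``variance`` is the sample variance (ddof=1) of the replicates;
    ``ci_low``/``ci_high`` is the percentile interval.  Resamples in which
    a margin collapses to a single category have no defined rho; they are
    dropped and counted in ``n_degenerate``.
    """

    replicates: np.ndarray
    B: int
    variance: float
    ci_low: float
    ci_high: float
    n_degenerate: int
    seed: int | None
    alpha: float = 0.05


def bootstrap_rho(
    sample: PairedSample | CountTable,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Empirical bootstrap of the sample Spearman correlation.

    Parameters
    ----------
    sample
        Paired observations or their cross-tabulation; both carry the same
        information for the estimator.
    B
        Number of resamples (>= 2).
    seed
        Integer seed or an existing :class:`numpy.random.Generator`;
        a fixed integer makes the replicate vector bit-reproducible.
    alpha
        Level for the percentile interval.
    """
    if B < 2:
        raise ValidationError(f"need B >= 2 bootstrap resamples, got {B}")
    table = sample if isinstance(sample, CountTable) else table_from_pairs(sample)
    n = table.n
    if n < 2:
        raise ValidationError("need at least two pairs to bootstrap")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    phat = (table.counts / n).ravel()
    draws = rng.multinomial(n, phat, size=B).reshape(B, *table.shape)
    reps = batch_rho(draws)
    ok = ~np.isnan(reps)
    n_degen = int(B - ok.sum())
    reps = reps[ok]
    if len(reps) < 2:
        raise DegenerateMarginError(
            "all (or all but one) bootstrap resamples had a flat margin; "
            "bootstrap variance undefined",
            n=n,
        )
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapResult(
        replicates=reps,
        B=B,
        variance=float(np.var(reps, ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_degenerate=n_degen,
        seed=seed if isinstance(seed, int) else None,
        alpha=alpha,
    )


def independence_approx_variance(rho_hat: float, n: int) -> float:
    """Classical no-ties, independence-only variance approximation, 1/(n-1).

    This is the large-sample null variance of Spearman's rho for continuous
    data, the formula behind textbook z-tests (and common software
    defaults).  It does not depend on ``rho_hat``; the argument is kept so
    all variance estimators share a signature.  Valid only under
    independence and without ties — used here as a comparator, not as a
    recommended method.
    """
    if n < 3:
        raise ValidationError(f"need n >= 3, got {n}")
    return 1.0 / (n - 1)
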