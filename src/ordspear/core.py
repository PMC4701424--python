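"""Contingency-table data model and Spearman rank-correlation estimators.

For ordinal variables X in {1..I} and Y in {1..J} the joint distribution is
an I x J table of cell probabilities ``h[i, j] = P(X=i+1, Y=j+1)``.  The
population rank correlation of such a pair is a smooth function of the cell
probabilities:

    rho_s = 3 * (A - 1) / B

with

    A = sum_ij h_ij (F_i + F_{i-1}) (G_j + G_{j-1}),
    B = sqrt((1 - sum_i p_i^3) * (1 - sum_j q_j^3)),

where p, q are the marginal mass functions and F, G their CDFs (with the
convention F_0 = G_0 = 0).  Evaluated at the observed cell proportions this
coincides exactly with the classical sample Spearman correlation computed
from midranks, which is the identity that makes the plug-in estimator
meaningful and is enforced by the test suite.

Category codes are 1-based throughout, matching the usual presentation of
ordinal scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateMarginError, ValidationError

__all__ = [
    "ProbabilityTable",
    "Marginals",
    "CountTable",
    "PairedSample",
    "marginals",
    "population_rho",
    "sample_rho_from_counts",
    "sample_rho_from_ranks",
    "table_from_pairs",
    "expand_table",
]

_PROB_TOL = 1e-12
# sum(p^3) == 1 iff one category carries all mass; use a tolerance suited
# to accumulated rounding in the cubic sums
_DEGEN_TOL = 1e-12


@dataclass(frozen=True)
class ProbabilityTable:
    """Joint cell probabilities of a pair of ordinal variables.

    Parameters
    ----------
    h : ndarray of shape (I, J)
        Nonnegative cell probabilities summing to one.
    """

    h: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.h, dtype=float)
        if h.ndim != 2 or h.shape[0] < 2 or h.shape[1] < 2:
            raise ValidationError(
                f"probability table must be at least 2x2, got shape {h.shape}"
            )
        neg = np.argwhere(h < -_PROB_TOL)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative cell probability h[{i + 1},{j + 1}] = {h[i, j]!r}"
            )
        total = h.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"cell probabilities sum to {total!r}, not 1")
        h = np.clip(h, 0.0, None)
        h = h / h.sum()  # renormalize away the <=1e-9 slack
        object.__setattr__(self, "h", h)
        self.h.setflags(write=False)

    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return self.h.shape[0]

    @property
    def J(self) -> int:
        return self.h.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.h.shape


@dataclass(frozen=True)
class Marginals:
    """Marginal mass functions p, q and CDFs F, G with F[0] = G[0] = 0."""

    p: np.ndarray
    q: np.ndarray
    F: np.ndarray
    G: np.ndarray


@dataclass(frozen=True)
class CountTable:
    """Observed I x J table of nonnegative integer counts."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValidationError(
                f"count table must be at least 2x2, got shape {c.shape}"
            )
        if np.any(c < 0):
            i, j = np.argwhere(c < 0)[0]
            raise ValidationError(f"negative count at cell ({i + 1},{j + 1})")
        if not np.all(np.equal(np.mod(c, 1), 0)):
            i, j = np.argwhere(np.mod(c, 1) != 0)[0]
            raise ValidationError(f"non-integer count at cell ({i + 1},{j + 1})")
        c = c.astype(np.int64)
        if c.sum() < 1:
            raise ValidationError("count table is empty (total count 0)")
        object.__setattr__(self, "counts", c)
        self.counts.setflags(write=False)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_probability(self) -> ProbabilityTable:
        """Observed cell proportions as a :class:`ProbabilityTable`."""
        return ProbabilityTable(self.counts / self.n)


@dataclass(frozen=True)
class PairedSample:
    """n paired ordinal observations with declared supports.

    ``x[k]`` in {1..levels_x}, ``y[k]`` in {1..levels_y}.  Declared supports
    may exceed the observed maxima so that categories with zero observed
    mass are retained in downstream tables.
    """

    x: np.ndarray
    y: np.ndarray
    levels_x: int = field(default=0)
    levels_y: int = field(default=0)

    def __post_init__(self):
        x = np.asarray(self.x)
        y = np.asarray(self.y)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise ValidationError(
                f"x and y must be equal-length vectors, got {x.shape} and {y.shape}"
            )
        if len(x) == 0:
            raise ValidationError("empty sample")
        for name, v in (("x", x), ("y", y)):
            if not np.all(np.equal(np.mod(v, 1), 0)):
                raise ValidationError(f"non-integer category code in {name}")
        x = x.astype(np.int64)
        y = y.astype(np.int64)
        lx = self.levels_x or int(x.max())
        ly = self.levels_y or int(y.max())
        for name, v, lv in (("x", x, lx), ("y", y, ly)):
            bad = np.nonzero((v < 1) | (v > lv))[0]
            if bad.size:
                k = bad[0]
                raise ValidationError(
                    f"{name}[{k}] = {v[k]} outside declared support 1..{lv}"
                )
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "levels_x", lx)
        object.__setattr__(self, "levels_y", ly)
        self.x.setflags(write=False)
        self.y.setflags(write=False)

    @property
    def n(self) -> int:
        return len(self.x)


def marginals(table: ProbabilityTable) -> Marginals:
    """Marginal mass functions and CDFs of a probability table.

    The CDF vectors have length I+1 / J+1 with a leading explicit zero, so
    that ``F[i] - F[i-1] == p[i-1]`` holds index-for-index.
    """
    p = table.h.sum(axis=1)
    q = table.h.sum(axis=0)
    F = np.concatenate([[0.0], np.cumsum(p)])
    G = np.concatenate([[0.0], np.cumsum(q)])
    F[-1] = 1.0
    G[-1] = 1.0
    return Marginals(p=p, q=q, F=F, G=G)


def _rho_from_prob(h: np.ndarray) -> float:
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    bp = 1.0 - np.sum(p**3)
    bq = 1.0 - np.sum(q**3)
    if bp <= _DEGEN_TOL:
        raise DegenerateMarginError(
            "margin of X is degenerate (all mass in one category); "
            "rank correlation undefined",
            margin="x",
        )
    if bq <= _DEGEN_TOL:
        raise DegenerateMarginError(
            "margin of Y is degenerate (all mass in one category); "
            "rank correlation undefined",
            margin="y",
        )
    F = np.cumsum(p)
    G = np.cumsum(q)
    # F_i + F_{i-1} = 2 F_i - p_i, with F_0 = 0
    vF = 2.0 * F - p
    vG = 2.0 * G - q
    A = float(np.einsum("ij,i,j->", h, vF, vG))
    B = float(np.sqrt(bp * bq))
    rho = 3.0 * (A - 1.0) / B
    # guard tiny overshoot from rounding at the +-1 boundary
    return float(np.clip(rho, -1.0, 1.0))


def population_rho(table: ProbabilityTable) -> float:
    """Population Spearman rank correlation of an ordinal pair.

    Computed from the cell probabilities as ``3 (A - 1) / B`` (see module
    docstring).  Always in [-1, 1]; equals 0 for any independence table
    ``h = outer(p, q)`` and +-1 for comonotone/antitone tables with equal
    margins.

    Raises
    ------
    DegenerateMarginError
        If either margin puts all mass in a single category.
    """
    return _rho_from_prob(table.h)


def sample_rho_from_counts(counts: CountTable) -> float:
    """Sample Spearman correlation from an observed contingency table.

    Plug-in evaluation of :func:`population_rho` at the observed cell
    proportions; identical to the midrank sample correlation of the
    expanded paired data.
    """
    try:
        return _rho_from_prob(counts.counts / counts.n)
    except DegenerateMarginError as e:
        raise DegenerateMarginError(
            f"observed margin of {e.margin} has a single category "
            f"(n={counts.n}); sample rank correlation undefined",
            margin=e.margin,
            n=counts.n,
        ) from None


def sample_rho_from_ranks(sample: PairedSample) -> float:
    """Sample Spearman correlation of paired data via midranks.

    Pearson correlation of the rank vectors, tied observations receiving
    the mean of the rank positions they occupy.
    """
    if sample.n < 2:
        raise ValidationError("need at least two pairs to correlate")
    if np.all(sample.x == sample.x[0]):
        raise DegenerateMarginError(
            "all x values identical; rank correlation undefined",
            margin="x", n=sample.n,
        )
    if np.all(sample.y == sample.y[0]):
        raise DegenerateMarginError(
            "all y values identical; rank correlation undefined",
            margin="y", n=sample.n,
        )
    r = stats.rankdata(sample.x, method="average")
    s = stats.rankdata(sample.y, method="average")
    rc = r - r.mean()
    sc = s - s.mean()
    return float(np.dot(rc, sc) / np.sqrt(np.dot(rc, rc) * np.dot(sc, sc)))


def table_from_pairs(sample: PairedSample) -> CountTable:
    """Cross-tabulate a paired sample into a count table.

    Declared-but-unobserved categories are retained as zero rows/columns so
    the table shape always equals (levels_x, levels_y).
    """
    counts = np.zeros((sample.levels_x, sample.levels_y), dtype=np.int64)
    np.add.at(counts, (sample.x - 1, sample.y - 1), 1)
    return CountTable(counts)


def expand_table(counts: CountTable) -> PairedSample:
    """Expand a count table back into paired observations (row-major order)."""
    I, J = counts.shape
    flat = counts.counts.ravel()
    cells = np.repeat(np.arange(I * J), flat)
    return PairedSample(
        x=cells // J + 1, y=cells % J + 1, levels_x=I, levels_y=J
    )
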