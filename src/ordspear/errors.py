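"""Typed errors raised across the package.

Degenerate margins (all probability mass in a single category) make the
rank correlation undefined; pipelines should fail loudly rather than
propagate NaN, so that condition gets its own exception type.
"""


class OrdspearError(Exception):
    """Base class for all package errors."""


class ValidationError(OrdspearError, ValueError):
    """Malformed input: negative cells, probabilities not summing to one,
    codes outside the declared support, unknown config keys, ..."""


class DegenerateMarginError(OrdspearError, ValueError):
    """The rank correlation is undefined because a margin has no variation
    (sum of cubed marginal probabilities equals one).

    Attributes
    ----------
    margin : str
        Which margin is flat, ``"x"`` or ``"y"``.
    n : int or None
        Sample size, when the error arises from observed data.
    """

    def __init__(self, message: str, margin: str | None = None, n: int | None = None):
        super().__init__(message)
        self.margin = margin
        self.n = n
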