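"""Exception types used across the pipeline.

The distinction that matters downstream is between malformed input
(:class:`ValidationError`) and a product that is well-formed but outside the
quantitative scope — injectables and human medicines, whose doses cannot be
derived from label mixing instructions (:class:`ExcludedProductError`).
Callers catch the latter to tally excluded events rather than abort.
"""


class AmuQuantError(Exception):
    """Base class for package errors."""


class ValidationError(AmuQuantError):
    """Malformed or inconsistent input data."""


class ExcludedProductError(AmuQuantError):
    """Product is outside the quantifiable scope (injection / human medicine).

    Signals "excluded from quantification", not bad data: such events are
    counted and logged but contribute to no dose- or weight-based metric.
    """


class FittingError(AmuQuantError):
    """A statistical model could not be fitted (e.g. single-class outcome)."""
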