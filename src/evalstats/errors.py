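"""Typed error signals shared across the toolkit.

A ratio metric with a zero denominator is *undefined*, not zero: silently
returning 0 or 1 hides degenerate inputs (e.g. a test set with no positive
instances) and different ecosystems disagree on the convention. All metric
functions raise :class:`UndefinedMetricError` instead of picking a value.
"""

from __future__ import annotations


class EvalStatsError(Exception):
    """Base class for all toolkit errors."""


class InputError(EvalStatsError, ValueError):
    """Malformed or inconsistent input data (shape/length/value domain)."""


class UndefinedMetricError(EvalStatsError, ZeroDivisionError):
    """A metric is mathematically undefined for the given counts.

    Parameters
    ----------
    metric:
        Name of the metric that could not be evaluated.
    reason:
        Human-readable explanation (which denominator or variance vanished).
    context:
        Optional extra detail, e.g. the class index inside an aggregate.
    """

    def __init__(self, metric: str, reason: str, context: str | None = None):
        self.metric = metric
        self.reason = reason
        self.context = context
        msg = f"{metric} is undefined: {reason}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)
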