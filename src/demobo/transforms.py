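"""Observation transform for the log-scale surrogate."""

from __future__ import annotations

import numpy as np

__all__ = ["transform_for_logei"]


def transform_for_logei(y) -> tuple[np.ndarray, float]:
    """Log-transform observations, shifting first if any are non-positive.

    Negative log-likelihoods are usually positive, in which case the log is
    taken directly (shift 0). Otherwise the values are shifted so the
    minimum becomes exactly 1, keeping the log well-defined and the
    incumbent scale stable. Returns ``(log(y + shift), shift)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 1:
        raise ValueError("need at least one observation")
    ymin = float(np.min(y))
    shift = 0.0 if ymin > 0 else 1.0 - ymin
    return np.log(y + shift), shift
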