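"""Evaluation metrics for methylation-level agreement."""

from __future__ import annotations

import logging
import math

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["mae", "pearson_r"]


def mae(true_levels, predicted_levels) -> float:
    """Mean absolute error, sum |m_i - m_i'| / N."""
    m = np.asarray(true_levels, dtype=np.float64)
    mp = np.asarray(predicted_levels, dtype=np.float64)
    if m.shape != mp.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {mp.shape}")
    if m.size == 0:
        raise ValueError("need at least one pair of levels")
    return float(np.mean(np.abs(m - mp)))


def pearson_r(true_levels, predicted_levels) -> float:
    """Pearson correlation with sample (n-1) standard deviations.

    r = sum (m_i - mbar)(m_i' - mbar') / ((n - 1) * sigma_m * sigma_m').
    A constant vector makes the correlation undefined; nan is returned with
    a logged note so reporting code can exclude it.
    """
    m = np.asarray(true_levels, dtype=np.float64)
    mp = np.asarray(predicted_levels, dtype=np.float64)
    if m.shape != mp.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {mp.shape}")
    n = m.size
    if n < 2:
        raise ValueError("need at least two pairs of levels")
    if np.ptp(m) == 0.0 or np.ptp(mp) == 0.0:
        logger.info("constant level vector: correlation undefined")
        return math.nan
    sm = m.std(ddof=1)
    smp = mp.std(ddof=1)
    cov = float(np.sum((m - m.mean()) * (mp - mp.mean())))
    return cov / ((n - 1) * sm * smp)
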