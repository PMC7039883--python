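"""Plate quality control: the Z' factor.

Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|, with sample
(n-1) standard deviations. Z' is at most 1, equals 1 only when both
arms have zero spread, and is undefined (typed, not -inf) when the arm
means coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ZPrimeResult:
    """Z' factor of one plate; ``defined`` is False when means coincide."""

    value: float | None
    defined: bool
    mean_pos: float
    mean_neg: float
    sd_pos: float
    sd_neg: float


def zprime(positive: list[float], negative: list[float]) -> ZPrimeResult:
    """Compute the Z' factor from positive- and negative-control values."""
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("zprime needs at least 2 values per control arm")
    mean_pos, mean_neg = float(pos.mean()), float(neg.mean())
    sd_pos = float(pos.std(ddof=1))
    sd_neg = float(neg.std(ddof=1))
    if mean_pos == mean_neg:
        return ZPrimeResult(None, False, mean_pos, mean_neg, sd_pos, sd_neg)
    value = 1.0 - 3.0 * (sd_pos + sd_neg) / abs(mean_pos - mean_neg)
    return ZPrimeResult(value, True, mean_pos, mean_neg, sd_pos, sd_neg)
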