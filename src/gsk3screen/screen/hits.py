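"""Banded hit calling with a toxicity counter-screen.

Compounds are banded by their mean normalized percent p-CRMP2/MAP2:
strong (GSK3-inhibitor-like) below 80, candidate in [80, 90), inactive
otherwise. A compound whose MAP2-positive neuron count falls below the
toxicity floor (default half the reference count) is called toxic
regardless of its activity band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BANDS = ("strong", "candidate", "inactive", "toxic")


@dataclass
class BandConfig:
    """Hit-band edges (percent of reference) and the toxicity floor."""

    strong_below: float = 80.0
    candidate_below: float = 90.0
    toxicity_floor: float = 0.5

    def __post_init__(self) -> None:
        if not self.strong_below < self.candidate_below:
            raise ValueError(
                "band edges must be strictly increasing: strong_below "
                f"{self.strong_below} !< candidate_below {self.candidate_below}"
            )


@dataclass
class HitCall:
    """One compound's screen outcome."""

    compound: str
    mean_percent: float
    sd_percent: float
    n_replicates: int
    neuron_count_ratio: float
    band: str


def call_hits(
    normalized: dict[str, list[float]],
    count_ratios: dict[str, float],
    bands: BandConfig | None = None,
) -> list[HitCall]:
    """Band every compound; toxicity overrides activity.

    ``normalized`` maps compound -> replicate normalized percents;
    ``count_ratios`` maps compound -> MAP2-positive neuron count relative
    to the reference wells.
    """
    bands = bands or BandConfig()
    calls = []
    for compound in sorted(normalized):
        values = [v for v in normalized[compound] if v is not None]
        ratio = count_ratios.get(compound, 1.0)
        if not values:
            # a readout can only be undefined when no neurons survived
            if ratio < bands.toxicity_floor:
                calls.append(
                    HitCall(compound, float("nan"), 0.0, 0, ratio, "toxic")
                )
                continue
            raise ValueError(f"compound {compound!r} has no replicate values")
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        if ratio < bands.toxicity_floor:
            band = "toxic"
        elif mean < bands.strong_below:
            band = "strong"
        elif mean < bands.candidate_below:
            band = "candidate"
        else:
            band = "inactive"
        calls.append(
            HitCall(
                compound=compound,
                mean_percent=mean,
                sd_percent=sd,
                n_replicates=len(values),
                neuron_count_ratio=ratio,
                band=band,
            )
        )
    return calls
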