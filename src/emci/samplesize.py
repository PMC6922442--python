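"""A-posteriori Bonferroni sample-size calculation.

Of the three simultaneous-CI methods only Bonferroni's correction admits
an explicit sample-size formula: a Bonferroni interval at family level
alpha_S over p quantities has half-width z_{1-alpha_S/(2p)} * s / sqrt(n),
so the n needed for a maximal margin of error E over all quantities is

    n = ceil( ( z_{1-alpha_S/(2p)} * max_j s_j / E )^2 ).

The calculation is a-posteriori: the standard deviations s_j are estimated
from the sample already in hand (per-variable SDs, or per-comparison
difference SDs sqrt(s_A^2 + s_B^2) when the margins target mean
differences under equal per-case n). The normal quantile is used rather
than t because n is the unknown; at the resulting n the difference is nil.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import ValidationError

logger = logging.getLogger("emci")


@dataclass(frozen=True)
class SampleSizeRequest:
    """Target margin, family level, SD estimates and family size."""

    margin_E: float
    alpha_s: float
    sds: np.ndarray
    p_or_q: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        if self.margin_E <= 0:
            raise ValidationError("margin_E must be positive")
        if not 0.0 < self.alpha_s < 1.0:
            raise ValidationError("alpha_s must lie in (0, 1)")
        if self.sds.ndim != 1 or self.sds.size == 0:
            raise ValidationError("sds must be a nonempty vector")
        if np.any(self.sds < 0):
            raise ValidationError("sds must be nonnegative")
        if self.p_or_q < 1:
            raise ValidationError("p_or_q must be positive")


def bonferroni_sample_size(req: SampleSizeRequest) -> int:
    """Smallest n whose Bonferroni maximal margin of error is <= E."""
    max_sd = float(req.sds.max())
    if max_sd == 0.0:
        logger.warning("all SDs are zero; any n achieves the margin, returning 1")
        return 1
    z = stats.norm.ppf(1.0 - req.alpha_s / (2.0 * req.p_or_q))
    return int(math.ceil((z * max_sd / req.margin_E) ** 2))


def difference_sds(sds_a: np.ndarray, sds_b: np.ndarray) -> np.ndarray:
    """Per-comparison SD sqrt(s_A^2 + s_B^2) under equal per-case n."""
    sds_a = np.asarray(sds_a, float)
    sds_b = np.asarray(sds_b, float)
    if sds_a.shape != sds_b.shape:
        raise ValidationError("SD vectors must align")
    return np.sqrt(sds_a**2 + sds_b**2)
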