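"""Data preparation: variance filtering and ranking by absolute mean.

Ensembles of control coefficients routinely contain variables that are
numerically constant (reactions with no control on the target flux); these
carry zero information and break correlation estimation, so they are
dropped before any interval construction. Sample standard deviations use
the n-1 denominator throughout the package.
"""

from __future__ import annotations

import logging

import numpy as np

from .core_io import Ensemble, ValidationError

logger = logging.getLogger("emci")

#: Default standard-deviation tolerance below which a variable is dropped.
DEFAULT_SD_TOL = 1e-9


def filter_low_variance(
    ensemble: Ensemble, tol: float = DEFAULT_SD_TOL
) -> tuple[Ensemble, list[str]]:
    """Drop variables whose sample SD falls below ``tol``.

    Returns the filtered ensemble (original column order preserved) and
    the list of removed variable names.
    """
    if tol < 0:
        raise ValidationError("tolerance must be nonnegative")
    sds = ensemble.values.std(axis=0, ddof=1)
    keep = sds >= tol
    removed = [name for name, k in zip(ensemble.variable_names, keep) if not k]
    if not keep.any():
        raise ValidationError(
            f"all {ensemble.p} variables have SD < {tol}; nothing to analyze"
        )
    if removed:
        logger.info(
            "filtered %d/%d variables with SD < %g", len(removed), ensemble.p, tol
        )
        kept_names = tuple(
            name for name, k in zip(ensemble.variable_names, keep) if k
        )
        ensemble = Ensemble(
            ensemble.values[:, keep], kept_names, ensemble.case_label
        )
    return ensemble, removed


def rank_by_abs_mean(ensemble: Ensemble) -> list[str]:
    """Variable names sorted by decreasing absolute sample mean.

    Ties keep the original column order (stable sort).
    """
    means = ensemble.values.mean(axis=0)
    order = np.argsort(-np.abs(means), kind="stable")
    return [ensemble.variable_names[j] for j in order]
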