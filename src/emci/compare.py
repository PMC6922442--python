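"""Multi-case comparisons of ensemble means with global simultaneity.

Two cases are compared, variable by variable, through the difference of
their sample means d = mean_A - mean_B with standard error
sqrt(s_A^2/n_A + s_B^2/n_B). With k cases and v selected variables the
family holds q_total = C(k, 2) * v estimates, and the correction is global
over all of them — never per pair — so that with probability 1 - alpha_S
every true mean difference lies in its interval at once.

Four calibrations of the common critical value are provided:

* ``univariate``    — z at alpha_S per difference, no correction (baseline
                      for how over-eager uncorrected testing is);
* ``bonferroni``    — z at alpha_S / q_total;
* ``exact_normal``  — equicoordinate quantile of the q_total-dimensional
                      normal whose covariance is assembled from per-case
                      sample covariances; comparisons sharing a case are
                      correlated through that case's block
                      (Cov(d^AB, d^AC) = Sigma_A / n_A, sign-adjusted for
                      pair orientation);
* ``bootstrap``     — every case resampled independently per replicate,
                      all q_total differences recomputed, then the
                      balanced max-rank construction applied in the
                      q_total-dimensional difference space.

Difference intervals use normal (z) quantiles rather than Welch-t: at
ensemble sizes in the thousands the distinction is immaterial and the
exact-normal construction is normal-based, so the four methods stay on a
common convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap_ci import DEFAULT_B, _balanced_bounds
from .core_io import CISet, Ensemble, METHODS, ValidationError
from .parametric_ci import CorrelationMatrix, exact_normal_quantile

logger = logging.getLogger("emci")


@dataclass(frozen=True)
class Comparison:
    """One case-pair x variable mean-difference interval."""

    case_a: str
    case_b: str
    variable: str
    diff_mean: float
    lower: float
    upper: float
    significant: bool


@dataclass(frozen=True)
class ComparisonSet:
    """All pairwise mean-difference CIs under one global correction."""

    comparisons: tuple[Comparison, ...]
    method: str
    simultaneous_level: float
    q_total: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "comparisons", tuple(self.comparisons))
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.q_total != len(self.comparisons):
            raise ValidationError("q_total must equal the number of comparisons")

    @property
    def n_significant(self) -> int:
        return sum(c.significant for c in self.comparisons)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_a": [c.case_a for c in self.comparisons],
                "case_b": [c.case_b for c in self.comparisons],
                "variable": [c.variable for c in self.comparisons],
                "diff": [c.diff_mean for c in self.comparisons],
                "lower": [c.lower for c in self.comparisons],
                "upper": [c.upper for c in self.comparisons],
                "significant": [c.significant for c in self.comparisons],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Preselection
# ---------------------------------------------------------------------------


def preselect_top_variables(
    cisets_per_case: Sequence[CISet], k: int = 7
) -> list[str]:
    """Union of each case's top-k significant variables by absolute mean.

    Per case, keep the k variables of largest |mean| among those whose
    interval excludes zero (fewer if fewer are significant); the union
    across cases is returned sorted by name for determinism.
    """
    if k < 1:
        raise ValidationError("k must be positive")
    selected: set[str] = set()
    for ciset in cisets_per_case:
        flags = ciset.significance().significant
        sig = [
            (abs(m), name)
            for name, m, f in zip(ciset.variable_names, ciset.means, flags)
            if f
        ]
        sig.sort(key=lambda t: -t[0])
        selected.update(name for _, name in sig[:k])
    if not selected:
        logger.warning("no significant variables in any case; empty selection")
    return sorted(selected)


# ---------------------------------------------------------------------------
# Difference statistics
# ---------------------------------------------------------------------------


def pairwise_differences(
    ensembles: Sequence[Ensemble], variables: Sequence[str]
) -> pd.DataFrame:
    """Mean differences and standard errors for every unordered case pair.

    Rows are ordered pair-major (pairs in combination order, variables in
    the order given), matching the layout of the comparison methods.
    """
    if len(ensembles) < 2:
        raise ValidationError("need at least two cases to compare")
    variables = list(variables)
    if not variables:
        raise ValidationError("no variables selected for comparison")
    labels = [e.case_label for e in ensembles]
    if len(set(labels)) != len(labels):
        raise ValidationError("case labels must be unique")
    sub = [e.select(variables) for e in ensembles]
    rows = []
    for ia, ib in combinations(range(len(sub)), 2):
        a, b = sub[ia], sub[ib]
        d = a.values.mean(axis=0) - b.values.mean(axis=0)
        se = np.sqrt(
            a.values.var(axis=0, ddof=1) / a.n + b.values.var(axis=0, ddof=1) / b.n
        )
        for j, name in enumerate(variables):
            rows.append(
                {
                    "case_a": labels[ia],
                    "case_b": labels[ib],
                    "variable": name,
                    "diff": d[j],
                    "se": se[j],
                }
            )
    return pd.DataFrame(rows)


def _difference_covariance(
    sub: Sequence[Ensemble], pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Covariance of the stacked difference-of-means vector.

    Block (pair1, pair2) is sum over shared cases of +/- Sigma_case/n_case:
    a case contributes with sign +1 when it sits on the same side (first or
    second) of both pairs and -1 when on opposite sides.
    """
    v = sub[0].p
    covs = [np.cov(e.values, rowvar=False).reshape(v, v) / e.n for e in sub]
    q = len(pairs) * v
    out = np.zeros((q, q))
    for i, (a1, b1) in enumerate(pairs):
        for j, (a2, b2) in enumerate(pairs):
            block = np.zeros((v, v))
            for case, sign in (
                (a1 if a1 == a2 else None, +1.0),
                (a1 if a1 == b2 else None, -1.0),
                (b1 if b1 == a2 else None, -1.0),
                (b1 if b1 == b2 else None, +1.0),
            ):
                if case is not None:
                    block += sign * covs[case]
            out[i * v : (i + 1) * v, j * v : (j + 1) * v] = block
    return out


def compare_cases(
    ensembles: Sequence[Ensemble],
    variables: Sequence[str],
    method: str = "bootstrap",
    alpha_s: float = 0.05,
    B: int = DEFAULT_B,
    M: int = 100_000,
    seed: int | np.random.Generator = 0,
    cross_case_correlation: bool = True,
) -> ComparisonSet:
    """Globally corrected mean-difference CIs for all case pairs.

    ``cross_case_correlation`` controls whether the exact-normal
    calibration models the correlation between comparisons that share a
    case (default) or treats pairs as uncorrelated blocks.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    if not 0.0 < alpha_s < 1.0:
        raise ValidationError("alpha_s must lie in (0, 1)")
    stats_df = pairwise_differences(ensembles, variables)
    variables = list(variables)
    v = len(variables)
    pairs = list(combinations(range(len(ensembles)), 2))
    q_total = len(pairs) * v
    if q_total == 0:
        raise ValidationError("no comparisons to make")
    diffs = stats_df["diff"].to_numpy()
    ses = stats_df["se"].to_numpy()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    meta: dict = {"alpha_s": alpha_s, "q_total": q_total}

    if method == "univariate":
        z = stats.norm.ppf(1.0 - alpha_s / 2.0)
        lower, upper = diffs - z * ses, diffs + z * ses
        level = 1.0 - alpha_s
    elif method == "bonferroni":
        z = stats.norm.ppf(1.0 - alpha_s / (2.0 * q_total))
        lower, upper = diffs - z * ses, diffs + z * ses
        level = 1.0 - alpha_s
        meta["alpha_per_comparison"] = alpha_s / q_total
    elif method == "exact_normal":
        sub = [e.select(variables) for e in ensembles]
        if cross_case_correlation:
            cov = _difference_covariance(sub, pairs)
        else:
            cov = np.zeros((q_total, q_total))
            v_covs = [np.cov(e.values, rowvar=False).reshape(v, v) / e.n for e in sub]
            for i, (a, b) in enumerate(pairs):
                cov[i * v : (i + 1) * v, i * v : (i + 1) * v] = (
                    v_covs[a] + v_covs[b]
                )
        sd = np.sqrt(np.diag(cov))
        if np.any(sd == 0.0):
            raise ValidationError("zero-variance difference; filter variables first")
        corr = CorrelationMatrix(cov / np.outer(sd, sd))
        c = exact_normal_quantile(corr, alpha_s, M, rng)
        lower, upper = diffs - c * ses, diffs + c * ses
        level = 1.0 - alpha_s
        meta.update({"M": M, "quantile": c, "cross_case": cross_case_correlation})
    else:  # bootstrap
        if B < 200:
            raise ValidationError("need at least B = 200 bootstrap replicates")
        sub = [e.select(variables) for e in ensembles]
        boot_means = []
        for e in sub:
            idx = rng.integers(0, e.n, size=(B, e.n))
            boot_means.append(e.values[idx].mean(axis=1))  # B x v
        samples = np.concatenate(
            [boot_means[a] - boot_means[b] for a, b in pairs], axis=1
        )  # B x q_total
        lower, upper, qq = _balanced_bounds(samples, alpha_s)
        level = 1.0 - alpha_s
        meta.update({"B": B, "q": qq})

    comps = []
    for r, (lo, hi) in zip(stats_df.itertuples(index=False), zip(lower, upper)):
        comps.append(
            Comparison(
                r.case_a,
                r.case_b,
                r.variable,
                float(r.diff),
                float(lo),
                float(hi),
                bool(lo > 0.0 or hi < 0.0),
            )
        )
    return ComparisonSet(tuple(comps), method, level, q_total, meta)
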