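"""Domain containers and delimited-text I/O.

The package operates on *ensembles*: n x p matrices whose rows are
observations (e.g. sampled kinetic models) and whose columns are the
variables of interest (e.g. flux control coefficients of one target flux).
Ensembles travel as TSV/CSV with a header of variable names; confidence
intervals travel as TSV tables with one row per variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("emci")

#: Methods understood throughout the package.
METHODS = ("univariate", "bonferroni", "exact_normal", "bootstrap")

#: Number of significant digits preserved by the text writers.
_WRITE_DIGITS = 17


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ensemble:
    """An n x p matrix of model outputs with named columns.

    Parameters
    ----------
    values
        Real matrix, shape (n, p); rows are observations/models, columns
        are variables.
    variable_names
        Unique identifiers, length p.
    case_label
        Free-text label of the case (e.g. an operational configuration).
    """

    values: np.ndarray
    variable_names: tuple[str, ...]
    case_label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "variable_names", tuple(self.variable_names))
        if values.ndim != 2:
            raise ValidationError("ensemble values must be a 2-D matrix")
        n, p = values.shape
        if n < 2:
            raise ValidationError(f"an ensemble needs n >= 2 observations, got n={n}")
        if p < 1:
            raise ValidationError("an ensemble needs at least one variable")
        if len(self.variable_names) != p:
            raise ValidationError(
                f"{len(self.variable_names)} variable names for {p} columns"
            )
        if len(set(self.variable_names)) != p:
            raise ValidationError("variable names must be unique")
        if not np.all(np.isfinite(values)):
            raise ValidationError("ensemble entries must all be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        """Return one variable's observations by name."""
        try:
            j = self.variable_names.index(name)
        except ValueError:
            raise KeyError(f"variable {name!r} not in ensemble") from None
        return self.values[:, j]

    def select(self, names: Sequence[str]) -> "Ensemble":
        """Project onto a subset of variables, in the order given."""
        idx = []
        for name in names:
            if name not in self.variable_names:
                raise ValidationError(
                    f"variable {name!r} missing from case {self.case_label!r}"
                )
            idx.append(self.variable_names.index(name))
        return Ensemble(self.values[:, idx], tuple(names), self.case_label)


@dataclass(frozen=True)
class CISet:
    """Per-variable simultaneous confidence intervals for the mean.

    ``simultaneous_level`` is the family-wise coverage 1 - alpha_S; the
    ``per_variable_level`` is the marginal coverage 1 - alpha of each
    individual interval (for corrected methods 1 - alpha > 1 - alpha_S).
    """

    variable_names: tuple[str, ...]
    means: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    method: str
    simultaneous_level: float
    per_variable_level: float
    n_used: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variable_names", tuple(self.variable_names))
        for attr in ("means", "lower", "upper"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), float))
        p = len(self.variable_names)
        if not (self.means.shape == self.lower.shape == self.upper.shape == (p,)):
            raise ValidationError("means/lower/upper must align with variable_names")
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if not 0.0 < self.simultaneous_level < 1.0:
            raise ValidationError("simultaneous_level must lie in (0, 1)")
        if np.any(self.lower > self.upper):
            raise ValidationError("lower bound exceeds upper bound")
        if self.method != "bootstrap" and (
            np.any(self.lower > self.means + 1e-12)
            or np.any(self.upper < self.means - 1e-12)
        ):
            raise ValidationError("symmetric CI must bracket the mean")

    @property
    def p(self) -> int:
        return len(self.variable_names)

    @property
    def half_widths(self) -> np.ndarray:
        return (self.upper - self.lower) / 2.0

    def significance(self) -> "SignificanceFlags":
        """Flag the variables whose interval excludes zero."""
        flags = (self.lower > 0.0) | (self.upper < 0.0)
        return SignificanceFlags(self.variable_names, flags)


@dataclass(frozen=True)
class SignificanceFlags:
    """Boolean per-variable flags: True when the CI excludes zero."""

    variable_names: tuple[str, ...]
    significant: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "variable_names", tuple(self.variable_names))
        object.__setattr__(
            self, "significant", np.asarray(self.significant, dtype=bool)
        )
        if self.significant.shape != (len(self.variable_names),):
            raise ValidationError("flags must align with variable_names")


@dataclass
class RunConfig:
    """Run-level settings: coverage level, method, replication, seed.

    The seed fully determines every stochastic output (Monte Carlo
    quantile draws, bootstrap resampling, synthetic generators).
    """

    alpha_s: float = 0.05
    method: str = "bonferroni"
    bootstrap_B: int = 2000
    mc_draws_M: int = 100_000
    seed: int = 0
    sd_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_s < 1.0:
            raise ValidationError("alpha_s must lie in (0, 1)")
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.bootstrap_B < 1 or self.mc_draws_M < 1:
            raise ValidationError("replicate counts must be positive")
        if self.sd_tolerance < 0:
            raise ValidationError("sd_tolerance must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_ensemble(
    path: str | Path, delimiter: str = "\t", case_label: str | None = None
) -> Ensemble:
    """Read an ensemble matrix from a delimited text file.

    The first row is the header of variable names; every body cell must be
    a finite number (missing values are rejected, not imputed).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n")
    names = header.split(delimiter)
    if len(set(names)) != len(names):
        raise ValidationError(f"{path}: duplicate header names")
    df = pd.read_csv(path, sep=delimiter, header=None, names=names, skiprows=1,
                     dtype=str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        values, bad = None, None
        for j, col in enumerate(df.columns):
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    bad = (i + 2, j + 1, cell)  # +2: header row + 1-based
                    break
            if bad:
                break
        raise ValidationError(
            f"{path}: non-numeric cell {bad[2]!r} at row {bad[0]}, column {bad[1]}"
        ) from None
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"{path}: non-finite value at row {i + 2}, column {j + 1}"
        )
    if values.shape[0] < 2:
        raise ValidationError(f"{path}: need at least 2 observation rows")
    label = case_label if case_label is not None else path.stem
    return Ensemble(values, tuple(names), label)


def write_ensemble(ensemble: Ensemble, path: str | Path, delimiter: str = "\t") -> None:
    """Write an ensemble as delimited text (header row then numeric body)."""
    df = pd.DataFrame(ensemble.values, columns=list(ensemble.variable_names))
    df.to_csv(path, sep=delimiter, index=False, float_format=f"%.{_WRITE_DIGITS}g")


def write_ci_table(
    ciset: CISet, flags: SignificanceFlags, path: str | Path
) -> None:
    """Write a CI table: variable, mean, lower, upper, significant, ...

    One row per variable, tab-separated, deterministic column order.
    """
    if ciset.variable_names != flags.variable_names:
        raise ValidationError("CISet and SignificanceFlags name mismatch")
    if ciset.p == 0:
        logger.warning("writing empty CI table (no variables) to %s", path)
    df = pd.DataFrame(
        {
            "variable": list(ciset.variable_names),
            "mean": ciset.means,
            "lower": ciset.lower,
            "upper": ciset.upper,
            "significant": flags.significant,
            "method": ciset.method,
            "simultaneous_level": ciset.simultaneous_level,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{_WRITE_DIGITS}g")


def read_ci_table(path: str | Path) -> pd.DataFrame:
    """Read back a CI table written by :func:`write_ci_table`."""
    return pd.read_csv(path, sep="\t")
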