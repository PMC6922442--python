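"""Known-truth generators and the coverage-experiment harness.

Three generators back the package's validation story:

* **Toy metabolic-control ensembles.** A linear reaction chain at steady
  state, with scaled elasticities drawn at random, yields flux control
  coefficients (FCCs) through the standard control-matrix identity
  ``C = I - E (N Dv E)^{-1} N Dv``. The resulting FCC ensembles carry the
  features that make real ensemble-modeling outputs statistically awkward
  — skewed, heavy-tailed, mutually correlated marginals constrained by the
  summation theorem (each row of C sums to one) and the connectivity
  theorem (C E = 0), both of which hold as exact algebraic identities and
  therefore serve as oracles for every generated sample.
* **Gaussian-copula ensembles.** A latent multivariate normal with a
  prescribed correlation is pushed through per-variable marginal
  transforms (normal, shifted lognormal, shifted gamma) and rescaled so
  each variable has an exactly known population mean and SD — the ground
  truth that coverage experiments require.
* **The coverage harness** repeats dataset generation + CI construction
  and reports simultaneous coverage, per-variable marginal coverages, and
  left/right miss rates (the quantities the CI contracts promise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .bootstrap_ci import DEFAULT_B, balanced_simultaneous_ci
from .core_io import CISet, Ensemble, METHODS, ValidationError
from .parametric_ci import bonferroni_ci, exact_normal_ci, univariate_ci

logger = logging.getLogger("emci")

#: Condition-number ceiling above which an elasticity draw is rejected
#: (mirrors keeping only numerically stable kinetic models).
CONDITION_LIMIT = 1e8

MARGINAL_FAMILIES = ("normal", "lognormal_shifted", "gamma_shifted")


# ---------------------------------------------------------------------------
# Toy network and MCA machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyNetwork:
    """A small metabolic network at steady state.

    ``stoichiometry`` is m x r (m internal metabolites, r reactions) with
    full row rank; ``reference_flux`` is a steady-state flux vector, i.e.
    stoichiometry @ reference_flux = 0.
    """

    stoichiometry: np.ndarray
    reference_flux: np.ndarray
    reaction_names: tuple[str, ...]
    metabolite_names: tuple[str, ...]

    def __post_init__(self) -> None:
        N = np.asarray(self.stoichiometry, dtype=float)
        v = np.asarray(self.reference_flux, dtype=float)
        object.__setattr__(self, "stoichiometry", N)
        object.__setattr__(self, "reference_flux", v)
        object.__setattr__(self, "reaction_names", tuple(self.reaction_names))
        object.__setattr__(self, "metabolite_names", tuple(self.metabolite_names))
        m, r = N.shape
        if v.shape != (r,) or np.any(v == 0.0):
            raise ValidationError("reference_flux must be a nonzero r-vector")
        if len(self.reaction_names) != r or len(self.metabolite_names) != m:
            raise ValidationError("name lists must match the stoichiometry shape")
        if np.linalg.matrix_rank(N) != m:
            raise ValidationError("stoichiometry must have full row rank")
        if not np.allclose(N @ v, 0.0, atol=1e-10):
            raise ValidationError("reference_flux is not a steady state")

    @property
    def m(self) -> int:
        return self.stoichiometry.shape[0]

    @property
    def r(self) -> int:
        return self.stoichiometry.shape[1]

    def participation(self) -> np.ndarray:
        """Boolean r x m pattern: metabolite i participates in reaction j."""
        return (self.stoichiometry != 0.0).T


@dataclass(frozen=True)
class ElasticitySample:
    """Scaled elasticities (log-log rate sensitivities), r x m.

    Nonzero only where a metabolite participates in the reaction;
    substrates get elasticities in (0, 1], products in [-1, 0).
    """

    elasticity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "elasticity", np.asarray(self.elasticity, dtype=float)
        )


@dataclass(frozen=True)
class FCCMatrix:
    """Flux control coefficients: row = controlled flux, column = enzyme."""

    values: np.ndarray


def build_linear_pathway(r: int) -> ToyNetwork:
    """Unbranched chain of r reactions through r-1 internal metabolites.

    Reaction j consumes metabolite j-1 and produces metabolite j (boundary
    species omitted); the reference flux is one through every step.
    """
    if r < 2:
        raise ValidationError("a pathway needs at least 2 reactions")
    m = r - 1
    N = np.zeros((m, r))
    for i in range(m):
        N[i, i] = 1.0  # produced by reaction i
        N[i, i + 1] = -1.0  # consumed by reaction i+1
    return ToyNetwork(
        N,
        np.ones(r),
        tuple(f"R{j + 1}" for j in range(r)),
        tuple(f"M{i + 1}" for i in range(m)),
    )


def sample_elasticities(
    net: ToyNetwork, seed: int | np.random.Generator = 0
) -> ElasticitySample:
    """Draw one elasticity matrix uniformly on the participation pattern.

    Substrate elasticities (metabolite consumed by the reaction) are drawn
    in (0, 1); product elasticities (metabolite produced) in (-1, 0).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    E = np.zeros((net.r, net.m))
    NT = net.stoichiometry.T  # r x m
    consumed = NT < 0  # reaction consumes metabolite -> substrate
    produced = NT > 0
    E[consumed] = 1.0 - rng.uniform(size=int(consumed.sum()))  # in (0, 1]
    E[produced] = -rng.uniform(size=int(produced.sum()))
    return ElasticitySample(E)


def compute_fcc(net: ToyNetwork, e: ElasticitySample) -> FCCMatrix:
    """Flux control coefficients from the control-matrix identity.

    With N the stoichiometry, Dv = diag(reference flux) and E the scaled
    elasticities, C = I - E (N Dv E)^{-1} N Dv. Steady state (N v = 0)
    makes the rows of C sum to one (summation theorem) and C E = 0
    (connectivity theorem) exact identities; draws for which N Dv E is
    ill-conditioned are rejected so both hold to tight tolerance.
    """
    N, v, E = net.stoichiometry, net.reference_flux, e.elasticity
    NDv = N * v  # N @ diag(v)
    jac = NDv @ E  # m x m
    if not np.all(np.isfinite(jac)):
        raise ValidationError("non-finite elasticities")
    cond = np.linalg.cond(jac)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise ArithmeticError(
            f"ill-conditioned system (cond={cond:.3g}); redraw elasticities"
        )
    C = np.eye(net.r) - E @ np.linalg.solve(jac, NDv)
    return FCCMatrix(C)


def generate_fcc_ensemble(
    net: ToyNetwork,
    target_reaction: int = 0,
    n_models: int = 5000,
    seed: int | np.random.Generator = 0,
) -> Ensemble:
    """Ensemble of one flux's control coefficients over sampled models.

    Each row is the ``target_reaction`` row of the FCC matrix for an
    independently drawn elasticity sample; ill-conditioned draws are
    rejected and redrawn (the rejection count is logged). Aborts if the
    acceptance rate drops below 1%.
    """
    if n_models < 2:
        raise ValidationError("need at least 2 models")
    if not 0 <= target_reaction < net.r:
        raise ValidationError("target_reaction out of range")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = np.empty((n_models, net.r))
    accepted = rejected = 0
    while accepted < n_models:
        try:
            fcc = compute_fcc(net, sample_elasticities(net, rng))
        except ArithmeticError:
            rejected += 1
        else:
            rows[accepted] = fcc.values[target_reaction]
            accepted += 1
        drawn = accepted + rejected
        if drawn >= 1000 and accepted / drawn < 0.01:
            raise ValidationError(
                f"acceptance rate {accepted / drawn:.2%} below 1%: "
                "the network yields almost no stable models"
            )
    if rejected:
        logger.info("rejected %d ill-conditioned draws", rejected)
    return Ensemble(
        rows,
        tuple(f"C_{net.reaction_names[target_reaction]}_{rn}" for rn in net.reaction_names),
        case_label=f"fcc_{net.reaction_names[target_reaction]}",
    )


# ---------------------------------------------------------------------------
# Gaussian-copula generator with known truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Marginal:
    """One variable's marginal family and skew parameter.

    ``skew`` is ignored for the normal family; for the shifted lognormal
    it is the log-scale sigma, for the shifted gamma it is 2/sqrt(shape).
    A negative skew mirrors the distribution.
    """

    family: str = "normal"
    skew: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in MARGINAL_FAMILIES:
            raise ValidationError(f"unknown marginal family {self.family!r}")
        if self.family != "normal" and self.skew == 0.0:
            raise ValidationError(f"{self.family} needs a nonzero skew parameter")


@dataclass(frozen=True)
class CopulaSpec:
    """Latent-normal copula with exactly known per-variable mean and SD."""

    true_means: np.ndarray
    sds: np.ndarray
    correlation: np.ndarray
    marginals: tuple[Marginal, ...]
    variable_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        mu = np.asarray(self.true_means, dtype=float)
        sd = np.asarray(self.sds, dtype=float)
        R = np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "true_means", mu)
        object.__setattr__(self, "sds", sd)
        object.__setattr__(self, "correlation", R)
        p = mu.size
        if sd.shape != (p,) or np.any(sd <= 0):
            raise ValidationError("sds must be positive and align with true_means")
        if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-10):
            raise ValidationError("correlation must be a symmetric p x p matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ValidationError("correlation diagonal must be one")
        if np.linalg.eigvalsh(R)[0] < -1e-10:
            raise ValidationError("correlation must be positive semidefinite")
        margs = tuple(self.marginals)
        if len(margs) != p:
            raise ValidationError("one marginal per variable required")
        object.__setattr__(self, "marginals", margs)
        names = tuple(self.variable_names) or tuple(
            f"v{j + 1:02d}" for j in range(p)
        )
        if len(names) != p:
            raise ValidationError("variable_names must align with true_means")
        object.__setattr__(self, "variable_names", names)

    @property
    def p(self) -> int:
        return self.true_means.size


def _standardized_marginal(z: np.ndarray, marg: Marginal) -> np.ndarray:
    """Transform standard-normal draws to a zero-mean unit-SD marginal."""
    if marg.family == "normal":
        return z
    s = abs(marg.skew)
    sign = 1.0 if marg.skew > 0 else -1.0
    if marg.family == "lognormal_shifted":
        x = np.exp(s * z)
        mean = np.exp(s * s / 2.0)
        sd = np.sqrt((np.exp(s * s) - 1.0) * np.exp(s * s))
    else:  # gamma_shifted, skew parameter 2/sqrt(shape)
        shape = (2.0 / s) ** 2
        x = stats.gamma.ppf(stats.norm.cdf(z), a=shape)
        mean, sd = shape, np.sqrt(shape)
    return sign * (x - mean) / sd


def generate_copula_ensemble(
    spec: CopulaSpec, n: int, seed: int | np.random.Generator = 0
) -> Ensemble:
    """Draw n observations with known means/SDs and latent correlation.

    A latent N_p(0, R) draw is transformed through each marginal and
    affinely rescaled so that, in distribution, variable j has exactly
    mean ``true_means[j]`` and SD ``sds[j]``. For non-normal marginals the
    observed (Pearson) correlation differs somewhat from the latent R, as
    it does in real data.
    """
    if n < 2:
        raise ValidationError("need n >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    w, V = np.linalg.eigh(spec.correlation)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, spec.p)) @ L.T
    out = np.empty_like(z)
    for j, marg in enumerate(spec.marginals):
        out[:, j] = spec.true_means[j] + spec.sds[j] * _standardized_marginal(
            z[:, j], marg
        )
    return Ensemble(out, spec.variable_names, case_label="copula")


def exchangeable_correlation(p: int, rho: float) -> np.ndarray:
    """Compound-symmetry correlation: 1 on the diagonal, rho elsewhere."""
    low = -1.0 / (p - 1) if p > 1 else -1.0
    if not low <= rho <= 1.0:
        raise ValidationError("rho outside the valid exchangeable range")
    return np.full((p, p), rho) + (1.0 - rho) * np.eye(p)


# ---------------------------------------------------------------------------
# Multi-case fixture with planted differences
# ---------------------------------------------------------------------------


def make_comparison_cases(
    n: int = 500,
    sd: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> tuple[list[Ensemble], dict[str, np.ndarray]]:
    """Four copula cases emulating alternative operational configurations.

    Twenty variables per case; each case has exactly seven variables with
    large planted means (its 'top seven'), chosen so the union of the four
    top-seven sets has 15 members; the remaining variables have true mean
    zero (true nulls for family-wise-error experiments). Returns the
    ensembles and the map case label -> true mean vector.
    """
    p = 20
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    names = tuple(f"v{j + 1:02d}" for j in range(p))
    # per-case indices of the seven planted variables (0-based)
    tops = {
        "case1": [0, 1, 2, 3, 4, 5, 6],
        "case2": [0, 1, 2, 3, 4, 7, 8],
        "case3": [0, 1, 2, 3, 9, 10, 11],
        "case4": [0, 1, 2, 3, 12, 13, 14],
    }
    magnitudes = np.array([1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
    R = exchangeable_correlation(p, 0.2)
    skew_cycle = (
        Marginal("lognormal_shifted", 0.8),
        Marginal("normal"),
        Marginal("gamma_shifted", -1.0),
        Marginal("normal"),
    )
    ensembles, truths = [], {}
    for label, idx in tops.items():
        mu = np.zeros(p)
        mu[idx] = magnitudes
        spec = CopulaSpec(
            mu,
            np.full(p, sd),
            R,
            tuple(skew_cycle[j % len(skew_cycle)] for j in range(p)),
            names,
        )
        ens = generate_copula_ensemble(spec, n, rng)
        ensembles.append(Ensemble(ens.values, names, case_label=label))
        truths[label] = mu
    return ensembles, truths


# ---------------------------------------------------------------------------
# Coverage harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoverageReport:
    """Monte Carlo coverage diagnostics for one CI method."""

    simultaneous_coverage: float
    marginal_coverages: np.ndarray
    left_miss: np.ndarray
    right_miss: np.ndarray
    mean_widths: np.ndarray
    reps: int
    seed: int | None

    def __post_init__(self) -> None:
        for attr in ("marginal_coverages", "left_miss", "right_miss", "mean_widths"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), float))
        rates = np.concatenate(
            [
                [self.simultaneous_coverage],
                self.marginal_coverages,
                self.left_miss,
                self.right_miss,
            ]
        )
        if np.any(rates < 0) or np.any(rates > 1):
            raise ValidationError("rates must lie in [0, 1]")
        total = self.marginal_coverages + self.left_miss + self.right_miss
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValidationError("coverage + left miss + right miss must be 1")


def _build_ci(
    ensemble: Ensemble,
    method: str,
    alpha_s: float,
    B: int,
    M: int,
    rng: np.random.Generator,
) -> CISet:
    if method == "univariate":
        return univariate_ci(ensemble, alpha_s)
    if method == "bonferroni":
        return bonferroni_ci(ensemble, alpha_s)
    if method == "exact_normal":
        return exact_normal_ci(ensemble, alpha_s, M, rng)
    if method == "bootstrap":
        return balanced_simultaneous_ci(ensemble, alpha_s, B, rng)
    raise ValidationError(f"unknown method {method!r}")


def run_coverage_experiment(
    spec: CopulaSpec,
    method: str = "bonferroni",
    alpha_s: float = 0.05,
    n: int = 500,
    reps: int = 500,
    seed: int = 0,
    B: int = DEFAULT_B,
    M: int = 100_000,
) -> CoverageReport:
    """Repeat generate-and-cover and tally the promised probabilities.

    For each of ``reps`` independent datasets from ``spec``, the chosen
    method's CIs are built and checked against the spec's true means:
    simultaneous coverage is the fraction of repetitions in which every
    interval contains its true mean; left (right) miss is the fraction in
    which the true mean falls below (above) the interval, per variable.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    if reps < 100:
        raise ValidationError("need at least 100 repetitions")
    rng = np.random.default_rng(seed)
    p = spec.p
    all_in = 0
    left = np.zeros(p)
    right = np.zeros(p)
    widths = np.zeros(p)
    for _ in range(reps):
        ens = generate_copula_ensemble(spec, n, rng)
        ciset = _build_ci(ens, method, alpha_s, B, M, rng)
        lo_miss = spec.true_means < ciset.lower
        hi_miss = spec.true_means > ciset.upper
        left += lo_miss
        right += hi_miss
        widths += ciset.upper - ciset.lower
        if not (lo_miss.any() or hi_miss.any()):
            all_in += 1
    return CoverageReport(
        simultaneous_coverage=all_in / reps,
        marginal_coverages=1.0 - (left + right) / reps,
        left_miss=left / reps,
        right_miss=right / reps,
        mean_widths=widths / reps,
        reps=reps,
        seed=seed,
    )
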