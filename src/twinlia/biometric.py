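"""Variance-component (biometric) models for the classical twin design.

The phenotypic (liability) variance is decomposed into additive genetic
(a2), dominance (d2), shared-environment (c2) and unique-environment
(e2) proportions.  Genetic theory fixes the cross-twin correlations of
the latent factors — A: 1 / 0.5, D: 1 / 0.25, C: 1 / 1 for MZ / DZ — so
a model implies

    r_MZ = a2 + c2 + d2          r_DZ = 0.5*a2 + c2 + 0.25*d2

Models are fitted to the two estimated polychoric correlations by
weighted least squares: minimise

    chi2(theta) = ((r_MZ - rho_MZ(theta)) / se_MZ)^2
                + ((r_DZ - rho_DZ(theta)) / se_DZ)^2

subject to all components >= 0 and a2+c2+d2+e2 = 1.  The minimised
value is an approximate goodness-of-fit chi-square with df equal to the
number of fitted statistics (2) minus the number of free genetic/shared
parameters not pinned at a boundary.  The ACDE model is not identified
from MZ/DZ data and is excluded; c2 and d2 are never simultaneously
free.

The model is parameterised directly in variance proportions; path
coefficients (a, c, d, e) are reported as their square roots, which
sidesteps the sign indeterminacy of path coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

#: free genetic/shared variance parameters per model (e2 is always free
#: through the unit-variance constraint)
MODEL_FREE: dict[str, tuple[str, ...]] = {
    "ADE": ("a2", "d2"),
    "ACE": ("a2", "c2"),
    "AE": ("a2",),
    "CE": ("c2",),
    "DE": ("d2",),
    "E": (),
}

#: (MZ, DZ) cross-twin correlation of each latent factor
_FACTOR_CORR = {"a2": (1.0, 0.5), "c2": (1.0, 1.0), "d2": (1.0, 0.25)}

_SUM_TOL = 1e-8
_BOUNDARY_EPS = 1e-7


@dataclass(frozen=True)
class VarianceComponents:
    """Standardised variance proportions; must sum to 1."""

    a2: float = 0.0
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 1.0

    def __post_init__(self):
        vals = (self.a2, self.c2, self.d2, self.e2)
        if any(v < -_SUM_TOL for v in vals):
            raise ValueError(f"variance components must be non-negative, got {vals}")
        total = sum(vals)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"variance components must sum to 1, got {total:.8f}")
        if self.e2 <= 0:
            raise ValueError("e2 must be strictly positive (measurement error exists)")

    def as_dict(self) -> dict[str, float]:
        return {"a2": self.a2, "c2": self.c2, "d2": self.d2, "e2": self.e2}


@dataclass(frozen=True)
class ModelSpec:
    """One of the classical identified twin models."""

    name: str

    def __post_init__(self):
        if self.name not in MODEL_FREE:
            raise ValueError(
                f"unknown model {self.name!r}; choose from {sorted(MODEL_FREE)} "
                "(ACDE is not identified in the classical twin design)"
            )

    @property
    def free(self) -> tuple[str, ...]:
        return MODEL_FREE[self.name]


@dataclass(frozen=True)
class CorrelationPair:
    """Estimated MZ and DZ twin correlations with standard errors."""

    r_mz: float
    r_dz: float
    se_mz: float
    se_dz: float
    n_mz: int = 0
    n_dz: int = 0

    def __post_init__(self):
        for r in (self.r_mz, self.r_dz):
            if not abs(r) < 1:
                raise ValueError(f"correlations must lie in (-1, 1), got {r}")
        if self.se_mz <= 0 or self.se_dz <= 0:
            raise ValueError("standard errors must be positive")


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    components: VarianceComponents
    chi2: float
    df: int
    p: float
    boundary_flags: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class NestedTest:
    delta_chi2: float
    df: int
    p: float


def expected_correlations(v: VarianceComponents) -> tuple[float, float]:
    """Model-implied (r_MZ, r_DZ) for given variance components."""
    r_mz = v.a2 + v.c2 + v.d2
    r_dz = 0.5 * v.a2 + v.c2 + 0.25 * v.d2
    return r_mz, r_dz


def variance_from_paths(a: float, c: float, d: float, e: float) -> VarianceComponents:
    """Squared path coefficients renormalised to exact unit variance.

    Printed path coefficients are typically rounded to 2 decimals, so
    their squares are allowed to miss 1 by up to 0.02 before being
    renormalised.
    """
    sq = np.array([a, c, d, e], dtype=float) ** 2
    total = sq.sum()
    if abs(total - 1.0) > 0.02:
        raise ValueError(
            f"squared path coefficients sum to {total:.4f}; expected 1 within 0.02"
        )
    sq /= total
    return VarianceComponents(*sq)


def _chi2_statistic(free: tuple[str, ...], x: np.ndarray, corr: CorrelationPair) -> float:
    r_mz = sum(xi * _FACTOR_CORR[name][0] for name, xi in zip(free, x))
    r_dz = sum(xi * _FACTOR_CORR[name][1] for name, xi in zip(free, x))
    return (
        ((corr.r_mz - r_mz) / corr.se_mz) ** 2
        + ((corr.r_dz - r_dz) / corr.se_dz) ** 2
    )


def _components_from_free(free: tuple[str, ...], x: np.ndarray) -> VarianceComponents:
    d = {"a2": 0.0, "c2": 0.0, "d2": 0.0}
    for name, xi in zip(free, x):
        d[name] = float(max(xi, 0.0))
    e2 = 1.0 - sum(d.values())
    return VarianceComponents(a2=d["a2"], c2=d["c2"], d2=d["d2"], e2=e2)


def solve_saturated(
    spec: ModelSpec | str, r_mz: float, r_dz: float
) -> tuple[VarianceComponents, frozenset[str]]:
    """Exact solution of a saturated model (ADE or ACE) to two correlations.

    ADE: a2 = 4*r_DZ - r_MZ, d2 = 2*r_MZ - 4*r_DZ;
    ACE: a2 = 2*(r_MZ - r_DZ), c2 = 2*r_DZ - r_MZ; e2 = 1 - r_MZ.
    A negative component is clipped to zero (boundary flag) and the
    remaining free components re-solved by non-negative least squares.
    """
    spec = ModelSpec(spec) if isinstance(spec, str) else spec
    if spec.name not in ("ADE", "ACE"):
        raise ValueError(f"{spec.name} is not saturated for two correlations")
    if not (abs(r_mz) < 1 and abs(r_dz) < 1):
        raise ValueError("correlations must lie in (-1, 1)")
    if spec.name == "ADE":
        x = np.array([4 * r_dz - r_mz, 2 * r_mz - 4 * r_dz])
    else:
        x = np.array([2 * (r_mz - r_dz), 2 * r_dz - r_mz])
    flags: set[str] = set()
    if np.any(x < 0) or x.sum() > 1:
        flags.update(n for n, xi in zip(spec.free, x) if xi < 0)
        # re-solve under the constraints by unit-weight least squares
        g = np.array([_FACTOR_CORR[n] for n in spec.free]).T  # 2 x m
        res = optimize.lsq_linear(g, [r_mz, r_dz], bounds=(0.0, 1.0))
        x = res.x
        x[x < _BOUNDARY_EPS] = 0.0
        if x.sum() >= 1.0:
            x *= (1.0 - 1e-9) / x.sum()
        flags.update(n for n, xi in zip(spec.free, x) if xi < _BOUNDARY_EPS)
    return _components_from_free(spec.free, x), frozenset(flags)


def fit_model(spec: ModelSpec | str, corr: CorrelationPair) -> FitResult:
    """Constrained weighted-least-squares fit of one twin model.

    A saturated spec with an interior solution reproduces the observed
    correlations exactly (chi2 = 0, df = 0).  Components pinned at the
    non-negativity boundary are flagged and do not count as free in the
    df bookkeeping.
    """
    spec = ModelSpec(spec) if isinstance(spec, str) else spec
    free = spec.free
    m = len(free)
    if m == 0:
        x = np.empty(0)
    elif m == 1:
        # quadratic in one variable: closed-form WLS solution, clipped
        g = np.array(_FACTOR_CORR[free[0]])
        w = np.array([1 / corr.se_mz**2, 1 / corr.se_dz**2])
        r = np.array([corr.r_mz, corr.r_dz])
        x_hat = (w * g * r).sum() / (w * g * g).sum()
        x = np.array([np.clip(x_hat, 0.0, 1.0 - 1e-9)])
    else:
        x0, _ = solve_saturated(spec, np.clip(corr.r_mz, -0.99, 0.99),
                                np.clip(corr.r_dz, -0.99, 0.99))
        x0 = np.array([x0.as_dict()[n] for n in free])
        res = optimize.minimize(
            lambda x: _chi2_statistic(free, x, corr),
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * m,
            constraints=[{"type": "ineq", "fun": lambda x: 1.0 - 1e-9 - x.sum()}],
            options={"ftol": 1e-14, "maxiter": 200},
        )
        x = np.clip(res.x, 0.0, 1.0)
        if x.sum() >= 1.0:
            x *= (1.0 - 1e-9) / x.sum()
    chi2 = max(float(_chi2_statistic(free, x, corr)), 0.0)
    flags = frozenset(n for n, xi in zip(free, x) if xi < _BOUNDARY_EPS)
    df = 2 - (m - len(flags))
    p = chi2_pvalue(chi2, df)
    return FitResult(
        spec=spec,
        components=_components_from_free(free, x),
        chi2=chi2,
        df=df,
        p=p,
        boundary_flags=flags,
    )


def falconer_heritability(r_mz: float, r_dz: float) -> float:
    """Falconer's broad-sense heritability, 2*(r_MZ - r_DZ)."""
    if abs(r_mz) > 1 or abs(r_dz) > 1:
        raise ValueError("correlations must lie in [-1, 1]")
    return 2.0 * (r_mz - r_dz)


def chi2_pvalue(x: float, df: int) -> float:
    """Upper-tail chi-square probability; df = 0 means a saturated fit."""
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df == 0:
        return 1.0 if x < 1e-8 else 0.0
    if df < 0:
        raise ValueError("degrees of freedom must be >= 0")
    return float(chi2_dist.sf(x, df))


def compare_nested(full: FitResult, reduced: FitResult) -> NestedTest:
    """Likelihood-ratio-style chi-square difference test of nested fits."""
    full_free, red_free = set(full.spec.free), set(reduced.spec.free)
    if not red_free < full_free:
        raise ValueError(
            f"{reduced.spec.name} is not nested in {full.spec.name}: "
            f"free set {sorted(red_free)} is not a proper subset of {sorted(full_free)}"
        )
    delta = max(reduced.chi2 - full.chi2, 0.0)
    df = len(full_free) - len(red_free)
    return NestedTest(delta_chi2=delta, df=df, p=chi2_pvalue(delta, df))


class TwinVarianceModel(BaseEstimator):
    """Scikit-learn-style estimator for one classical twin model.

    Parameters
    ----------
    model : str
        One of ``ADE, ACE, AE, CE, DE, E``.

    Attributes (after :meth:`fit`)
    ------------------------------
    components_ : VarianceComponents
    chi2_, df_, p_ : goodness of fit
    boundary_flags_ : frozenset of components pinned at zero
    """

    def __init__(self, model: str = "ADE"):
        self.model = model

    def fit(self, corr: CorrelationPair, y=None):
        if not isinstance(corr, CorrelationPair):
            raise TypeError("fit expects a CorrelationPair")
        result = fit_model(ModelSpec(self.model), corr)
        self.result_ = result
        self.components_ = result.components
        self.chi2_ = result.chi2
        self.df_ = result.df
        self.p_ = result.p
        self.boundary_flags_ = result.boundary_flags
        return self

    def expected_correlations(self) -> tuple[float, float]:
        return expected_correlations(self.components_)
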