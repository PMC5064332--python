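"""Monte-Carlo power to detect genetic dominance in the classical twin design.

The test of interest is the chi-square difference between the AE model
(additive + unique environment) and the full ADE model, with one degree
of freedom.  Power is low when the truth contains dominance: the MZ/DZ
correlation pattern that distinguishes d2 from a2 is subtle, and much
of the information is lost when an ordinal or dichotomous trait stands
in for the latent liability.  Each replicate simulates a twin cohort,
estimates the per-zygosity polychoric correlations, fits AE and ADE by
constrained weighted least squares and applies the df = 1 test.

Replicates whose polychoric fit degenerates (e.g. an empty margin in a
small dichotomous table) are resampled and counted.  All randomness
descends from one master seed, and `required_n` reuses the same
replicate streams at every evaluated sample size (common random
numbers), which smooths the simulated power curve for the bisection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .biometric import CorrelationPair, VarianceComponents, compare_nested, fit_model
from .polychoric import double_enter, fit_polychoric
from .simulate import SimulationConfig, simulate_pairs

logger = logging.getLogger(__name__)

_MAX_RESAMPLE_FACTOR = 4


@dataclass(frozen=True)
class PowerResult:
    """Simulated rejection rate of the false AE model."""

    power: float
    mc_se: float
    reps: int
    n_mz: int
    n_dz: int
    alpha: float
    n_failed: int = 0


@dataclass(frozen=True)
class RequiredNResult:
    """Smallest total pair count reaching the target power."""

    n_total: int
    power: float
    mc_se: float
    target_power: float
    evaluations: tuple[tuple[int, float], ...] = field(default_factory=tuple)


def _replicate_pvalue(
    truth: VarianceComponents,
    prevalences,
    n_mz: int,
    n_dz: int,
    seed: int,
) -> float:
    n_categories = len(prevalences)
    cfg = SimulationConfig(
        components=truth, n_mz=n_mz, n_dz=n_dz, seed=seed, prevalences=tuple(prevalences)
    )
    records = simulate_pairs(cfg)
    estimates = {}
    for zyg in ("MZ", "DZ"):
        table = double_enter(records, zyg, n_categories=n_categories)
        n_pairs = int(table.sum() // 2)
        estimates[zyg] = fit_polychoric(table, zygosity=zyg, n_pairs=n_pairs)
    corr = CorrelationPair(
        r_mz=estimates["MZ"].rho,
        r_dz=estimates["DZ"].rho,
        se_mz=estimates["MZ"].se_rho,
        se_dz=estimates["DZ"].se_rho,
        n_mz=estimates["MZ"].n_pairs,
        n_dz=estimates["DZ"].n_pairs,
    )
    ade = fit_model("ADE", corr)
    ae = fit_model("AE", corr)
    return compare_nested(ade, ae).p


def power_reject_AE(
    truth: VarianceComponents,
    prevalences=(0.63, 0.08, 0.14, 0.15),
    n_mz: int = 725,
    n_dz: int = 724,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
) -> PowerResult:
    """Simulated power of the df = 1 AE-vs-ADE test at size ``alpha``.

    ``truth`` with d2 = 0 gives a size calibration run (rejection rate
    should approximate alpha).  Deterministic for fixed ``seed``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    # one integer sub-seed per potential replicate, derived from the master
    master = np.random.SeedSequence(seed)
    sub_seeds = master.generate_state(_MAX_RESAMPLE_FACTOR * reps) % (2**31)
    rejections = 0
    n_failed = 0
    done = 0
    i = 0
    while done < reps:
        if i >= len(sub_seeds):
            raise RuntimeError(
                f"too many degenerate replicates ({n_failed}); "
                "increase the sample size or category prevalences"
            )
        try:
            p = _replicate_pvalue(truth, prevalences, n_mz, n_dz, int(sub_seeds[i]))
        except ValueError:
            n_failed += 1
            i += 1
            continue
        rejections += p < alpha
        done += 1
        i += 1
    if n_failed:
        logger.info("power_reject_AE: %d degenerate replicates resampled", n_failed)
    power = rejections / reps
    return PowerResult(
        power=power,
        mc_se=float(np.sqrt(power * (1 - power) / reps)),
        reps=reps,
        n_mz=n_mz,
        n_dz=n_dz,
        alpha=alpha,
        n_failed=n_failed,
    )


def _split(n_total: int) -> tuple[int, int]:
    n_mz = n_total // 2
    return n_total - n_mz, n_mz


def required_n(
    target_power: float,
    truth: VarianceComponents,
    prevalences=(0.63, 0.08, 0.14, 0.15),
    alpha: float = 0.05,
    reps: int = 500,
    seed: int = 0,
    n_bounds: tuple[int, int] = (500, 60000),
    rel_tol: float = 0.1,
) -> RequiredNResult:
    """Smallest total pair count (equal MZ/DZ split) reaching ``target_power``.

    Bisection on total n over a power curve simulated with common random
    numbers, stopping when the bracket is within ``rel_tol`` relative
    width; returns the upper end (the smallest evaluated n whose power
    met the target).
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    lo, hi = n_bounds
    if lo >= hi or lo < 4:
        raise ValueError("n_bounds must satisfy 4 <= lower < upper")

    evals: list[tuple[int, float]] = []

    def power_at(n_total: int) -> float:
        res = power_reject_AE(
            truth, prevalences, *_split(n_total), alpha=alpha, reps=reps, seed=seed
        )
        evals.append((n_total, res.power))
        logger.info("required_n: power %.3f at n_total=%d", res.power, n_total)
        return res.power

    p_lo = power_at(lo)
    if p_lo >= target_power:
        return RequiredNResult(lo, p_lo, _mc_se(p_lo, reps), target_power, tuple(evals))
    p_hi = power_at(hi)
    if p_hi < target_power:
        raise ValueError(
            f"bracket failure: power {p_lo:.3f} at n={lo} and {p_hi:.3f} at "
            f"n={hi}, both below target {target_power}"
        )
    while hi - lo > 2 and hi > lo * (1 + rel_tol):
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    p_final = dict(evals)[hi]
    return RequiredNResult(
        n_total=hi,
        power=p_final,
        mc_se=_mc_se(p_final, reps),
        target_power=target_power,
        evaluations=tuple(evals),
    )


def _mc_se(p: float, reps: int) -> float:
    return float(np.sqrt(p * (1 - p) / reps))
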