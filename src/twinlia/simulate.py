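"""Synthetic MZ/DZ twin pairs from the liability-threshold model.

Each twin's ordinal score arises by cutting a latent standard-normal
liability at fixed thresholds.  Within a pair the two liabilities are
bivariate standard normal with correlation implied by the biometric
variance components:

    r_MZ = a2 + c2 + d2          r_DZ = 0.5*a2 + c2 + 0.25*d2

(additive effects correlate 1 in MZ and 1/2 in DZ pairs, dominance
deviations 1 and 1/4, shared environment 1 in both, and the random
environment not at all).  Thresholds are common to both twins and both
zygosity groups, chosen so the marginal category probabilities match
the requested prevalences — by default the four-level severity
distribution 63/8/14/15%.

Liabilities are drawn directly from the implied bivariate normal
(``method="bivariate"``), which is distributionally identical to, and
cheaper than, summing separate A/C/D/E factor draws; the factor-wise
construction is kept as ``method="components"`` for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .biometric import VarianceComponents, expected_correlations

DEFAULT_PREVALENCES = (0.63, 0.08, 0.14, 0.15)

ZYGOSITIES = ("MZ", "DZ")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated twin cohort."""

    components: VarianceComponents
    n_mz: int
    n_dz: int
    seed: int
    prevalences: tuple[float, ...] = DEFAULT_PREVALENCES

    def __post_init__(self):
        p = np.asarray(self.prevalences, dtype=float)
        _validate_simplex(p)
        if self.n_mz < 1 or self.n_dz < 1:
            raise ValueError("n_mz and n_dz must each be >= 1")


def _validate_simplex(p: np.ndarray) -> None:
    if p.ndim != 1 or p.size < 2:
        raise ValueError("prevalence vector must have at least 2 categories")
    if np.any(p <= 0):
        raise ValueError("all prevalences must be strictly positive")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError(f"prevalences must sum to 1, got {p.sum():.6f}")


def thresholds_from_prevalences(p) -> np.ndarray:
    """Liability thresholds implied by category prevalences.

    For K categories returns the K-1 strictly increasing standard-normal
    quantiles of the cumulative prevalences.
    """
    p = np.asarray(p, dtype=float)
    _validate_simplex(p)
    return norm.ppf(np.cumsum(p)[:-1])


def _draw_bivariate(rng: np.random.Generator, n: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(n)
    w = rng.standard_normal(n)
    return z1, r * z1 + np.sqrt(1.0 - r * r) * w


def _draw_components(
    rng: np.random.Generator, n: int, v: VarianceComponents, zygosity: str
) -> tuple[np.ndarray, np.ndarray]:
    # Factor-wise construction: P_i = a*A_i + c*C + d*D_i + e*E_i with
    # corr(A1,A2) = 1 or 0.5 and corr(D1,D2) = 1 or 0.25 by zygosity.
    r_a = 1.0 if zygosity == "MZ" else 0.5
    r_d = 1.0 if zygosity == "MZ" else 0.25
    a1, a2_ = _draw_bivariate(rng, n, r_a)
    d1, d2_ = _draw_bivariate(rng, n, r_d)
    c = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2_ = rng.standard_normal(n)
    a, cc, d, e = (np.sqrt(v.a2), np.sqrt(v.c2), np.sqrt(v.d2), np.sqrt(v.e2))
    p1 = a * a1 + cc * c + d * d1 + e * e1
    p2 = a * a2_ + cc * c + d * d2_ + e * e2_
    return p1, p2


def simulate_pairs(cfg: SimulationConfig, method: str = "bivariate") -> pd.DataFrame:
    """Simulate a twin cohort; returns ``pair_id, zygosity, score1, score2``.

    Deterministic for a fixed ``cfg.seed``: the MZ and DZ groups use
    substreams spawned from one master seed, so enlarging one group does
    not perturb the other.
    """
    if method not in ("bivariate", "components"):
        raise ValueError(f"unknown method {method!r}")
    tau = thresholds_from_prevalences(cfg.prevalences)
    r_mz, r_dz = expected_correlations(cfg.components)
    ss = np.random.SeedSequence(cfg.seed)
    streams = dict(zip(ZYGOSITIES, ss.spawn(2)))
    frames = []
    offset = 0
    for zyg, n, r in (("MZ", cfg.n_mz, r_mz), ("DZ", cfg.n_dz, r_dz)):
        rng = np.random.default_rng(streams[zyg])
        if method == "bivariate":
            l1, l2 = _draw_bivariate(rng, n, r)
        else:
            l1, l2 = _draw_components(rng, n, cfg.components, zyg)
        frames.append(
            pd.DataFrame(
                {
                    "pair_id": np.arange(offset, offset + n),
                    "zygosity": zyg,
                    "score1": np.searchsorted(tau, l1),
                    "score2": np.searchsorted(tau, l2),
                }
            )
        )
        offset += n
    return pd.concat(frames, ignore_index=True)


def observed_category_frequencies(records: pd.DataFrame, n_categories: int | None = None) -> np.ndarray:
    """Pooled score frequencies over both twins of every pair; sums to 1."""
    if len(records) == 0:
        raise ValueError("no records to summarise")
    scores = np.concatenate(
        [records["score1"].to_numpy(int), records["score2"].to_numpy(int)]
    )
    k = n_categories if n_categories is not None else int(scores.max()) + 1
    counts = np.bincount(scores, minlength=k).astype(float)
    return counts / counts.sum()


def simulate_individuals(
    prevalences, n: int, seed: int
) -> np.ndarray:
    """Ordinal scores for ``n`` unrelated individuals from the threshold model."""
    tau = thresholds_from_prevalences(prevalences)
    rng = np.random.default_rng(seed)
    return np.searchsorted(tau, rng.standard_normal(n))
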