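"""End-to-end twin analysis: read, balance, correlate, fit, report.

The pipeline mirrors a two-group (MZ/DZ) categorical twin analysis:

1. read and validate pair records;
2. optionally equalise group sizes by random subsampling of the larger
   group (a common recommendation for two-group fitting);
3. double-enter each group into a contingency table and estimate the
   polychoric correlation and thresholds;
4. fit the nested variance-component models (ADE, ACE, AE, CE, DE, E)
   and run chi-square difference tests;
5. report Falconer's heritability and a most-parsimonious adequate
   model, with a count ledger of every filtering step.

An optional severity-restricted arm repeats the analysis after removing
(or recoding) the top severity category, which probes how much of the
familial signal is carried by the severe/recurrent cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .biometric import (
    CorrelationPair,
    FitResult,
    ModelSpec,
    NestedTest,
    compare_nested,
    falconer_heritability,
    fit_model,
)
from .polychoric import PolychoricEstimate, double_enter, fit_polychoric

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("pair_id", "zygosity", "score1", "score2")
DEFAULT_MODELS = ("ADE", "ACE", "AE", "CE", "DE", "E")


@dataclass(frozen=True)
class AnalysisConfig:
    seed: int = 0
    n_categories: int = 4
    balance: bool = True
    models: tuple[str, ...] = DEFAULT_MODELS
    min_pairs_per_group: int = 30
    alpha: float = 0.05
    severe_arm: bool = True
    severe_mode: str = "drop"  # "drop" pairs touching the top category, or "recode"


@dataclass(frozen=True)
class ArmResult:
    """One analysis arm (full sample or severity-restricted)."""

    label: str
    correlations: dict[str, PolychoricEstimate]
    corr_pair: CorrelationPair
    heritability: float
    fits: dict[str, FitResult]
    nested_tests: dict[str, NestedTest]
    best_model: str
    best_model_reason: str
    n_pairs: dict[str, int]


@dataclass(frozen=True)
class AnalysisReport:
    config: AnalysisConfig
    counts: dict[str, int]
    full: ArmResult
    restricted: Optional[ArmResult] = None

    def to_text(self) -> str:
        lines = ["Twin liability analysis report", "=" * 31, ""]
        lines.append("Counts ledger:")
        for k, v in self.counts.items():
            lines.append(f"  {k}: {v}")
        for arm in filter(None, (self.full, self.restricted)):
            lines += ["", f"--- {arm.label} ---"]
            for zyg, est in arm.correlations.items():
                lines.append(
                    f"{zyg}: n={arm.n_pairs[zyg]} pairs, rho={est.rho:.3f} "
                    f"(se {est.se_rho:.3f}), thresholds "
                    + ", ".join(f"{t:.3f}" for t in est.tau_rows)
                )
            lines.append(f"Falconer broad-sense heritability: {arm.heritability:.2f}")
            lines.append("Model fits (df = statistics - interior free parameters):")
            lines.append("  model   a2    c2    d2    e2   chi2   df     p  boundary")
            for name, fit in arm.fits.items():
                c = fit.components
                lines.append(
                    f"  {name:<5} {c.a2:5.2f} {c.c2:5.2f} {c.d2:5.2f} {c.e2:5.2f} "
                    f"{fit.chi2:6.2f} {fit.df:4d} {fit.p:5.2f}  "
                    + (",".join(sorted(fit.boundary_flags)) or "-")
                )
            for label, test in arm.nested_tests.items():
                lines.append(
                    f"  {label}: delta_chi2={test.delta_chi2:.2f}, "
                    f"df={test.df}, p={test.p:.2f}"
                )
            lines.append(f"Preferred model: {arm.best_model} ({arm.best_model_reason})")
        return "\n".join(lines) + "\n"


def read_pairs(path, n_categories: int = 4) -> pd.DataFrame:
    """Read and validate a ``pair_id, zygosity, score1, score2`` CSV.

    Rows with out-of-range scores are rejected with row-numbered log
    messages; a missing column, empty file, unknown zygosity token or
    duplicated pair id is an error.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    bad_zyg = ~df["zygosity"].isin(["MZ", "DZ"])
    if bad_zyg.any():
        tokens = sorted(df.loc[bad_zyg, "zygosity"].unique())
        raise ValueError(f"{path}: unknown zygosity token(s) {tokens}")
    scores = df[["score1", "score2"]].apply(pd.to_numeric, errors="coerce")
    valid = (
        scores.notna().all(axis=1)
        & (scores >= 0).all(axis=1)
        & (scores < n_categories).all(axis=1)
        & (scores == scores.round()).all(axis=1)
    )
    for idx in df.index[~valid]:
        logger.warning(
            "row %d rejected: scores (%r, %r) not integers in 0..%d",
            idx, df.loc[idx, "score1"], df.loc[idx, "score2"], n_categories - 1,
        )
    df = df[valid].copy()
    if len(df) == 0:
        raise ValueError(f"{path}: no valid records after filtering")
    dup = df["pair_id"][df["pair_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate pair_id {dup.iloc[0]!r}")
    df["score1"] = df["score1"].astype(int)
    df["score2"] = df["score2"].astype(int)
    df.attrs["n_rejected"] = int((~valid).sum())
    return df.reset_index(drop=True)


def balanced_subsample(records: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Randomly downsample the larger zygosity group to the smaller's size."""
    groups = {z: records[records["zygosity"] == z] for z in ("MZ", "DZ")}
    sizes = {z: len(g) for z, g in groups.items()}
    if min(sizes.values()) == 0:
        raise ValueError(f"both zygosity groups must be non-empty, got {sizes}")
    n_target = min(sizes.values())
    rng = np.random.default_rng(seed)
    kept = []
    for z, g in groups.items():
        if len(g) > n_target:
            keep_idx = rng.choice(g.index.to_numpy(), size=n_target, replace=False)
            kept.append(g.loc[np.sort(keep_idx)])
        else:
            kept.append(g)
    return pd.concat(kept, ignore_index=True)


def _restrict_severe(records: pd.DataFrame, k: int, mode: str) -> pd.DataFrame:
    top = k - 1
    if mode == "drop":
        keep = (records["score1"] != top) & (records["score2"] != top)
        return records[keep].reset_index(drop=True)
    if mode == "recode":
        out = records.copy()
        out["score1"] = out["score1"].clip(upper=top - 1)
        out["score2"] = out["score2"].clip(upper=top - 1)
        return out
    raise ValueError(f"severe_mode must be 'drop' or 'recode', got {mode!r}")


def _select_best(fits: dict[str, FitResult], alpha: float) -> tuple[str, str]:
    """Most parsimonious model whose absolute fit is adequate (p >= alpha)."""
    order = sorted(fits, key=lambda m: (len(ModelSpec(m).free), m))
    for name in order:
        if fits[name].p >= alpha:
            return name, (
                f"most parsimonious model with adequate fit "
                f"(chi2={fits[name].chi2:.2f}, df={fits[name].df}, "
                f"p={fits[name].p:.2f} >= {alpha})"
            )
    best = min(fits, key=lambda m: fits[m].chi2)
    return best, f"no model fits at alpha={alpha}; smallest chi2 ({fits[best].chi2:.2f})"


def _analyse_arm(
    records: pd.DataFrame, cfg: AnalysisConfig, k: int, label: str
) -> ArmResult:
    correlations = {}
    n_pairs = {}
    for zyg in ("MZ", "DZ"):
        table = double_enter(records, zyg, n_categories=k)
        n_pairs[zyg] = int(table.sum() // 2)
        if n_pairs[zyg] < cfg.min_pairs_per_group:
            raise ValueError(
                f"{label}: only {n_pairs[zyg]} {zyg} pairs, below the floor of "
                f"{cfg.min_pairs_per_group}"
            )
        correlations[zyg] = fit_polychoric(table, zygosity=zyg, n_pairs=n_pairs[zyg])
    corr = CorrelationPair(
        r_mz=correlations["MZ"].rho,
        r_dz=correlations["DZ"].rho,
        se_mz=correlations["MZ"].se_rho,
        se_dz=correlations["DZ"].se_rho,
        n_mz=n_pairs["MZ"],
        n_dz=n_pairs["DZ"],
    )
    fits = {name: fit_model(name, corr) for name in cfg.models}
    nested: dict[str, NestedTest] = {}
    for full_name, red_name in (("ADE", "AE"), ("ADE", "DE"), ("ADE", "E"),
                                ("ACE", "AE"), ("ACE", "CE")):
        if full_name in fits and red_name in fits:
            nested[f"{full_name} vs {red_name}"] = compare_nested(
                fits[full_name], fits[red_name]
            )
    best, reason = _select_best(fits, cfg.alpha)
    return ArmResult(
        label=label,
        correlations=correlations,
        corr_pair=corr,
        heritability=falconer_heritability(corr.r_mz, corr.r_dz),
        fits=fits,
        nested_tests=nested,
        best_model=best,
        best_model_reason=reason,
        n_pairs=n_pairs,
    )


def run_full_analysis(records: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Run the full two-group analysis and return a structured report."""
    counts = {"input_pairs": len(records)}
    counts["rejected_rows"] = int(records.attrs.get("n_rejected", 0))
    if config.balance:
        balanced = balanced_subsample(records, config.seed)
        counts["subsampled_out"] = len(records) - len(balanced)
        records = balanced
    counts["analysed_pairs"] = len(records)
    full = _analyse_arm(records, config, config.n_categories, "severe level included")
    restricted = None
    if config.severe_arm and config.n_categories > 2:
        sub = _restrict_severe(records, config.n_categories, config.severe_mode)
        counts["severe_arm_pairs"] = len(sub)
        k_sub = config.n_categories - 1
        if config.balance:
            sub = balanced_subsample(sub, config.seed)
            counts["severe_arm_balanced_pairs"] = len(sub)
        restricted = _analyse_arm(sub, config, k_sub, "severe level excluded")
    return AnalysisReport(config=config, counts=counts, full=full, restricted=restricted)


def write_report(report: AnalysisReport, out_dir) -> None:
    """Write correlations.csv, fits.csv, variance_components.csv, report.txt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corr_rows, fit_rows, vc_rows = [], [], []
    for arm in filter(None, (report.full, report.restricted)):
        for zyg, est in arm.correlations.items():
            corr_rows.append(
                {
                    "arm": arm.label,
                    "zygosity": zyg,
                    "n_pairs": arm.n_pairs[zyg],
                    "rho": est.rho,
                    "se_rho": est.se_rho,
                    **{f"tau{i + 1}": t for i, t in enumerate(est.tau_rows)},
                }
            )
        for name, fit in arm.fits.items():
            c = fit.components
            fit_rows.append(
                {
                    "arm": arm.label,
                    "model": name,
                    "a2": c.a2, "c2": c.c2, "d2": c.d2, "e2": c.e2,
                    "chi2": fit.chi2, "df": fit.df, "p": fit.p,
                    "boundary_flags": ";".join(sorted(fit.boundary_flags)),
                }
            )
        c = arm.fits["ADE"].components if "ADE" in arm.fits else arm.fits[arm.best_model].components
        vc_rows.append(
            {
                "arm": arm.label,
                "a": np.sqrt(c.a2), "c": np.sqrt(c.c2),
                "d": np.sqrt(c.d2), "e": np.sqrt(c.e2),
                "a2": c.a2, "c2": c.c2, "d2": c.d2, "e2": c.e2,
                "falconer_h2": arm.heritability,
            }
        )
    pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)
    pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
    pd.DataFrame(vc_rows).to_csv(out / "variance_components.csv", index=False)
    (out / "report.txt").write_text(report.to_text())
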