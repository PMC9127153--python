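"""Repeated-measures inference on the long ESS/Reynolds table.

Covers the full downstream analysis: mixed-effects ANOVA (delegated to
:mod:`carotidflow.mixedmodel`), Holm-corrected paired post-hoc comparisons
with paired Hedges' g effect sizes, summary-statistics t tests, bootstrap
coefficient-of-variation reliability, Shapiro-Wilk normality, and
per-condition Reynolds confidence intervals against the turbulence
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .mixedmodel import MixedModelResult, fit_mixed_model
from .synthetic import BASELINES, REST

__all__ = [
    "PairwiseResult",
    "ReliabilitySummary",
    "validate_long_dataset",
    "holm_adjust",
    "hedges_g_paired",
    "interpret_effect",
    "pairwise_comparisons",
    "t_from_summary",
    "cv_with_ci",
    "normality_check",
    "re_ci_summary",
    "analyze_dataset",
    "fit_mixed_model",
]

TURBULENCE_THRESHOLD = 2000.0


@dataclass(frozen=True)
class PairwiseResult:
    family: str
    level1: str
    level2: str
    t_stat: float
    p_raw: float
    p_adj: float
    hedges_g: float
    magnitude: str


@dataclass(frozen=True)
class ReliabilitySummary:
    cv: float
    ci_lower: float
    ci_upper: float
    interpretation: str


def validate_long_dataset(data: pd.DataFrame, response: str = "ess_mean_dyn_cm2") -> None:
    """Check the invariants of the long analysis table."""
    required = {"participant_id", "sex", "modality", "intensity", response}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"long dataset missing columns {sorted(missing)}")
    if data[response].isna().any():
        raise ValueError("long dataset contains missing response values")
    per_participant = data.groupby("participant_id").size()
    if (per_participant < 2).any():
        bad = per_participant[per_participant < 2].index.tolist()
        raise ValueError(f"participants with fewer than 2 conditions: {bad}")


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Step-down Holm adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    k = p.size
    order = np.argsort(p)
    adjusted = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (k - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def hedges_g_paired(x: np.ndarray, y: np.ndarray) -> float:
    """Paired standardized mean difference with small-sample correction.

    ``d = mean(x - y) / sd(x - y)`` (sample SD) scaled by
    ``J = 1 - 3 / (4 (n - 1) - 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0
        raise ValueError("zero variance of the paired differences")
    d = diff.mean() / sd
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    return float(d * j)


def interpret_effect(g: float) -> str:
    """Magnitude band of |g|: very small / small / moderate / large."""
    a = abs(g)
    if a < 0.2:
        return "very small"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "moderate"
    return "large"


def _paired_vectors(data: pd.DataFrame, response: str, factor: str, lev1: str, lev2: str):
    d1 = data[data[factor] == lev1].set_index("participant_id")[response]
    d2 = data[data[factor] == lev2].set_index("participant_id")[response]
    if d1.index.has_duplicates or d2.index.has_duplicates:
        raise ValueError(
            f"duplicate participant rows in comparison {lev1} vs {lev2}"
        )
    if set(d1.index) != set(d2.index):
        raise ValueError(
            f"unpaired participants in comparison {lev1} vs {lev2}: "
            f"{sorted(set(d1.index) ^ set(d2.index))}"
        )
    d2 = d2.reindex(d1.index)
    return d1.to_numpy(), d2.to_numpy()


def pairwise_comparisons(
    data: pd.DataFrame,
    family: str,
    response: str = "ess_mean_dyn_cm2",
) -> list[PairwiseResult]:
    """Paired t tests with Holm correction applied within each family.

    ``family="within_modality"``: one family per exercise modality, comparing
    intensities.  ``family="between_modality_at_intensity"``: one family per
    intensity, comparing modalities.
    """
    if family == "within_modality":
        group_by, compare = "modality", "intensity"
    elif family == "between_modality_at_intensity":
        group_by, compare = "intensity", "modality"
    else:
        raise ValueError(f"unknown family {family!r}")

    results: list[PairwiseResult] = []
    for group_label, block in data.groupby(group_by, sort=False):
        levels = list(dict.fromkeys(block[compare]))
        if len(levels) < 2:
            continue
        rows = []
        for lev1, lev2 in combinations(levels, 2):
            x, y = _paired_vectors(block, response, compare, lev1, lev2)
            if np.allclose(x, y):
                t_stat, p_raw = 0.0, 1.0
            else:
                t_stat, p_raw = stats.ttest_rel(x, y)
            rows.append((lev1, lev2, float(t_stat), float(p_raw), hedges_g_paired(x, y)))
        adjusted = holm_adjust(np.array([r[3] for r in rows]))
        for (lev1, lev2, t_stat, p_raw, g), p_adj in zip(rows, adjusted):
            results.append(
                PairwiseResult(
                    family=str(group_label),
                    level1=lev1,
                    level2=lev2,
                    t_stat=t_stat,
                    p_raw=p_raw,
                    p_adj=float(p_adj),
                    hedges_g=g,
                    magnitude=interpret_effect(g),
                )
            )
    return results


def pairwise_frame(results: list[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "level1": r.level1,
                "level2": r.level2,
                "t": r.t_stat,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "hedges_g": r.hedges_g,
                "magnitude": r.magnitude,
            }
            for r in results
        ]
    )


def t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Pooled-variance two-sample t test from group summaries.

    Returns ``(t, df, p_two_sided)`` with ``df = n1 + n2 - 2``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("standard deviations must be >= 0 and not both zero")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def cv_with_ci(
    values: np.ndarray, n_boot: int = 10_000, seed: int = 0
) -> ReliabilitySummary:
    """Coefficient of variation (%) with a seeded percentile-bootstrap 95% CI.

    Interpretation bands: < 10% very good, 10-20% good, 20-30% acceptable,
    >= 30% poor.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    cv = 100.0 * values.std(ddof=1) / mean
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    samples = values[idx]
    means = samples.mean(axis=1)
    sds = samples.std(ddof=1, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = 100.0 * sds / means
    boot = boot[np.isfinite(boot)]
    lower, upper = np.percentile(boot, [2.5, 97.5])
    return ReliabilitySummary(
        cv=float(cv),
        ci_lower=float(lower),
        ci_upper=float(upper),
        interpretation=_cv_band(cv),
    )


def _cv_band(cv: float) -> str:
    if cv < 10.0:
        return "very good"
    if cv < 20.0:
        return "good"
    if cv < 30.0:
        return "acceptable"
    return "poor"


def normality_check(residuals: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p value."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 3:
        raise ValueError("need at least 3 residuals")
    if np.ptp(residuals) == 0:
        raise ValueError("residuals are constant; normality test undefined")
    w, p = stats.shapiro(residuals)
    return float(w), float(p)


def re_ci_summary(data: pd.DataFrame, response: str = "reynolds") -> pd.DataFrame:
    """Per-condition mean Reynolds number with a t-based 95% CI.

    The ``turbulent`` flag requires the CI lower bound to clear the
    turbulence threshold of 2000.
    """
    rows = []
    for (modality, intensity), block in data.groupby(["modality", "intensity"], sort=False):
        values = block[response].to_numpy(dtype=float)
        if values.size < 2:
            raise ValueError(
                f"condition ({modality}, {intensity}) has a single observation"
            )
        mean = values.mean()
        se = values.std(ddof=1) / np.sqrt(values.size)
        half = stats.t.ppf(0.975, values.size - 1) * se
        rows.append(
            {
                "modality": modality,
                "intensity": intensity,
                "n": values.size,
                "mean_re": mean,
                "ci_lower": mean - half,
                "ci_upper": mean + half,
                "turbulent": bool(mean - half > TURBULENCE_THRESHOLD),
            }
        )
    return pd.DataFrame(rows)


def exercise_rows(data: pd.DataFrame) -> pd.DataFrame:
    return data[~data["modality"].isin(BASELINES)].copy()


def baseline_rows(data: pd.DataFrame) -> pd.DataFrame:
    return data[data["modality"].isin(BASELINES)].copy()


def analyze_dataset(
    data: pd.DataFrame,
    outdir: str | Path,
    seed: int = 0,
    n_boot: int = 10_000,
    df_method: str = "satterthwaite",
) -> dict:
    """Full inferential pipeline on a long results table.

    Writes ``anova.csv``, ``pairwise_within.csv``, ``pairwise_between.csv``,
    ``reliability.csv``, ``re_summary.csv`` and ``report.md`` into ``outdir``
    and returns the in-memory objects.
    """
    validate_long_dataset(data)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    exercise = exercise_rows(data)
    baseline = baseline_rows(data)
    if exercise["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants for the mixed model")

    model = fit_mixed_model(exercise, df_method=df_method)
    anova = model.anova_table()
    anova.to_csv(outdir / "anova.csv", index=False)

    within = pairwise_comparisons(exercise, "within_modality")
    between = pairwise_comparisons(exercise, "between_modality_at_intensity")
    within_frame = pairwise_frame(within)
    between_frame = pairwise_frame(between)
    within_frame.to_csv(outdir / "pairwise_within.csv", index=False)
    between_frame.to_csv(outdir / "pairwise_between.csv", index=False)

    reliability_rows = []
    if not baseline.empty:
        for label, column in (("ESS", "ess_mean_dyn_cm2"), ("Re", "reynolds")):
            summary = cv_with_ci(
                baseline[column].to_numpy(), n_boot=n_boot, seed=seed
            )
            reliability_rows.append(
                {
                    "measure": label,
                    "cv_percent": summary.cv,
                    "ci_lower": summary.ci_lower,
                    "ci_upper": summary.ci_upper,
                    "interpretation": summary.interpretation,
                }
            )
    reliability = pd.DataFrame(reliability_rows)
    reliability.to_csv(outdir / "reliability.csv", index=False)

    re_summary = re_ci_summary(exercise)
    re_summary.to_csv(outdir / "re_summary.csv", index=False)

    residuals = _model_residuals(exercise, model)
    w_stat, w_p = normality_check(residuals)

    report = _markdown_report(model, within_frame, between_frame, reliability, re_summary, w_stat, w_p)
    (outdir / "report.md").write_text(report, encoding="utf-8")

    return {
        "model": model,
        "anova": anova,
        "pairwise_within": within_frame,
        "pairwise_between": between_frame,
        "reliability": reliability,
        "re_summary": re_summary,
        "normality": (w_stat, w_p),
    }


def _model_residuals(data: pd.DataFrame, model: MixedModelResult) -> np.ndarray:
    """Marginal residuals: observed minus the fitted condition/sex cell mean."""
    fitted = data.groupby(["modality", "intensity", "sex"])[
        "ess_mean_dyn_cm2"
    ].transform("mean")
    return (data["ess_mean_dyn_cm2"] - fitted).to_numpy()


def _md_table(frame: pd.DataFrame) -> str:
    """Minimal GitHub-style markdown rendering of a DataFrame."""
    cells = frame.copy()
    for col in cells.columns:
        if pd.api.types.is_float_dtype(cells[col]):
            cells[col] = cells[col].map(lambda v: f"{v:.3f}")
    cells = cells.astype(str)
    header = "| " + " | ".join(cells.columns) + " |"
    rule = "| " + " | ".join("---" for _ in cells.columns) + " |"
    body = ["| " + " | ".join(row) + " |" for row in cells.itertuples(index=False)]
    return "\n".join([header, rule, *body])


def _markdown_report(model, within, between, reliability, re_summary, w_stat, w_p) -> str:
    lines = ["# Carotid flow analysis report", ""]
    lines.append("## Mixed-effects ANOVA (ESS)")
    lines.append("")
    lines.append(_md_table(model.anova_table()))
    lines.append("")
    lines.append(
        f"Random-intercept variance {model.random_intercept_var:.3f}, "
        f"residual variance {model.residual_var:.3f} "
        f"({model.n_obs} observations, {model.n_groups} participants)."
    )
    lines.append("")
    lines.append(f"Shapiro-Wilk on residuals: W = {w_stat:.3f}, p = {w_p:.3f}.")
    lines.append("")
    if not reliability.empty:
        lines.append("## Baseline reliability (CV)")
        lines.append("")
        lines.append(_md_table(reliability))
        lines.append("")
    lines.append("## Pairwise comparisons within modality")
    lines.append("")
    lines.append(_md_table(within))
    lines.append("")
    lines.append("## Pairwise comparisons between modalities")
    lines.append("")
    lines.append(_md_table(between))
    lines.append("")
    lines.append("## Reynolds number by condition")
    lines.append("")
    lines.append(_md_table(re_summary))
    lines.append("")
    n_turb = int(re_summary["turbulent"].sum())
    lines.append(
        f"{n_turb} of {len(re_summary)} exercise conditions have a 95% CI "
        f"entirely above the turbulence threshold (Re > {TURBULENCE_THRESHOLD:.0f})."
    )
    lines.append("")
    return "\n".join(lines)
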