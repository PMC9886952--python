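"""Classical averaged-RT analyses.

Two-way mixed-design ANOVAs (within: distractor condition, between: task)
with Mauchly sphericity testing and Greenhouse-Geisser correction, planned
within-group contrasts on per-participant difference scores, and paired
t-tests for the intertrial-priming control.  The ANOVA decomposition is
delegated to pingouin; the contrast is the one-sample-on-differences form
(F with df 1, n-1, identical to the squared paired t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "EffectResult",
    "AnovaResult",
    "ContrastResult",
    "mixed_anova",
    "planned_contrast",
    "paired_t",
    "normality_report",
]


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float
    gg_epsilon: float | None = None
    mauchly_p: float | None = None
    p_gg: float | None = None

    def __str__(self) -> str:
        s = (f"F({self.df_num:g},{self.df_den:g}) = {self.F:.2f}, "
             f"p = {self.p:.4g}, pes = {self.partial_eta_sq:.3f}")
        if self.gg_epsilon is not None:
            s += f" (GG eps = {self.gg_epsilon:.3f}, Mauchly p = {self.mauchly_p:.3g})"
        return s


@dataclass(frozen=True)
class AnovaResult:
    """Within, between and interaction effects of a mixed-design ANOVA.

    When sphericity is rejected (Mauchly p < 0.05 with 3 within levels) the
    within and interaction p-values are Greenhouse-Geisser corrected while
    the uncorrected degrees of freedom are reported alongside.
    """

    within: EffectResult
    between: EffectResult
    interaction: EffectResult
    sphericity_corrected: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for name in ("within", "between", "interaction"):
            e: EffectResult = getattr(self, name)
            rows[name] = {
                "F": e.F, "df_num": e.df_num, "df_den": e.df_den, "p": e.p,
                "partial_eta_sq": e.partial_eta_sq,
                "gg_epsilon": e.gg_epsilon, "mauchly_p": e.mauchly_p,
            }
        return pd.DataFrame(rows).T


def _check_balanced(cells: pd.DataFrame, dv: str, within: str,
                    between: str, subject: str) -> None:
    counts = cells.groupby(subject, observed=True)[within].nunique()
    k = cells[within].nunique()
    bad = counts.index[counts != k].tolist()
    if bad:
        raise ValueError(f"participants with missing within-cells: {bad}")
    groups = cells.groupby(subject, observed=True)[between].nunique()
    bad = groups.index[groups != 1].tolist()
    if bad:
        raise ValueError(f"participants in more than one group: {bad}")
    if cells.groupby([subject, within], observed=True)[dv].size().gt(1).any():
        raise ValueError("expected one cell mean per participant x level")


def mixed_anova(cells: pd.DataFrame, dv: str = "mean_rt",
                within: str = "condition", between: str = "task",
                subject: str = "participant_id",
                alpha_sphericity: float = 0.05) -> AnovaResult:
    """Two-way mixed-design ANOVA on per-participant cell means."""
    _check_balanced(cells, dv, within, between, subject)
    k = cells[within].nunique()
    res = pg.mixed_anova(data=cells, dv=dv, within=within, subject=subject,
                         between=between, correction=True).set_index("Source")
    wrow = res.loc[within]
    brow = res.loc[between]
    irow = res.loc["Interaction"]

    gg_epsilon = mauchly_p = None
    corrected = False
    if k >= 3:
        sph = pg.sphericity(cells, dv=dv, subject=subject, within=within)
        mauchly_p = float(sph.pval)
        gg_epsilon = float(wrow["eps"])
        corrected = mauchly_p < alpha_sphericity

    def effect(row, use_gg: bool) -> EffectResult:
        p = float(row["p_GG_corr"]) if use_gg and pd.notna(
            row.get("p_GG_corr", np.nan)) else float(row["p_unc"])
        return EffectResult(
            F=float(row["F"]), df_num=float(row["DF1"]),
            df_den=float(row["DF2"]), p=p,
            partial_eta_sq=float(row["np2"]),
            gg_epsilon=gg_epsilon if row.name == within else None,
            mauchly_p=mauchly_p if row.name == within else None,
            p_gg=float(row["p_GG_corr"]) if pd.notna(
                row.get("p_GG_corr", np.nan)) else None,
        )

    return AnovaResult(
        within=effect(wrow, corrected),
        between=effect(brow, False),
        interaction=effect(irow, corrected),
        sphericity_corrected=corrected,
    )


@dataclass(frozen=True)
class ContrastResult:
    mean_diff: float
    sem: float
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float

    def __str__(self) -> str:
        return (f"dM = {self.mean_diff:.2f} ms, SEM = {self.sem:.2f}, "
                f"F({self.df_num},{self.df_den}) = {self.F:.2f}, p = {self.p:.4g}")


def planned_contrast(cells: pd.DataFrame, level_a: str, level_b: str,
                     group: str | None = None, dv: str = "mean_rt",
                     within: str = "condition", between: str = "task",
                     subject: str = "participant_id") -> ContrastResult:
    """Within-group repeated-measures contrast (level_a minus level_b).

    Per-participant difference scores are tested against zero; F has
    (1, n - 1) degrees of freedom and equals the squared paired t.
    """
    df = cells if group is None else cells.loc[cells[between] == group]
    wide = df.pivot_table(index=subject, columns=within, values=dv,
                          observed=True)
    if level_a not in wide or level_b not in wide:
        raise ValueError(f"levels {level_a!r}/{level_b!r} not in {within!r}")
    diff = (wide[level_a] - wide[level_b]).dropna().to_numpy()
    n = diff.size
    if n < 2:
        raise ValueError("need at least 2 participants for a contrast")
    mean = float(diff.mean())
    sem = float(diff.std(ddof=1) / np.sqrt(n))
    if sem == 0:
        F = 0.0 if mean == 0 else np.inf
    else:
        F = (mean / sem) ** 2
    p = float(stats.f.sf(F, 1, n - 1))
    pes = float(F / (F + (n - 1))) if np.isfinite(F) else 1.0
    return ContrastResult(mean_diff=mean, sem=sem, F=float(F), df_num=1,
                          df_den=n - 1, p=p, partial_eta_sq=pes)


def paired_t(scores_a, scores_b) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


def normality_report(cells: pd.DataFrame, dv: str = "mean_rt",
                     within: str = "condition", between: str = "task"
                     ) -> pd.DataFrame:
    """Shapiro-Wilk per within x between cell (reported, never gating)."""
    rows = []
    for (w, b), sub in cells.groupby([within, between], observed=True):
        if len(sub) >= 3:
            stat, p = stats.shapiro(sub[dv])
            rows.append((w, b, len(sub), stat, p))
    return pd.DataFrame(rows, columns=[within, between, "n", "W", "p"])
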