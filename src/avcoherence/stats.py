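"""Group-level inference: 2 x 3 mixed ANOVA and post hoc comparisons.

The design has one between-subjects factor (auditory event type: pitch or
timbre group) and one within-subjects factor (audio-visual coherence
condition: match-target / match-masker / match-neither).  For a balanced
complete table the classical split-plot sums-of-squares decomposition
applies:

* between-subjects stratum — event type tested against subjects nested
  in groups, df (a-1, N-a);
* within-subjects stratum — coherence and the interaction tested against
  the condition x subject-within-group residual, df (b-1, (b-1)(N-a));
* the intercept (grand mean vs 0) tested against the between-subjects
  error, df (1, N-a) — this carries the "observers are conservative"
  test when the response variable is ln(beta).

With 16 + 16 subjects and 3 conditions that yields the familiar
F(1, 30) / F(2, 60) df structure.  No sphericity correction is applied
by default; Greenhouse-Geisser is available as an option.  Post hoc
condition contrasts are two-sided paired t tests pooled over both
groups, judged at the Bonferroni-corrected alpha 0.05 / 3 ~= 0.017.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import ttest_rel

from .scheduler import CONDITIONS

__all__ = [
    "AnovaTable",
    "PosthocResult",
    "AnalysisReport",
    "mixed_anova",
    "posthoc_pairwise",
    "normalize_within_subject",
    "run_full_analysis",
    "BONFERRONI_ALPHA",
    "MEASURES",
]

ALPHA = 0.05
BONFERRONI_ALPHA = ALPHA / 3  # three pairwise condition contrasts
MEASURES = ("d_prime", "ln_beta", "hit_rate", "fa_rate", "visual_hit_rate")
EFFECTS = ("intercept", "group", "condition", "interaction")


@dataclass(frozen=True)
class AnovaTable:
    """Mixed-ANOVA decomposition: one row per effect.

    ``table`` has columns effect, ss, df1, df2, F, p.
    """

    table: pd.DataFrame
    alpha: float = ALPHA

    def row(self, effect: str) -> pd.Series:
        return self.table.set_index("effect").loc[effect]

    def F(self, effect: str) -> float:
        return float(self.row(effect)["F"])

    def p(self, effect: str) -> float:
        return float(self.row(effect)["p"])

    def significant(self, effect: str) -> bool:
        return self.p(effect) < self.alpha


@dataclass(frozen=True)
class PosthocResult:
    """One paired condition contrast."""

    pair: Tuple[str, str]
    mean_difference: float
    t: float
    p: float
    corrected_alpha: float = BONFERRONI_ALPHA

    @property
    def significant(self) -> bool:
        return self.p < self.corrected_alpha


def _validate_table(
    df: pd.DataFrame, subject: str, within: str, between: str, dv: str
) -> None:
    counts = df.groupby([subject, within], observed=True)[dv].count().unstack()
    if counts.isna().any().any() or (counts != 1).any().any():
        raise ValueError("every subject must contribute exactly one value per condition")
    groups = df.groupby(subject, observed=True)[between].nunique()
    if (groups != 1).any():
        raise ValueError("each subject must belong to exactly one group")
    if df.groupby(between, observed=True)[subject].nunique().min() < 2:
        raise ValueError("need at least 2 subjects per group")


def mixed_anova(
    df: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: str = "condition",
    between: str = "group",
    *,
    gg_correction: bool = False,
) -> AnovaTable:
    """Classical split-plot decomposition of a complete balanced table.

    Parameters name the columns of the long-format ``df``.  Condition and
    interaction p-values optionally receive a Greenhouse-Geisser
    epsilon correction (off by default; the reference analysis reports
    uncorrected degrees of freedom).
    """
    _validate_table(df, subject, within, between, dv)
    y = df[dv].astype(float)
    grand = y.mean()
    n_total = len(df)
    subj_mean = df.groupby(subject, observed=True)[dv].mean()
    group_of = df.groupby(subject, observed=True)[between].first()
    group_mean = df.groupby(between, observed=True)[dv].mean()
    cond_mean = df.groupby(within, observed=True)[dv].mean()
    cell_mean = df.groupby([between, within], observed=True)[dv].mean()
    n_subjects = len(subj_mean)
    a = group_mean.size
    b = cond_mean.size
    n_per_group = df.groupby(between, observed=True)[subject].nunique()

    ss_between_subj = b * ((subj_mean - grand) ** 2).sum()
    ss_group = b * (n_per_group * (group_mean - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    df_subj_within = n_subjects - a

    ss_cond = n_subjects * ((cond_mean - grand) ** 2).sum()
    inter_dev = cell_mean.copy()
    for (g, c) in inter_dev.index:
        inter_dev.loc[(g, c)] = (
            cell_mean.loc[(g, c)] - group_mean.loc[g] - cond_mean.loc[c] + grand
        )
    ss_inter = (
        n_per_group.reindex(inter_dev.index.get_level_values(0)).to_numpy()
        * inter_dev.to_numpy() ** 2
    ).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_within_total = ss_total - ss_between_subj
    ss_err_within = ss_within_total - ss_cond - ss_inter
    df_err_within = (b - 1) * (n_subjects - a)

    ss_intercept = n_total * grand**2

    ms_subj = ss_subj_within / df_subj_within
    ms_err = ss_err_within / df_err_within
    rows = [
        ("intercept", ss_intercept, 1, df_subj_within, ss_intercept / ms_subj),
        ("group", ss_group, a - 1, df_subj_within, (ss_group / (a - 1)) / ms_subj),
        ("condition", ss_cond, b - 1, df_err_within, (ss_cond / (b - 1)) / ms_err),
        (
            "interaction", ss_inter, (a - 1) * (b - 1), df_err_within,
            (ss_inter / ((a - 1) * (b - 1))) / ms_err,
        ),
    ]
    eps = 1.0
    if gg_correction:
        eps = _gg_epsilon(df, dv, subject, within)
    records = []
    for effect, ss, df1, df2, F in rows:
        e = eps if effect in ("condition", "interaction") else 1.0
        p = float(f_dist.sf(F, df1 * e, df2 * e))
        records.append(dict(effect=effect, ss=float(ss), df1=df1, df2=df2, F=float(F), p=p))
    return AnovaTable(table=pd.DataFrame(records))


def _gg_epsilon(df: pd.DataFrame, dv: str, subject: str, within: str) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-subject covariance."""
    wide = df.pivot(index=subject, columns=within, values=dv)
    s = np.cov(wide.to_numpy(), rowvar=False)
    k = s.shape[0]
    mean_diag = np.trace(s) / k
    num = (k * (mean_diag - s.mean())) ** 2
    den = (k - 1) * ((s**2).sum() - 2 * k * (s.mean(axis=1) ** 2).sum() + k**2 * s.mean() ** 2)
    return float(num / den)


def posthoc_pairwise(
    df: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: str = "condition",
    pairs: Sequence[Tuple[str, str]] | None = None,
    corrected_alpha: float = BONFERRONI_ALPHA,
) -> List[PosthocResult]:
    """Two-sided paired t tests across all subjects (groups pooled)."""
    wide = df.pivot(index=subject, columns=within, values=dv)
    if len(wide) < 2:
        raise ValueError("need at least 2 subjects for a paired comparison")
    if pairs is None:
        pairs = list(combinations([c for c in CONDITIONS if c in wide.columns], 2))
    out = []
    for a_, b_ in pairs:
        x, yv = wide[a_].to_numpy(), wide[b_].to_numpy()
        if np.allclose(x, yv):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = ttest_rel(x, yv)
        out.append(
            PosthocResult(
                pair=(a_, b_), mean_difference=float(np.mean(x - yv)),
                t=float(t_stat), p=float(p), corrected_alpha=corrected_alpha,
            )
        )
    return out


def normalize_within_subject(
    df: pd.DataFrame, dv: str = "value", subject: str = "subject"
) -> pd.DataFrame:
    """Subtract each subject's overall mean from their values.

    This is the within-subject view used for condition-effect summaries:
    between-subject ability differences (and the pitch/timbre difficulty
    gap) are removed, leaving each subject's condition pattern.
    """
    out = df.copy()
    out[dv] = df[dv] - df.groupby(subject, observed=True)[dv].transform("mean")
    return out


@dataclass(frozen=True)
class AnalysisReport:
    """ANOVAs for all five behavioral measures, plus gated post hocs."""

    anovas: Dict[str, AnovaTable]
    posthocs: Dict[str, List[PosthocResult]]
    alpha: float = ALPHA

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for measure, tab in self.anovas.items():
            t = tab.table.copy()
            t.insert(0, "measure", measure)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "anovas": {
                m: t.table.to_dict(orient="records") for m, t in self.anovas.items()
            },
            "posthocs": {
                m: [
                    dict(
                        pair=list(r.pair), mean_difference=r.mean_difference,
                        t=r.t, p=r.p, corrected_alpha=r.corrected_alpha,
                        significant=r.significant,
                    )
                    for r in res
                ]
                for m, res in self.posthocs.items()
            },
        }


def run_full_analysis(
    results: pd.DataFrame,
    measures: Sequence[str] = MEASURES,
    alpha: float = ALPHA,
) -> AnalysisReport:
    """Mixed ANOVA per measure; post hocs only where coherence is significant.

    ``results`` is the long-format scoring table (columns subject, task,
    condition, and the measure columns).  Pairwise condition contrasts
    are computed only for measures whose within-subjects coherence effect
    reaches ``alpha``, mirroring the gating of the reference analysis.
    """
    anovas: Dict[str, AnovaTable] = {}
    posthocs: Dict[str, List[PosthocResult]] = {}
    for m in measures:
        tab = mixed_anova(
            results, dv=m, subject="subject", within="condition", between="task"
        )
        anovas[m] = tab
        if tab.p("condition") < alpha:
            posthocs[m] = posthoc_pairwise(results, dv=m)
    return AnalysisReport(anovas=anovas, posthocs=posthocs, alpha=alpha)
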