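"""Repeated-measures comparison of fitted a-wave parameters.

One-way within-subject ANOVA (subjects × conditions, complete design,
no sphericity correction) followed by a Tukey HSD on the within-subject
error term: for conditions a, b the studentized statistic is

    q_ab = |mean_a - mean_b| / sqrt(MS_error / n)

with p from the studentized-range distribution on (k, df_error).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

ALPHA = 0.05  # significance threshold for the post-hoc flags


@dataclass
class RMAnovaResult:
    f_statistic: float
    df_condition: int
    df_error: int
    p_value: float
    grand_mean: float
    condition_means: dict[str, float]
    ss_condition: float
    ss_subject: float
    ss_error: float
    ms_error: float
    n_subjects: int


@dataclass(frozen=True)
class TukeyPair:
    condition_a: str
    condition_b: str
    mean_difference: float
    q_statistic: float
    p_adjusted: float
    significant: bool


@dataclass
class TukeyResult:
    pairs: list[TukeyPair]
    alpha: float = ALPHA

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition_a": p.condition_a,
                    "condition_b": p.condition_b,
                    "mean_difference": p.mean_difference,
                    "q_statistic": p.q_statistic,
                    "p_adjusted": p.p_adjusted,
                    "significant": p.significant,
                }
                for p in self.pairs
            ]
        )


def _as_matrix(values, condition_labels=None):
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValidationError("values must be a 2-D subject × condition matrix")
    n, k = m.shape
    if n < 2:
        raise ValidationError(f"need >= 2 subjects, got {n}")
    if k < 2:
        raise ValidationError(f"need >= 2 conditions, got {k}")
    if not np.all(np.isfinite(m)):
        raise ValidationError("missing or non-finite cells; complete design required")
    if condition_labels is None:
        condition_labels = [f"C{j + 1}" for j in range(k)]
    if len(condition_labels) != k:
        raise ValidationError("condition_labels length must match column count")
    return m, list(condition_labels)


def rm_anova(values, condition_labels: Sequence[str] | None = None) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a subject × condition matrix.

    Decomposes SS_total into condition, subject and error sums of
    squares; F = MS_condition / MS_error with (k-1, (k-1)(n-1)) degrees
    of freedom.  Identical columns give F = 0, p = 1 by convention.
    """
    m, labels = _as_matrix(values, condition_labels)
    n, k = m.shape
    grand = m.mean()
    cond_means = m.mean(axis=0)
    subj_means = m.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_c, df_e = k - 1, (k - 1) * (n - 1)
    ms_c, ms_e = ss_cond / df_c, max(ss_err, 0.0) / df_e

    scale = max(ss_total, 1.0)
    if ss_cond <= 1e-12 * scale:
        f_stat, p = 0.0, 1.0
    elif ms_e <= 1e-12 * scale:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = ms_c / ms_e
        p = float(sps.f.sf(f_stat, df_c, df_e))
    return RMAnovaResult(
        f_statistic=float(f_stat),
        df_condition=df_c,
        df_error=df_e,
        p_value=p,
        grand_mean=float(grand),
        condition_means=dict(zip(labels, cond_means.astype(float))),
        ss_condition=ss_cond,
        ss_subject=ss_subj,
        ss_error=ss_err,
        ms_error=ms_e,
        n_subjects=n,
    )


def tukey_hsd(
    values,
    rm_result: RMAnovaResult | None = None,
    condition_labels: Sequence[str] | None = None,
    alpha: float = ALPHA,
) -> TukeyResult:
    """All-pairs Tukey HSD using the within-subject MS_error."""
    m, labels = _as_matrix(values, condition_labels)
    n, k = m.shape
    if rm_result is None:
        rm_result = rm_anova(m, labels)
    ms_e, df_e = rm_result.ms_error, rm_result.df_error
    se = np.sqrt(ms_e / n)
    cond_means = m.mean(axis=0)
    pairs = []
    for ia, ib in combinations(range(k), 2):
        diff = float(cond_means[ia] - cond_means[ib])
        if se <= 0:
            q = 0.0 if abs(diff) < 1e-12 else np.inf
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_e)) if np.isfinite(q) else 0.0
        if q == 0.0:
            p = 1.0
        pairs.append(
            TukeyPair(
                condition_a=labels[ia],
                condition_b=labels[ib],
                mean_difference=diff,
                q_statistic=float(q),
                p_adjusted=p,
                significant=p < alpha,
            )
        )
    return TukeyResult(pairs=pairs, alpha=alpha)


PARAM_COLUMNS = ("r_max_uv", "s", "t_d_ms")


def parameter_comparison_report(
    fit_tables: Mapping[str, pd.DataFrame],
    parameters: Sequence[str] = PARAM_COLUMNS,
    alpha: float = ALPHA,
) -> dict[str, dict]:
    """RM-ANOVA + Tukey HSD per fitted parameter across condition labels.

    ``fit_tables`` maps a condition label (e.g. ``"SF"``, ``"LF-0"``,
    ``"LF-0.01"`` ...) to a one-row-per-subject fit table containing
    ``subject_id`` and the parameter columns.  Every condition must
    cover the same subjects (complete design).  Returns, per parameter,
    the ANOVA result, Tukey result and tidy frames ready for CSV.
    """
    if len(fit_tables) < 2:
        raise ValidationError("need at least two conditions to compare")
    labels = list(fit_tables)
    subjects = None
    for label, table in fit_tables.items():
        if "subject_id" not in table.columns:
            raise ValidationError(f"fit table {label!r} lacks subject_id")
        ids = sorted(table["subject_id"].astype(str))
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate subjects in condition {label!r}")
        if subjects is None:
            subjects = ids
        elif ids != subjects:
            raise ValidationError(
                f"condition {label!r} covers subjects {ids}, expected {subjects}"
            )
    if len(subjects) < 2:
        raise ValidationError("need >= 2 subjects for a repeated-measures comparison")

    report: dict[str, dict] = {}
    for param in parameters:
        cols = []
        for label in labels:
            table = fit_tables[label]
            if param not in table.columns:
                raise ValidationError(f"fit table {label!r} lacks column {param!r}")
            col = (
                table.assign(subject_id=table["subject_id"].astype(str))
                .set_index("subject_id")[param]
                .loc[subjects]
                .to_numpy(dtype=float)
            )
            cols.append(col)
        matrix = np.column_stack(cols)
        anova = rm_anova(matrix, labels)
        tukey = tukey_hsd(matrix, anova, labels, alpha=alpha)
        report[param] = {
            "anova": anova,
            "tukey": tukey,
            "anova_frame": pd.DataFrame(
                [
                    {
                        "parameter": param,
                        "f_statistic": anova.f_statistic,
                        "df_condition": anova.df_condition,
                        "df_error": anova.df_error,
                        "p_value": anova.p_value,
                        **{f"mean_{lbl}": v for lbl, v in anova.condition_means.items()},
                    }
                ]
            ),
            "tukey_frame": tukey.to_frame().assign(parameter=param),
        }
    return report
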