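"""Trial-level cleaning, participant exclusion, and dependent-measure scoring.

Nine tasks feed the factor models: three inhibiting tasks (anti-saccade,
stop-signal, color-word Stroop), three updating tasks (keep-track, letter
3-back, spatial 2-back) and three shifting tasks (number-letter, color-shape,
category-switch).  The module turns raw trial tables into a subjects x 9
score table in which every measure is oriented so that a higher value means
higher ability, transformed (arcsine / logit / d-prime), truncated at the
median +/- 1.5 IQR fences, and residualized on age and sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# task kinds and their scoring rules
RT_DIFF_TASKS = {
    "stroop": ("incongruent", "congruent"),
    "number_letter": ("switch", "repeat"),
    "color_shape": ("switch", "repeat"),
    "category_switch": ("switch", "repeat"),
}
NBACK_TASKS = {"letter_3back", "spatial_2back"}
#: measures whose raw value is an RT cost (negated at finalize)
RT_BASED_MEASURES = ("ssrt", "stroop", "number_letter", "color_shape", "category_switch")

TASKS = (
    "antisaccade",
    "ssrt",
    "stroop",
    "keep_track",
    "letter_3back",
    "spatial_2back",
    "number_letter",
    "color_shape",
    "category_switch",
)

#: chance accuracy per task, used by the binomial exclusion rule
CHANCE_RATE = {
    "antisaccade": 1.0 / 3.0,
    "stop_signal": 0.5,
    "stroop": 0.25,
    "number_letter": 0.5,
    "color_shape": 0.5,
    "category_switch": 0.5,
    "letter_3back": 0.5,
    "spatial_2back": 0.5,
}


@dataclass
class CleanReport:
    """Bookkeeping from trial cleaning and participant exclusion."""

    n_removed_fast: int = 0
    n_removed_iqr: int = 0
    excluded_no_response: list = field(default_factory=list)
    excluded_accuracy: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def excluded_subjects(self) -> set:
        return set(self.excluded_no_response) | set(self.excluded_accuracy)


def exclusion_threshold(n_trials: int, chance_rate: float) -> int:
    """Minimum correct count: the 95% quantile of Binomial(n_trials, chance_rate).

    Returns the smallest k with P(X <= k) >= 0.95.  A participant scoring at
    or below chance would rarely reach this count, so fewer correct trials
    flags off-task responding.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0 < chance_rate < 1:
        raise ValueError("chance_rate must lie strictly between 0 and 1")
    return int(stats.binom.ppf(0.95, n_trials, chance_rate))


def _iqr_fences(values: np.ndarray) -> tuple[float, float]:
    """Tukey fences Q1-1.5*IQR, Q3+1.5*IQR (type-7 linear quartiles)."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def clean_trials(trials: pd.DataFrame, task_kind: str) -> tuple[pd.DataFrame, CleanReport]:
    """Remove implausible trials and flag off-task participants.

    All tasks drop trials with RT < 100 ms.  RT-dependent tasks additionally
    drop trials outside the per-subject Tukey fences.  Subjects with >20%
    no-response trials or a correct count below the binomial threshold are
    flagged in the report and must be excluded from scoring.
    """
    report = CleanReport()
    if trials.empty:
        report.warnings.append("empty trial table")
        return trials.copy(), report

    df = trials.copy()
    n_total_per_subj = df.groupby("subject").size()
    no_resp = df.groupby("subject")["rt_ms"].apply(lambda s: s.isna().mean())
    report.excluded_no_response = sorted(no_resp.index[no_resp > 0.20])

    # 100 ms rule (responses only)
    fast = df["rt_ms"].notna() & (df["rt_ms"] < 100)
    report.n_removed_fast = int(fast.sum())
    df = df[~fast]

    if task_kind in ("generic_rt", "stop_signal", *RT_DIFF_TASKS):
        keep = np.ones(len(df), dtype=bool)
        rt = df["rt_ms"].to_numpy()
        for _, idx in df.groupby("subject").indices.items():
            rts = rt[idx]
            obs = ~np.isnan(rts)
            if obs.sum() < 2:
                continue
            lo, hi = _iqr_fences(rts[obs])
            bad = obs & ((rts < lo) | (rts > hi))
            keep[idx[bad]] = False
        report.n_removed_iqr = int((~keep).sum())
        df = df[keep]

    # binomial accuracy exclusion on the full trial count
    chance = CHANCE_RATE.get(task_kind, 0.5)
    n_correct = trials.groupby("subject")["correct"].sum()
    for subj, n_tr in n_total_per_subj.items():
        if n_correct.get(subj, 0) < exclusion_threshold(int(n_tr), chance):
            report.excluded_accuracy.append(subj)
    report.excluded_accuracy.sort()
    return df, report


def compute_ssrt(stop_trials: pd.DataFrame) -> tuple[float, list[str]]:
    """Stop-signal reaction time by the integration (percentile) method.

    p is the proportion of No-go trials on which the participant failed to
    stop; SSRT = p-th percentile (nearest rank) of the correct-Go RT
    distribution minus the mean stop-signal delay over No-go trials.  The
    method does not assume the stop rate is exactly 0.5.
    """
    warnings: list[str] = []
    go = stop_trials[stop_trials["condition"] == "go"]
    nogo = stop_trials[stop_trials["condition"] == "nogo"]
    go_rts = go.loc[go["correct"].astype(bool) & go["rt_ms"].notna(), "rt_ms"].to_numpy()
    if len(go_rts) == 0 or len(nogo) == 0:
        raise ValueError("need at least one correct Go trial and one No-go trial")
    p = float(nogo["rt_ms"].notna().mean())
    if p in (0.0, 1.0):
        warnings.append(f"stop-failure rate {p:g}: SSRT unreliable")
    srt = np.sort(go_rts)
    rank = min(max(int(np.ceil(p * len(srt))), 1), len(srt))
    percentile_rt = srt[rank - 1]
    ssrt = float(percentile_rt - nogo["ssd_ms"].mean())
    return ssrt, warnings


def dprime(hit_rate: float, fa_rate: float, n_signal: int, n_noise: int) -> float:
    """Signal-detection d' = z(hit) - z(FA), rates clamped to [1/(2N), 1-1/(2N)]."""

    def clamp(r, n):
        return min(max(r, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))

    return float(stats.norm.ppf(clamp(hit_rate, n_signal)) - stats.norm.ppf(clamp(fa_rate, n_noise)))


def score_task(clean: pd.DataFrame, task_kind: str) -> pd.Series:
    """Raw dependent measure per subject for one task.

    RTs are averaged over correct trials only.  Subjects lacking a required
    condition get a missing value.
    """
    out = {}
    for subj, sub in clean.groupby("subject"):
        out[subj] = _score_one(sub, task_kind)
    return pd.Series(out, name=task_kind, dtype=float)


def _score_one(sub: pd.DataFrame, task_kind: str) -> float:
    if task_kind == "antisaccade":
        return float(1.0 - sub["correct"].mean())  # percent error
    if task_kind == "stop_signal":
        try:
            ssrt, _ = compute_ssrt(sub)
        except ValueError:
            return np.nan
        return ssrt
    if task_kind in RT_DIFF_TASKS:
        hard, easy = RT_DIFF_TASKS[task_kind]
        corr = sub[sub["correct"].astype(bool) & sub["rt_ms"].notna()]
        rt_hard = corr.loc[corr["condition"] == hard, "rt_ms"]
        rt_easy = corr.loc[corr["condition"] == easy, "rt_ms"]
        if rt_hard.empty or rt_easy.empty:
            return np.nan
        return float(rt_hard.mean() - rt_easy.mean())
    if task_kind == "keep_track":
        return float(sub["correct"].sum())
    if task_kind in NBACK_TASKS:
        sig = sub[sub["condition"] == "match"]
        noi = sub[sub["condition"] == "nonmatch"]
        if sig.empty or noi.empty:
            return np.nan
        hit = float(sig["correct"].mean())  # correct on match = hit
        fa = float(1.0 - noi["correct"].mean())  # error on nonmatch = false alarm
        return dprime(hit, fa, len(sig), len(noi))
    raise ValueError(f"unknown task kind: {task_kind!r}")


def _truncate_column(col: pd.Series) -> pd.Series:
    """Clip to [median - 1.5 IQR, median + 1.5 IQR] (fences about the median)."""
    obs = col.dropna()
    if obs.empty:
        return col
    med = obs.median()
    q1, q3 = obs.quantile([0.25, 0.75])
    iqr = q3 - q1
    return col.clip(lower=med - 1.5 * iqr, upper=med + 1.5 * iqr)


def finalize_scores(raw: pd.DataFrame, keep_track_max: int = 36) -> pd.DataFrame:
    """Orient, transform, and truncate raw measures into the 9-column score table.

    RT-based measures (SSRT and the four RT-difference costs) are negated so
    higher = better.  Anti-saccade error rate becomes arcsine-sqrt accuracy;
    the keep-track count becomes a logit of the proportion correct (with a
    0.5-count continuity adjustment at the boundaries); n-back d' values pass
    through.  Finally every column is truncated at median +/- 1.5 IQR.
    """
    out = pd.DataFrame(index=raw.index)
    for task in raw.columns:
        col = raw[task].astype(float)
        if task == "antisaccade":
            acc = (1.0 - col).clip(0.0, 1.0)
            col = np.arcsin(np.sqrt(acc))
        elif task == "keep_track":
            prop = (col.clip(0, keep_track_max) + 0.5) / (keep_track_max + 1.0)
            col = np.log(prop / (1.0 - prop))
        elif task in RT_BASED_MEASURES or task == "stop_signal":
            col = -col
        out[task] = _truncate_column(col)
    return out


def residualize_scores(scores: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Regress each score column on intercept + covariates; z-score the residuals.

    OLS is fit per column on its non-missing cases.  Residuals are
    standardized to mean 0, SD 1; a zero-variance residual column is left
    unstandardized (degenerate fit).
    """
    cov = covariates.loc[scores.index]
    X = np.column_stack([np.ones(len(cov)), cov.to_numpy(float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    out = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    for c in scores.columns:
        y = scores[c].to_numpy(float)
        obs = ~np.isnan(y)
        if obs.sum() <= X.shape[1]:
            out[c] = np.nan
            continue
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        resid = y[obs] - X[obs] @ beta
        sd = resid.std(ddof=0)
        if sd > 1e-12:
            resid = (resid - resid.mean()) / sd
        vals = np.full(len(y), np.nan)
        vals[obs] = resid
        out[c] = vals
    return out
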