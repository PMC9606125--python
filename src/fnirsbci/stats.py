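"""Inferential layer: channel contrasts, ROI ANOVA with Scheffé
post-hoc, summary-statistic ANOVA, ANCOVA with a gender covariate,
Cronbach's alpha, behavioral purchase tests, and the topographic /
hemispheric-asymmetry summaries.

Conventions: channel-wise session contrasts run Levene's test first
and fall back to Welch's t when it rejects at alpha = 0.05 (the
pooled two-sample t otherwise).  No multiple-testing correction is
applied across the 15 channels by default — mirroring the reporting
convention of the protocol — but Bonferroni/BH corrections are
available and the output flags which was used.  Significance stars:
*** p<0.001, ** p<0.01, * p<0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .montage import ProbeLayout, ROIS

__all__ = [
    "stars",
    "channel_contrast",
    "roi_anova",
    "scheffe_pairs",
    "summary_anova",
    "ancova_gender",
    "cronbach_alpha",
    "ReliabilityReport",
    "purchase_tests",
    "topographic_map",
    "TopoMap",
    "asymmetry_index",
    "grand_average_trace",
]


def stars(p: float) -> str:
    """Significance stars as a pure function of p."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# channel-wise session contrast


def channel_contrast(means: pd.DataFrame, alpha: float = 0.05,
                     levene_alpha: float = 0.05,
                     correction: str | None = None) -> pd.DataFrame:
    """Two-sample t per channel between sessions 1 and 2.

    ``means`` is the tidy channel-means table (subject, session,
    channel, mean_dhbo).  Levene's test decides pooled vs. Welch t.
    ``correction`` in {None, "bonferroni", "fdr_bh"}.
    """
    sessions = sorted(means["session"].unique())
    if len(sessions) != 2:
        raise ValueError(f"need exactly 2 sessions, got {sessions}")
    rows = []
    for channel, g in means.groupby("channel"):
        a = g.loc[g["session"] == sessions[0], "mean_dhbo"].to_numpy()
        b = g.loc[g["session"] == sessions[1], "mean_dhbo"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"channel {channel}: need >= 2 subjects per session")
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError(f"channel {channel}: zero variance in both groups")
        lev_stat, lev_p = st.levene(a, b)
        equal_var = lev_p >= levene_alpha
        t, p = st.ttest_ind(a, b, equal_var=equal_var)
        rows.append({
            "channel": channel,
            "mean_s1": a.mean(), "mean_s2": b.mean(),
            "sem_s1": a.std(ddof=1) / np.sqrt(len(a)),
            "sem_s2": b.std(ddof=1) / np.sqrt(len(b)),
            "levene_p": lev_p, "equal_var": equal_var,
            "t": float(t), "p": float(p),
        })
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    elif correction == "fdr_bh":
        out["p_adj"] = sm.stats.multipletests(out["p"], method="fdr_bh")[1]
    elif correction is None:
        out["p_adj"] = out["p"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out["correction"] = correction or "none"
    out["significant"] = out["p_adj"] < alpha
    out["stars"] = out["p_adj"].map(stars)
    return out


# ---------------------------------------------------------------------------
# ROI ANOVA + Scheffé


def _roi_observations(means: pd.DataFrame, layout: ProbeLayout,
                      session: int) -> dict[str, np.ndarray]:
    """Per-subject ROI means (channels averaged within ROI) for a session."""
    sub = means[means["session"] == session]
    obs: dict[str, np.ndarray] = {}
    for roi in ROIS:
        chans = layout.channels_in_roi(roi)
        if not chans:
            continue
        g = sub[sub["channel"].isin(chans)]
        vals = g.groupby("subject")["mean_dhbo"].mean().to_numpy()
        obs[roi] = vals
    return obs


def scheffe_pairs(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise contrasts with Scheffé-adjusted p values.

    For groups i, j: F_ij = (m_i - m_j)^2 / (MSW (1/n_i + 1/n_j));
    the Scheffé p is P(F_{k-1, N-k} >= F_ij / (k-1)), which is never
    smaller than the unadjusted single-contrast p.
    """
    names = list(groups)
    k = len(names)
    ns = {g: len(v) for g, v in groups.items()}
    n_total = sum(ns.values())
    msw = sum(np.sum((v - v.mean()) ** 2) for v in groups.values()) / (n_total - k)
    rows = []
    for a, b in itertools.combinations(names, 2):
        va, vb = groups[a], groups[b]
        diff = va.mean() - vb.mean()
        denom = msw * (1 / ns[a] + 1 / ns[b])
        f_contrast = diff ** 2 / denom if denom > 0 else np.inf
        p_scheffe = float(st.f.sf(f_contrast / (k - 1), k - 1, n_total - k))
        p_unadj = float(st.f.sf(f_contrast, 1, n_total - k))
        rows.append({"group_a": a, "group_b": b, "diff": diff,
                     "F_contrast": f_contrast, "p_scheffe": p_scheffe,
                     "p_unadjusted": p_unadj, "stars": stars(p_scheffe)})
    return pd.DataFrame(rows)


def roi_anova(means: pd.DataFrame, layout: ProbeLayout,
              session: int) -> dict:
    """One-way ANOVA of channel means across ROIs + Scheffé post-hoc."""
    groups = _roi_observations(means, layout, session)
    groups = {g: v for g, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise ValueError("need at least 2 ROIs with observations")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"ROI {g}: fewer than 2 observations")
    f, p = st.f_oneway(*groups.values())
    k = len(groups)
    n_total = sum(len(v) for v in groups.values())
    return {
        "session": session,
        "F": float(f), "p": float(p),
        "df": (k - 1, n_total - k),
        "group_means": {g: float(v.mean()) for g, v in groups.items()},
        "posthoc": scheffe_pairs(groups),
        "stars": stars(float(p)),
    }


# ---------------------------------------------------------------------------
# summary-statistic ANOVA


def summary_anova(m1: float, sd1: float, n1: int,
                  m2: float, sd2: float, n2: int) -> dict:
    """Two-group one-way ANOVA from printed summary statistics.

    F = MSB / MSW with MSB = sum n_i (M_i - GM)^2 (1 df) and MSW the
    pooled within-group variance on n1 + n2 - 2 df.  Equals the raw
    two-group ANOVA on any data with these exact moments.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group sds must be > 0")
    gm = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2
    ssw = (n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2
    df = (1, n1 + n2 - 2)
    msw = ssw / df[1]
    f = ssb / msw
    p = float(st.f.sf(f, *df))
    return {"F": float(f), "df": df, "p": p, "stars": stars(p)}


# ---------------------------------------------------------------------------
# ANCOVA with gender covariate


def ancova_gender(scores: pd.DataFrame) -> dict:
    """Linear-model ANCOVA score ~ session + gender, type-II SS.

    ``scores`` has columns score, session, gender.  Returns the
    covariate (gender) p value and the adjusted session effect.
    """
    for col in ("score", "session", "gender"):
        if col not in scores.columns:
            raise ValueError(f"scores table missing column {col!r}")
    if scores["gender"].nunique() < 2:
        raise ValueError("need both genders present")
    if scores["session"].nunique() < 2:
        raise ValueError("need both sessions present")
    tab = pd.crosstab(scores["session"], scores["gender"])
    if (tab == 0).any().any():
        warnings.warn("gender and session are partially confounded "
                      "(an empty design cell)", stacklevel=2)
    model = smf.ols("score ~ C(session) + C(gender)", data=scores).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    session_row = anova.loc[anova.index.str.contains("session")].iloc[0]
    gender_row = anova.loc[anova.index.str.contains("gender")].iloc[0]
    return {
        "session_F": float(session_row["F"]),
        "session_p": float(session_row["PR(>F)"]),
        "gender_F": float(gender_row["F"]),
        "gender_p": float(gender_row["PR(>F)"]),
        "model": model,
    }


# ---------------------------------------------------------------------------
# reliability


@dataclass(frozen=True)
class ReliabilityReport:
    construct: str
    cronbach_alpha: float
    n_items: int
    n_respondents: int

    @property
    def reliable(self) -> bool:
        """Conventional alpha >= 0.7 reliability rule."""
        return self.cronbach_alpha >= 0.7


def cronbach_alpha(q: pd.DataFrame, construct: str | None = None,
                   condition: str | None = None) -> ReliabilityReport:
    """Internal consistency alpha = k/(k-1) (1 - sum var_i / var_total)."""
    sub = q
    if construct is not None:
        sub = sub[sub["construct"] == construct]
    else:
        constructs = sub["construct"].unique()
        if len(constructs) != 1:
            raise ValueError("multiple constructs present; pass construct=")
        construct = constructs[0]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    wide = sub.pivot_table(index="respondent_id", columns="item_id",
                           values="score")
    if wide.isna().any().any():
        raise ValueError("incomplete item responses")
    k = wide.shape[1]
    n = wide.shape[0]
    if k < 2 or n < 2:
        raise ValueError("need >= 2 items and >= 2 respondents")
    item_vars = wide.var(axis=0, ddof=1)
    total_var = wide.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance across respondents")
    alpha = k / (k - 1) * (1 - item_vars.sum() / total_var)
    return ReliabilityReport(construct=str(construct),
                             cronbach_alpha=float(alpha),
                             n_items=int(k), n_respondents=int(n))


# ---------------------------------------------------------------------------
# behavioral purchase tests


def purchase_tests(p: pd.DataFrame) -> pd.DataFrame:
    """Two-sample t per category (and per-subject totals) across sessions."""
    sessions = sorted(p["session"].unique())
    if len(sessions) != 2:
        raise ValueError(f"need exactly 2 sessions, got {sessions}")
    rows = []

    def one_test(name: str, a: np.ndarray, b: np.ndarray) -> None:
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"{name}: empty session group")
        degenerate = np.var(a) == 0 and np.var(b) == 0
        if degenerate:
            t = 0.0 if a.mean() == b.mean() else np.inf
            pval = 1.0 if a.mean() == b.mean() else 0.0
        else:
            t, pval = st.ttest_ind(a, b, equal_var=True)
        rows.append({
            "category": name,
            "sum_s1": float(a.sum()), "sum_s2": float(b.sum()),
            "sd_s1": float(a.std(ddof=1)), "sd_s2": float(b.std(ddof=1)),
            "t": float(t), "p": float(pval), "stars": stars(float(pval)),
            "degenerate": degenerate,
        })

    for category, g in p.groupby("category"):
        a = g.loc[g["session"] == sessions[0], "count"].to_numpy(float)
        b = g.loc[g["session"] == sessions[1], "count"].to_numpy(float)
        one_test(category, a, b)
    totals = p.groupby(["session", "respondent_id"])["count"].sum().reset_index()
    one_test(
        "total",
        totals.loc[totals["session"] == sessions[0], "count"].to_numpy(float),
        totals.loc[totals["session"] == sessions[1], "count"].to_numpy(float))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# topography + asymmetry


@dataclass
class TopoMap:
    """Normalized per-channel activation and its rendering grid."""

    normalized: dict[int, np.ndarray]    # session -> (n_channels,) in [-1, 1]
    grids: dict[int, np.ndarray]         # session -> (ny, nx) interpolated map
    grid_x: np.ndarray
    grid_y: np.ndarray
    channel_positions: dict[int, tuple[float, float]]


def _idw(xy: np.ndarray, values: np.ndarray, gx: np.ndarray,
         gy: np.ndarray, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted interpolation; exact at channel sites."""
    pts = np.stack(np.meshgrid(gx, gy), axis=-1).reshape(-1, 2)
    d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1)
    out = np.empty(len(pts))
    hit = d2 < 1e-18
    exact = hit.any(axis=1)
    out[exact] = values[np.argmax(hit[exact], axis=1)]
    w = 1.0 / d2[~exact] ** (power / 2.0)
    out[~exact] = (w * values[None, :]).sum(axis=1) / w.sum(axis=1)
    return out.reshape(len(gy), len(gx))


def topographic_map(means: pd.DataFrame, layout: ProbeLayout,
                    grid_shape: tuple[int, int] = (48, 64)) -> TopoMap:
    """Session topographies normalized to [-1, 1] by the joint max |mean|."""
    sessions = sorted(means["session"].unique())
    per_session = {}
    for s in sessions:
        g = (means[means["session"] == s]
             .groupby("channel")["mean_dhbo"].mean())
        vals = g.reindex(layout.channel_ids)
        if vals.isna().any():
            raise ValueError("all 15 channels required for the topographic map")
        per_session[s] = vals.to_numpy()
    scale = max(np.abs(v).max() for v in per_session.values())
    normalized = {s: (v / scale if scale > 0 else np.zeros_like(v))
                  for s, v in per_session.items()}
    xy = np.array([layout.positions[ch] for ch in layout.channel_ids])
    pad = 1.0
    gx = np.linspace(xy[:, 0].min() - pad, xy[:, 0].max() + pad, grid_shape[1])
    gy = np.linspace(xy[:, 1].min() - pad, xy[:, 1].max() + pad, grid_shape[0])
    grids = {s: _idw(xy, v, gx, gy) for s, v in normalized.items()}
    return TopoMap(normalized=normalized, grids=grids, grid_x=gx, grid_y=gy,
                   channel_positions={ch: layout.positions[ch]
                                      for ch in layout.channel_ids})


def asymmetry_index(means: pd.DataFrame, layout: ProbeLayout,
                    signed: bool = False) -> pd.DataFrame:
    """Right-minus-left frontal activity per subject-session.

    index = mean over right channels - mean over left channels of
    |dHbO| (of signed dHbO when ``signed``); the midline channel is
    excluded.  Positive values mean right-biased frontal activity.
    """
    right = layout.channels_in_hemisphere("right")
    left = layout.channels_in_hemisphere("left")
    if not right or not left:
        raise ValueError("layout must have channels in both hemispheres")
    f = (lambda v: v) if signed else np.abs
    rows = []
    for (subject, session), g in means.groupby(["subject", "session"]):
        v = g.set_index("channel")["mean_dhbo"]
        rows.append({
            "subject": subject, "session": session,
            "asymmetry": float(f(v.reindex(right)).mean()
                               - f(v.reindex(left)).mean()),
        })
    return pd.DataFrame(rows)


def grand_average_trace(epochsets: list) -> dict:
    """Cohort-average dHbO trace per session + session contrast t-test.

    Averages each subject-session epoch over trials and channels, then
    across subjects; the contrast t is a two-sample t between the
    subjects' 0..60 s grand means of the two sessions.
    """
    per_session: dict[int, list[np.ndarray]] = {}
    task_means: dict[int, list[float]] = {}
    times = None
    for e in epochsets:
        trace = e.trial_average().mean(axis=1)
        per_session.setdefault(e.session, []).append(trace)
        task_means.setdefault(e.session, []).append(
            float(trace[e.task_slice()].mean()))
        times = e.times
    out = {"times": times, "mean": {}, "sd": {}}
    for s, traces in per_session.items():
        arr = np.stack(traces)
        out["mean"][s] = arr.mean(axis=0)
        out["sd"][s] = arr.std(axis=0, ddof=1)
    if len(task_means) == 2:
        (s1, a), (s2, b) = sorted(task_means.items())
        t, p = st.ttest_ind(np.asarray(a), np.asarray(b), equal_var=True)
        out["contrast"] = {"t": float(t), "p": float(p), "stars": stars(float(p))}
    return out
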