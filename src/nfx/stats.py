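"""Pre/post group-delta statistical framework.

Per-subject deltas (post - pre) of every variable are contrasted between
each intervention group (interval hypoxic training, electrical muscle
stimulation) and control with a two-sided Mann-Whitney U test; a
Shapiro-Wilk normality gate is reported per variable but the
nonparametric test is used throughout. Families of raw p-values get
step-down Holm adjustment; a contrast is flagged significant only when
the adjusted p is at or below alpha AND Cohen's d on the deltas exceeds
the large-effect filter (0.75 by default). Analytic two-sample t power
(noncentral t) accompanies each contrast. Baseline homogeneity across
the three groups is screened with pairwise Kolmogorov-Smirnov tests
(Bonferroni over the 3 pairs) plus Tukey HSD, excluding variables whose
pre-intervention distributions already differ. Cross-modality
association uses Spearman rho and Kendall tau on pre-session values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "compute_deltas",
    "normality_gate",
    "mannwhitney_contrast",
    "holm_adjust",
    "bonferroni_adjust",
    "baseline_homogeneity",
    "effect_size_d",
    "posthoc_power",
    "correlation_matrix",
    "fc_correlation_summary",
    "anova_connectivity",
    "delta_contrasts",
]


def compute_deltas(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-subject post-minus-pre deltas from a tidy subject table.

    ``table`` columns: subject_id, group, session (pre|post), variable,
    value. Returns (delta table with columns subject_id/group/variable/
    delta, number of (subject, variable) cells missing a session).
    Missingness is data, not an error.
    """
    wide = table.pivot_table(
        index=["subject_id", "group", "variable"], columns="session",
        values="value", aggfunc="first",
    )
    for col in ("pre", "post"):
        if col not in wide:
            wide[col] = np.nan
    wide = wide.reset_index()
    wide["delta"] = wide["post"] - wide["pre"]
    n_missing = int(wide["delta"].isna().sum())
    out = wide.dropna(subset=["delta"])[["subject_id", "group", "variable", "delta"]]
    return out.reset_index(drop=True), n_missing


def normality_gate(values: np.ndarray, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk verdict for one variable's values.

    Returns dict(normal, p, degenerate). Constant input is reported
    non-normal with a degenerate flag (the test statistic is undefined).
    """
    values = np.asarray(values, float)
    if values.size < 3:
        raise ValueError("normality gate needs n >= 3")
    if np.ptp(values) == 0:
        return {"normal": False, "p": np.nan, "degenerate": True}
    stat, p = spstats.shapiro(values)
    return {"normal": bool(p > alpha), "p": float(p), "degenerate": False}


def mannwhitney_contrast(a: np.ndarray, b: np.ndarray) -> tuple[float, int, bool]:
    """Two-sided Mann-Whitney U; returns (p, direction, tie_flag).

    direction is the sign of median(a) - median(b). When every value in
    both samples is identical the test is undefined; p = 1 with a tie flag.
    The exact null distribution is used for small tie-free samples, the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each side needs n >= 3")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0, 0, True
    res = spstats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    direction = int(np.sign(np.median(a) - np.median(b)))
    return float(res.pvalue), direction, False


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment, order restored, capped at 1.

    p_(i) <- max_{j<=i} (m - j + 1) * p_(j) over the ascending order.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adj_sorted = np.maximum.accumulate(scaled)
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, float)
    return np.minimum(p * p.size, 1.0)


def effect_size_d(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Cohen's d with (n-1)-weighted pooled SD; returns (|d|, undefined_flag)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("effect size needs n >= 2 per side")
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        return np.nan, True
    return float(abs(a.mean() - b.mean()) / np.sqrt(pooled_var)), False


def posthoc_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Analytic two-sided two-sample t-test power at effect size d.

    Noncentral-t formulation with ncp = d * sqrt(n1 n2 / (n1 + n2)) and
    df = n1 + n2 - 2; at d = 0 this returns exactly alpha.
    """
    if d < 0:
        raise ValueError("d must be nonnegative")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = spstats.t.ppf(1 - alpha / 2, df)
    upper = spstats.nct.sf(tcrit, df, ncp)
    lower = spstats.nct.cdf(-tcrit, df, ncp)
    if not np.isfinite(lower):  # numerically negligible far tail at large ncp
        lower = 0.0
    return float(upper + lower)


def baseline_homogeneity(
    table: pd.DataFrame, variable: str, alpha: float = 0.05, groups: Sequence[str] | None = None
) -> dict:
    """Screen whether the three groups' pre-session values share a distribution.

    Pairwise two-sample KS with Bonferroni over the 3 pairs plus Tukey HSD;
    the variable is flagged excluded when any adjusted test rejects.
    Returns dict(verdict, excluded, ks_adjusted_p, tukey_p, degenerate).
    verdict is "insufficient" when any group has n < 3.
    """
    pre = table.query("session == 'pre' and variable == @variable")
    if groups is None:
        groups = sorted(pre["group"].unique())
    samples = [pre.loc[pre["group"] == g, "value"].dropna().to_numpy() for g in groups]
    if any(len(s) < 3 for s in samples):
        return {"verdict": "insufficient", "excluded": False, "ks_adjusted_p": None,
                "tukey_p": None, "degenerate": False}
    degenerate = all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1
    if degenerate:
        return {"verdict": "homogeneous", "excluded": False,
                "ks_adjusted_p": [1.0] * 3, "tukey_p": [1.0] * 3, "degenerate": True}
    ks_p = [spstats.ks_2samp(s1, s2).pvalue for s1, s2 in combinations(samples, 2)]
    ks_adj = bonferroni_adjust(ks_p)
    tukey = spstats.tukey_hsd(*samples)
    tukey_p = [float(tukey.pvalue[i, j]) for i, j in combinations(range(len(samples)), 2)]
    excluded = bool(np.any(ks_adj <= alpha) or np.any(np.asarray(tukey_p) <= alpha))
    return {
        "verdict": "excluded" if excluded else "homogeneous",
        "excluded": excluded,
        "ks_adjusted_p": [float(v) for v in ks_adj],
        "tukey_p": tukey_p,
        "degenerate": False,
    }


def correlation_matrix(
    table: pd.DataFrame,
    variables_a: Sequence[str],
    variables_b: Sequence[str] | None = None,
    session: str = "pre",
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman rho and Kendall tau between variable sets on one session.

    One row per (var_a, var_b) with both coefficients, their p-values and
    the pairwise-complete n. Constant variables yield NaN with a flag.
    """
    wide = (
        table.query("session == @session")
        .pivot_table(index="subject_id", columns="variable", values="value", aggfunc="first")
    )
    if variables_b is None:
        variables_b = variables_a
    rows = []
    for va in variables_a:
        for vb in variables_b:
            sub = wide[[va, vb]].dropna() if va != vb else wide[[va]].dropna()
            n = len(sub)
            if va == vb:
                rows.append(dict(var_a=va, var_b=vb, n=n, spearman_rho=1.0, spearman_p=0.0,
                                 kendall_tau=1.0, kendall_p=0.0, degenerate=False))
                continue
            x, y = sub[va].to_numpy(), sub[vb].to_numpy()
            if n < min_n:
                raise ValueError(f"pairwise-complete n < {min_n} for ({va}, {vb})")
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append(dict(var_a=va, var_b=vb, n=n, spearman_rho=np.nan, spearman_p=np.nan,
                                 kendall_tau=np.nan, kendall_p=np.nan, degenerate=True))
                continue
            rho, rho_p = spstats.spearmanr(x, y)
            tau, tau_p = spstats.kendalltau(x, y)
            rows.append(dict(var_a=va, var_b=vb, n=n, spearman_rho=float(rho),
                             spearman_p=float(rho_p), kendall_tau=float(tau),
                             kendall_p=float(tau_p), degenerate=False))
    return pd.DataFrame(rows)


def fc_correlation_summary(
    fc_table: pd.DataFrame,
    subject_table: pd.DataFrame,
    variables: Sequence[str],
    alpha: float = 0.05,
    session: str = "pre",
) -> pd.DataFrame:
    """Count channel pairs whose connectivity correlates with each variable.

    ``fc_table`` is tidy per-pair connectivity (subject_id, session,
    condition, method, band, pair, value). For every (variable, band,
    condition, method) the Spearman correlation against each channel
    pair's value is tested at ``alpha``; the summary counts significant
    positive and negative pairs — the heatmap-shade quantity used for
    connectivity-vs-score reporting.
    """
    scores = (
        subject_table.query("session == @session")
        .pivot_table(index="subject_id", columns="variable", values="value", aggfunc="first")
    )
    rows = []
    fc = fc_table.query("session == @session")
    for (condition, method, band), sub in fc.groupby(["condition", "method", "band"], sort=True):
        pair_wide = sub.pivot_table(index="subject_id", columns="pair", values="value", aggfunc="first")
        joined = pair_wide.join(scores, how="inner")
        for var in variables:
            n_pos = n_neg = 0
            for pair in pair_wide.columns:
                xy = joined[[pair, var]].dropna()
                if len(xy) < 5 or np.ptp(xy[var].to_numpy()) == 0 or np.ptp(xy[pair].to_numpy()) == 0:
                    continue
                rho, p = spstats.spearmanr(xy[pair], xy[var])
                if p <= alpha:
                    if rho > 0:
                        n_pos += 1
                    else:
                        n_neg += 1
            rows.append(dict(variable=var, condition=condition, method=method, band=band,
                             n_pairs_positive=n_pos, n_pairs_negative=n_neg))
    return pd.DataFrame(rows)


def anova_connectivity(groups: Sequence[np.ndarray]) -> tuple[float, float, bool]:
    """One-way ANOVA across group delta samples; returns (F, p, degenerate).

    Zero within-group variance with differing means yields an infinite-F
    degenerate flag; zero variance everywhere with equal means is undefined.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 3 for g in groups):
        raise ValueError("need >= 2 groups with n >= 3")
    within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    means = [g.mean() for g in groups]
    if within == 0:
        if np.ptp(means) == 0:
            return np.nan, np.nan, True
        return np.inf, 0.0, True
    f, p = spstats.f_oneway(*groups)
    return float(f), float(p), False


@dataclass
class ContrastConfig:
    alpha: float = 0.05
    es_min: float = 0.75
    contrast_pairs: tuple[tuple[str, str], ...] = (("EMS", "control"), ("hypoxia", "control"))


def delta_contrasts(
    deltas: pd.DataFrame,
    families: Mapping[str, Sequence[str]] | None = None,
    config: ContrastConfig | None = None,
) -> pd.DataFrame:
    """Group-vs-control Mann-Whitney contrasts of deltas with Holm families.

    ``deltas`` columns: subject_id, group, variable, delta. ``families``
    maps a family name (one Holm family per modality) to its variables; by
    default all variables form one family. Holm runs within each
    (family x contrast pair). Output carries raw and adjusted p, Cohen's d,
    analytic power, direction and the joint significance flag
    (adjusted p <= alpha and d > es_min).
    """
    config = config or ContrastConfig()
    if families is None:
        families = {"all": sorted(deltas["variable"].unique())}
    rows = []
    for family, variables in families.items():
        for grp, ctrl in config.contrast_pairs:
            fam_rows = []
            for var in variables:
                a = deltas.query("variable == @var and group == @grp")["delta"].to_numpy()
                b = deltas.query("variable == @var and group == @ctrl")["delta"].to_numpy()
                if a.size < 3 or b.size < 3:
                    continue
                p, direction, tie = mannwhitney_contrast(a, b)
                d, d_flag = effect_size_d(a, b)
                power = posthoc_power(d, a.size, b.size, config.alpha) if np.isfinite(d) else np.nan
                fam_rows.append(
                    dict(family=family, variable=var, group=grp, control=ctrl,
                         raw_p=p, effect_size=d, power=power,
                         direction={1: "Increase", -1: "Decrease", 0: "None"}[direction],
                         tie_flag=tie, es_undefined=d_flag, n_group=a.size, n_control=b.size)
                )
            if not fam_rows:
                continue
            adj = holm_adjust([r["raw_p"] for r in fam_rows])
            for r, ap in zip(fam_rows, adj):
                r["adjusted_p"] = float(ap)
                r["significant"] = bool(ap <= config.alpha and np.isfinite(r["effect_size"])
                                        and r["effect_size"] > config.es_min)
            rows.extend(fam_rows)
    return pd.DataFrame(rows)
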