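"""The cohort statistical battery: covariate-adjusted group tests, rank tests,
correlations with Fisher's z, and the a priori ANOVA power computation.

The battery mirrors a standard three-group clinical analysis plan: outcomes
are compared across groups with a one-way ANCOVA (linear model with group
indicators plus covariates, group effect tested by full-vs-reduced model
comparison) when group variances are compatible, and with Kruskal-Wallis +
Dunn's post hoc tests when Levene's test rejects homogeneity.  Pairwise
contrasts after the ANCOVA use a seeded percentile bootstrap of the
adjusted-mean differences (B = 1000 by default) with a studentized-range
(Tukey) family-wise adjustment; an analytic Tukey mode and unadjusted
planned contrasts are also available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "Contrast",
    "GroupComparisonResult",
    "PowerSpec",
    "DegenerateDataError",
    "spearman",
    "fisher_z",
    "ancova_group_test",
    "levene_test",
    "kruskal_wallis",
    "dunn_posthoc",
    "welch_t",
    "anova_required_n",
    "run_statistics",
    "StatisticsPlan",
    "OutcomeSpec",
    "CorrelationSpec",
    "report_to_markdown",
]


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined for the data (constant input, zero variance...)."""


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    fisher_z: float
    n: int


@dataclass(frozen=True)
class Contrast:
    pair: tuple[str, str]
    estimate: float
    p: float
    method: str


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float
    kind: str                      # "F", "H" or "t"
    df: tuple[float, ...]
    p: float
    adjusted_means: dict[str, float] = field(default_factory=dict)
    contrasts: tuple[Contrast, ...] = ()


@dataclass(frozen=True)
class PowerSpec:
    """A priori power specification for a fixed-effects one-way ANOVA."""

    effect_size_f: float = 0.40
    alpha: float = 0.05
    power: float = 0.95
    n_groups: int = 3

    def __post_init__(self) -> None:
        if self.effect_size_f <= 0:
            raise ValueError("effect size f must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties; p from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    z = fisher_z(rho) if abs(rho) < 1 else math.copysign(math.inf, rho)
    return CorrelationResult(rho=float(rho), p=float(p), fisher_z=z, n=int(x.size))


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = atanh(r); odd and strictly increasing on (-1, 1)."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"correlation {r} outside (-1, 1)")
    return float(np.arctanh(r))


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # identify columns involved in the collinearity for the error message
        bad = []
        keep: list[int] = []
        for j in range(arr.shape[1]):
            sub = arr[:, keep + [j]]
            if np.linalg.matrix_rank(sub) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(X.columns[j])
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")


def ancova_group_test(
    data: pd.DataFrame,
    outcome: str,
    group: str = "group",
    covariates: Sequence[str] = (),
    posthoc: str = "bootstrap-tukey",
    n_boot: int = 1000,
    seed: int | None = None,
    planned_unadjusted: bool = False,
) -> GroupComparisonResult:
    """One-way ANCOVA: group effect on ``outcome`` adjusting for ``covariates``.

    The group F-statistic comes from comparing the full linear model
    (group indicators + covariates) against the covariates-only model.
    Adjusted group means are model predictions at the covariate grand means.
    ``posthoc`` is one of ``"bootstrap-tukey"`` (percentile bootstrap of the
    contrast estimates, studentized-range adjustment; seeded), ``"tukey"``
    (analytic, model-based standard errors) or ``"none"``.  With
    ``planned_unadjusted`` the pairwise p-values come from the plain t
    distribution without family-wise correction.
    """
    import statsmodels.api as sm

    cols = [outcome, group, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    d = data[cols].dropna()
    levels = sorted(d[group].astype(str).unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    y = d[outcome].to_numpy(dtype=float)
    n = y.size
    if n <= k + len(covariates) + 1:
        raise ValueError("too few observations for the requested model")
    # constant covariates carry no information and would alias the intercept;
    # dropping them makes the ANCOVA reduce exactly to the one-way ANOVA
    covariates = [c for c in covariates if np.ptp(d[c].to_numpy(dtype=float)) > 0]

    def design(frame: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame({"Intercept": np.ones(len(frame))}, index=frame.index)
        for lev in levels[1:]:  # treatment coding, first level as reference
            X[f"{group}[{lev}]"] = (frame[group].astype(str) == lev).astype(float)
        for c in covariates:
            X[c] = frame[c].astype(float)
        return X

    X_full = design(d)
    _check_full_rank(X_full)
    X_red = X_full.drop(columns=[f"{group}[{lev}]" for lev in levels[1:]])

    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df1 = k - 1
    df2 = n - X_full.shape[1]
    eps = 1e-12 * n * (float(np.abs(y).max()) + 1.0) ** 2  # numerically-zero residual scale
    if full.ssr < eps and red.ssr < eps:
        F, p = 0.0, 1.0
    else:
        F = ((red.ssr - full.ssr) / df1) / (full.ssr / df2)
        p = float(sps.f.sf(F, df1, df2))

    # adjusted means: prediction at covariate grand means, per group
    cov_means = {c: float(d[c].astype(float).mean()) for c in covariates}
    beta = full.params
    adj = {}
    for lev in levels:
        mu = beta["Intercept"] + sum(beta[c] * cov_means[c] for c in covariates)
        if lev != levels[0]:
            mu += beta[f"{group}[{lev}]"]
        adj[lev] = float(mu)

    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]

    def contrast_se_model(a: str, b: str) -> float:
        c = np.zeros(X_full.shape[1])
        names = list(X_full.columns)
        if a != levels[0]:
            c[names.index(f"{group}[{a}]")] = 1.0
        if b != levels[0]:
            c[names.index(f"{group}[{b}]")] = -1.0
        return float(np.sqrt(c @ full.cov_params().to_numpy() @ c))

    contrasts: list[Contrast] = []
    if posthoc == "bootstrap-tukey" and not planned_unadjusted:
        rng = np.random.default_rng(seed)
        boot = {pair: [] for pair in pairs}
        idx_by_group = {lev: np.flatnonzero(d[group].astype(str).to_numpy() == lev)
                        for lev in levels}
        for _ in range(n_boot):
            # stratified resampling preserves the group design
            take = np.concatenate([rng.choice(ix, size=ix.size, replace=True)
                                   for ix in idx_by_group.values()])
            db = d.iloc[take]
            Xb = design(db)
            try:
                fb = sm.OLS(db[outcome].to_numpy(dtype=float), Xb).fit()
            except np.linalg.LinAlgError:      # pragma: no cover - degenerate resample
                continue
            bb = fb.params
            mu = {}
            for lev in levels:
                m = bb["Intercept"] + sum(bb[c] * cov_means[c] for c in covariates)
                if lev != levels[0]:
                    m += bb[f"{group}[{lev}]"]
                mu[lev] = m
            for a, b in pairs:
                boot[(a, b)].append(mu[a] - mu[b])
        for a, b in pairs:
            est = adj[a] - adj[b]
            se = float(np.std(boot[(a, b)], ddof=1)) if len(boot[(a, b)]) > 1 else 0.0
            if se == 0.0:
                pp = 1.0 if est == 0.0 else 0.0
            else:
                q = abs(est) / se * math.sqrt(2.0)
                pp = float(sps.studentized_range.sf(q, k, df2))
            contrasts.append(Contrast((a, b), float(est), pp,
                                      f"bootstrap(B={n_boot})+Tukey"))
    elif posthoc == "none" and not planned_unadjusted:
        pass
    else:
        for a, b in pairs:
            est = adj[a] - adj[b]
            se = contrast_se_model(a, b)
            if se == 0.0:
                pp = 1.0 if est == 0.0 else 0.0
                method = "degenerate"
            elif planned_unadjusted:
                t = est / se
                pp = float(2 * sps.t.sf(abs(t), df2))
                method = "planned t (unadjusted)"
            else:
                q = abs(est) / se * math.sqrt(2.0)
                pp = float(sps.studentized_range.sf(q, k, df2))
                method = "Tukey HSD (analytic)"
            contrasts.append(Contrast((a, b), float(est), pp, method))

    return GroupComparisonResult(statistic=float(F), kind="F", df=(float(df1), float(df2)),
                                 p=float(p), adjusted_means=adj, contrasts=tuple(contrasts))


def levene_test(groups: Sequence[Sequence[float]], center: str = "mean"):
    """Levene's test for equality of variances (one-way ANOVA on absolute deviations).

    ``center`` is ``"mean"`` (classic) or ``"median"`` (Brown-Forsythe).
    Returns (statistic, p).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    stat, p = sps.levene(*arrays, center=center)
    return float(stat), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]):
    """Kruskal-Wallis H with tie correction; p from chi-square with k-1 df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all values identical: tie correction divides by zero")
    stat, p = sps.kruskal(*arrays)
    return float(stat), float(p)


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    adjust: str = "holm",
) -> tuple[Contrast, ...]:
    """Dunn's post hoc pairwise tests after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12 (N - 1)); p-values from the standard
    normal, family-adjusted by ``adjust`` in {"none", "bonferroni", "holm"}.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    kruskal_wallis(arrays)  # validates applicability (raises on degenerate data)
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, a in zip(names, arrays):
        mean_ranks[name] = float(ranks[start:start + a.size].mean())
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    zs, ps = [], []
    sizes = {name: a.size for name, a in zip(names, arrays)}
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        zs.append(z)
        ps.append(2 * sps.norm.sf(abs(z)))
    if adjust == "none":
        padj = ps
    elif adjust in ("bonferroni", "holm"):
        padj = multipletests(ps, method=adjust)[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return tuple(Contrast(pair, float(z), float(pa), f"Dunn ({adjust})")
                 for pair, z, pa in zip(pairs, zs, padj))


def welch_t(x, y) -> GroupComparisonResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in both groups")
    res = sps.ttest_ind(x, y, equal_var=False)
    return GroupComparisonResult(statistic=float(res.statistic), kind="t",
                                 df=(float(res.df),), p=float(res.pvalue),
                                 adjusted_means={"x": float(x.mean()), "y": float(y.mean())})


def anova_required_n(spec: PowerSpec, balanced: bool = True, max_n: int = 100000) -> int:
    """Smallest total N reaching the target power for a fixed-effects one-way ANOVA.

    Power at total N is the noncentral-F tail probability beyond the level-
    alpha critical value, with df1 = k - 1, df2 = N - k and noncentrality
    lambda = f^2 * N.  With ``balanced`` the search steps over multiples of
    the group count; otherwise over every integer (ceiling allocation).
    """
    k = spec.n_groups
    step = k if balanced else 1
    start = k * 2 if balanced else k + 2
    for N in range(start, max_n + 1, step):
        df1, df2 = k - 1, N - k
        if df2 < 1:
            continue
        crit = sps.f.isf(spec.alpha, df1, df2)
        power = float(sps.ncf.sf(crit, df1, df2, spec.effect_size_f**2 * N))
        if power >= spec.power:
            return N
    raise ValueError(f"target power not reached by N = {max_n}")


# ---------------------------------------------------------------------------
# analysis plan driver

@dataclass(frozen=True)
class OutcomeSpec:
    """Selects one metric column slice from the tidy metrics table."""

    name: str
    measure: str = "overall_dev"       # metrics column
    frame: str = "retinotopic"
    plane: str = "azimuth"
    covariates: tuple[str, ...] = ("age",)


@dataclass(frozen=True)
class CorrelationSpec:
    name: str
    x: str                             # metadata column
    outcome: OutcomeSpec


@dataclass(frozen=True)
class StatisticsPlan:
    """Which outcomes, correlations and flag splits to run, and with what options."""

    outcomes: tuple[OutcomeSpec, ...] = ()
    correlations: tuple[CorrelationSpec, ...] = ()
    welch_flags: tuple[tuple[str, str], ...] = ()   # (flag column, outcome name)
    alpha: float = 0.05
    levene_alpha: float = 0.05
    posthoc: str = "bootstrap-tukey"
    n_boot: int = 1000
    seed: int = 0


def default_plan(seed: int = 0) -> StatisticsPlan:
    """The standard analysis plan: age-corrected accuracy ANCOVAs, anxiety
    correlations with post-rotation accuracy and with the strategy index."""
    outcomes = []
    for frame in ("retinotopic", "world"):
        for measure in ("overall_dev", "reproduction_dev", "transformation_dev",
                        "postrotation_dev"):
            outcomes.append(OutcomeSpec(
                name=f"{measure[:-4]}_{frame}_azimuth", measure=measure,
                frame=frame, plane="azimuth"))
            outcomes.append(OutcomeSpec(
                name=f"{measure[:-4]}_{frame}_polar", measure=measure,
                frame=frame, plane="polar"))
    post_world = OutcomeSpec(name="postrotation_world_azimuth", measure="postrotation_dev",
                             frame="world", plane="azimuth")
    strategy_az = OutcomeSpec(name="strategy_azimuth", measure="strategy_index",
                              frame="retinotopic", plane="azimuth")
    correlations = (
        CorrelationSpec("stai_state_vs_postrotation_world", "stai_state", post_world),
        CorrelationSpec("stai_trait_vs_postrotation_world", "stai_trait", post_world),
        CorrelationSpec("stai_state_vs_strategy_azimuth", "stai_state", strategy_az),
        CorrelationSpec("stai_trait_vs_strategy_azimuth", "stai_trait", strategy_az),
        CorrelationSpec("eisod_scalar_vs_postrotation_retino", "eisod_scalar",
                        OutcomeSpec(name="postrotation_retino_azimuth",
                                    measure="postrotation_dev", frame="retinotopic",
                                    plane="azimuth")),
    )
    return StatisticsPlan(outcomes=tuple(outcomes), correlations=correlations,
                          welch_flags=(("avoidance_behavior", "overall_retinotopic_azimuth"),
                                       ("visual_aggravation", "overall_retinotopic_azimuth")),
                          seed=seed)


def _select_outcome(metrics: pd.DataFrame, spec: OutcomeSpec) -> pd.DataFrame:
    sub = metrics[(metrics["frame"] == spec.frame) & (metrics["plane"] == spec.plane)]
    if spec.measure not in sub.columns:
        raise KeyError(f"missing metrics column {spec.measure!r}")
    return sub[["participant_id", spec.measure]].rename(columns={spec.measure: spec.name})


def run_statistics(
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    plan: StatisticsPlan | None = None,
) -> dict:
    """Run the full analysis plan on a tidy metrics table joined with metadata.

    For each outcome: Levene across groups decides the track — ANCOVA with
    the configured covariates when variances are compatible, Kruskal-Wallis
    + Dunn otherwise.  Returns a JSON-serializable report.
    """
    plan = plan or default_plan()
    need = {"participant_id", "group"}
    missing = sorted(need - set(metadata.columns))
    if missing:
        raise KeyError(f"metadata missing columns: {missing}")

    report: dict = {"plan": {"alpha": plan.alpha, "levene_alpha": plan.levene_alpha,
                             "posthoc": plan.posthoc, "n_boot": plan.n_boot,
                             "seed": plan.seed},
                    "group_tests": {}, "correlations": {}, "welch": {}}
    outcome_tables: dict[str, pd.DataFrame] = {}
    for i, spec in enumerate(plan.outcomes):
        cols = _select_outcome(metrics, spec)
        d = cols.merge(metadata, on="participant_id").dropna(subset=[spec.name])
        outcome_tables[spec.name] = d
        missing_cov = [c for c in spec.covariates if c not in d.columns]
        if missing_cov:
            raise KeyError(f"outcome {spec.name}: missing covariates {missing_cov}")
        by_group = [g[spec.name].to_numpy() for _, g in d.groupby("group")]
        lev_stat, lev_p = levene_test(by_group)
        entry = {"outcome": spec.name, "levene": {"statistic": lev_stat, "p": lev_p}}
        if lev_p < plan.levene_alpha:
            H, p = kruskal_wallis(by_group)
            dunn = dunn_posthoc({name: g[spec.name].to_numpy()
                                 for name, g in d.groupby("group")})
            entry["test"] = {"kind": "H", "statistic": H,
                             "df": [len(by_group) - 1], "p": p,
                             "contrasts": [_contrast_dict(c) for c in dunn]}
        else:
            res = ancova_group_test(d, spec.name, "group", spec.covariates,
                                    posthoc=plan.posthoc, n_boot=plan.n_boot,
                                    seed=plan.seed + i)
            entry["test"] = _group_result_dict(res)
        report["group_tests"][spec.name] = entry

    for cspec in plan.correlations:
        out = outcome_tables.get(cspec.outcome.name)
        if out is None:
            cols = _select_outcome(metrics, cspec.outcome)
            out = cols.merge(metadata, on="participant_id").dropna(subset=[cspec.outcome.name])
        d = out.dropna(subset=[cspec.x, cspec.outcome.name])
        res = spearman(d[cspec.x], d[cspec.outcome.name])
        report["correlations"][cspec.name] = {
            "rho": res.rho, "p": res.p, "fisher_z": res.fisher_z, "n": res.n}

    for flag, outcome_name in plan.welch_flags:
        d = outcome_tables.get(outcome_name)
        if d is None or flag not in d.columns:
            continue
        sub = d[d["group"] != "HC"].dropna(subset=[flag])
        x = sub.loc[sub[flag].astype(bool), outcome_name].to_numpy()
        y = sub.loc[~sub[flag].astype(bool), outcome_name].to_numpy()
        if x.size < 2 or y.size < 2:
            continue
        res = welch_t(x, y)
        report["welch"][f"{flag}:{outcome_name}"] = {
            "t": res.statistic, "df": res.df[0], "p": res.p,
            "means": res.adjusted_means}
    return report


def _contrast_dict(c: Contrast) -> dict:
    return {"pair": list(c.pair), "estimate": c.estimate, "p": c.p, "method": c.method}


def _group_result_dict(r: GroupComparisonResult) -> dict:
    return {"kind": r.kind, "statistic": r.statistic, "df": list(r.df), "p": r.p,
            "adjusted_means": r.adjusted_means,
            "contrasts": [_contrast_dict(c) for c in r.contrasts]}


def report_to_markdown(report: dict) -> str:
    """Human-readable summary of a run_statistics report."""
    lines = ["# Cohort statistics report", ""]
    lines.append("## Group comparisons")
    lines.append("")
    lines.append("| outcome | test | statistic | df | p | Levene p |")
    lines.append("|---|---|---|---|---|---|")
    for name, entry in report.get("group_tests", {}).items():
        t = entry["test"]
        df = ", ".join(f"{v:g}" for v in t["df"])
        lines.append(f"| {name} | {t['kind']} | {t['statistic']:.3f} | {df} "
                     f"| {t['p']:.4f} | {entry['levene']['p']:.3f} |")
    if report.get("correlations"):
        lines += ["", "## Correlations (Spearman)", "",
                  "| pair | rho | p | Fisher z | n |", "|---|---|---|---|---|"]
        for name, c in report["correlations"].items():
            lines.append(f"| {name} | {c['rho']:.3f} | {c['p']:.4f} "
                         f"| {c['fisher_z']:.3f} | {c['n']} |")
    if report.get("welch"):
        lines += ["", "## Clinical-flag splits (Welch t)", "",
                  "| split | t | df | p |", "|---|---|---|---|"]
        for name, w in report["welch"].items():
            lines.append(f"| {name} | {w['t']:.3f} | {w['df']:.1f} | {w['p']:.4f} |")
    return "\n".join(lines) + "\n"
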