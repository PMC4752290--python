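"""The cohort statistical battery.

Implements the analyses relating regional EEG complexity to group, age,
cognition and copper status:

* normality-gated correlation (Pearson when both variables pass a
  Shapiro-Wilk test at alpha = .05, Spearman otherwise),
* quadratic (parabolic) least-squares fit of whole-brain HFD on age,
* partial correlation by double residualisation,
* split-plot (mixed-design) repeated-measures ANOVA with region and
  hemisphere as within-subject factors and group as a between-subjects
  factor, with Greenhouse-Geisser sphericity correction,
* per-region reduced models with Bonferroni-corrected post-hoc group
  comparisons (the YC-EC and EC-AD family),
* one-way ANOVA of the interhemispheric symmetry index per region,
* demographic matching t-tests.

The repeated-measures engine works on orthonormal within-subject contrast
scores: for each within effect the data are projected onto a Helmert
contrast basis, the hypothesis sum of squares uses unweighted group means
(the conventional choice for unbalanced groups), the error term pools the
within-group scatter of the scores, and the Greenhouse-Geisser epsilon is
``tr(S)^2 / (d * tr(S^2))`` for the pooled score covariance ``S``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss
from scipy.linalg import helmert

logger = logging.getLogger(__name__)

__all__ = [
    "ALPHA",
    "TREND_ALPHA",
    "StatResult",
    "correlate",
    "fit_quadratic",
    "partial_correlation",
    "mixed_rm_anova",
    "full_anova",
    "reduced_anovas",
    "posthoc_group_tests",
    "hars_anova",
    "matching_tests",
]

ALPHA = 0.05
TREND_ALPHA = 0.10

#: The post-hoc family: adjacent group contrasts only (young vs elderly
#: controls, elderly controls vs patients); the YC-AD comparison is omitted.
POSTHOC_FAMILY = (("YC", "EC"), ("EC", "AD"))


@dataclass
class StatResult:
    """One named test: statistic, df, p, effect descriptors, correction."""

    name: str
    statistic: float
    df: tuple[float, ...] | float | None
    p: float
    effect: dict = field(default_factory=dict)
    correction: str = "none"
    p_uncorrected: float | None = None
    notes: str = ""

    @property
    def significant(self) -> bool:
        return self.p < ALPHA

    @property
    def trend(self) -> bool:
        return ALPHA <= self.p < TREND_ALPHA

    def __str__(self) -> str:
        df = self.df
        if isinstance(df, tuple):
            df = ", ".join(f"{d:g}" if float(d).is_integer() else f"{d:.2f}" for d in df)
        head = f"{self.name}: stat={self.statistic:.3f}"
        if df is not None:
            head += f", df=({df})"
        tail = f", p={self.p:.4g}"
        if self.correction != "none":
            tail += f" [{self.correction}]"
        return head + tail


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def correlate(x, y, method: str = "auto", name: str = "correlation") -> StatResult:
    """Correlation with a normality gate.

    ``method='auto'`` runs a Shapiro-Wilk test on each variable at
    alpha = .05 and uses Pearson's r when both pass, Spearman's rho
    otherwise; the gate decision is logged and recorded in the result.
    """
    x, y = _clean_pairs(x, y)
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance variable in correlation")
    chosen = method
    gate: dict = {}
    if method == "auto":
        wx = ss.shapiro(x)
        wy = ss.shapiro(y)
        gate = {
            "shapiro_x": (float(wx.statistic), float(wx.pvalue)),
            "shapiro_y": (float(wy.statistic), float(wy.pvalue)),
        }
        chosen = "pearson" if (wx.pvalue >= ALPHA and wy.pvalue >= ALPHA) else "spearman"
        logger.info("%s: normality gate chose %s", name, chosen)
    if chosen == "pearson":
        r, p = ss.pearsonr(x, y)
    elif chosen == "spearman":
        r, p = ss.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult(
        name=name,
        statistic=float(r),
        df=float(n - 2),
        p=float(p),
        effect={"r": float(r), "n": n, "method": chosen, **gate},
    )


def fit_quadratic(age, hfd, name: str = "quadratic age fit") -> StatResult:
    """Least-squares parabola ``hfd = a*age^2 + b*age + c``.

    Reports R^2, the overall F test against the intercept-only model, and
    the vertex age ``-b / (2a)`` (the turning point of the fitted curve).
    """
    x, y = _clean_pairs(age, hfd)
    n = x.size
    if n < 4 or np.unique(x).size < 3:
        raise ValueError("need >= 4 points with >= 3 distinct ages")
    if np.ptp(y) == 0:
        return StatResult(
            name=name, statistic=0.0, df=(2.0, float(n - 3)), p=1.0,
            effect={"a": 0.0, "b": 0.0, "c": float(y[0]), "r2": 0.0,
                    "vertex_age": float("nan"), "n": n},
        )
    X = np.column_stack([x**2, x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    cond = np.linalg.cond(X)
    if not np.all(np.isfinite(coef)) or cond > 1e12:
        raise ValueError(f"degenerate design (condition number {cond:.3g})")
    a, b, c = (float(v) for v in coef)
    fitted = X @ coef
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    df1, df2 = 2, n - 3
    if ss_tot == 0:
        fstat, p = 0.0, 1.0
    elif 1.0 - r2 < 1e-12:
        fstat, p = np.inf, 0.0
    else:
        fstat = (r2 / df1) / ((1 - r2) / df2)
        p = float(ss.f.sf(fstat, df1, df2))
    vertex = float("nan") if a == 0 else -b / (2 * a)
    return StatResult(
        name=name,
        statistic=float(fstat),
        df=(float(df1), float(df2)),
        p=float(p),
        effect={"a": a, "b": b, "c": c, "r2": float(r2), "vertex_age": vertex, "n": n},
    )


def partial_correlation(x, y, control, name: str = "partial correlation") -> StatResult:
    """Pearson correlation of x and y after removing a control variable.

    Both variables are regressed on the control (with intercept) and the
    residuals are correlated; df = n - 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    x, y, c = x[keep], y[keep], c[keep]
    n = x.size
    if n < 5:
        raise ValueError(f"need at least 5 complete triples, got {n}")
    Z = np.column_stack([c, np.ones(n)])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    # a residual that is numerically zero relative to its source means the
    # variable is an affine function of the control: partial r is 0
    if float(rx @ rx) <= 1e-24 * float(x @ x) or float(ry @ ry) <= 1e-24 * float(y @ y):
        r = 0.0
    else:
        r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * ss.t.sf(abs(t), df))
    return StatResult(
        name=name, statistic=r, df=float(df), p=p, effect={"r": r, "n": n}
    )


# --- split-plot repeated-measures engine -----------------------------------


def _orthonormal_effect_matrix(levels: Sequence[int], active: Sequence[bool]) -> np.ndarray:
    """Kronecker contrast matrix over the flattened cell grid.

    For each within factor, an ``active`` factor contributes its Helmert
    contrast rows (orthonormal, orthogonal to the constant) and an
    inactive factor contributes the normalised constant vector, so the
    rows of the result are orthonormal over cells.
    """
    mat = np.ones((1, 1))
    for lv, act in zip(levels, active):
        block = helmert(lv) if act else np.full((1, lv), 1.0 / np.sqrt(lv))
        mat = np.kron(mat, block)
    return mat


def _gg_epsilon(z_resid: np.ndarray, df_pool: int) -> float:
    d = z_resid.shape[1]
    if d < 2:
        return 1.0
    S = z_resid.T @ z_resid / df_pool
    tr = float(np.trace(S))
    tr2 = float(np.trace(S @ S))
    if tr2 <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / d, tr**2 / (d * tr2))))


def mixed_rm_anova(
    cell_values: pd.DataFrame,
    groups: Sequence[str],
    within: Sequence[tuple[str, int]],
    *,
    gg_correction: bool = True,
) -> pd.DataFrame:
    """Split-plot ANOVA: crossed within factors, one between factor.

    Parameters
    ----------
    cell_values
        Subjects x cells; columns enumerate the within-cell grid in
        C-order of ``within`` (last factor fastest).
    groups
        Between-group label per subject (a single constant label yields a
        pure repeated-measures design with no between tests).
    within
        ``(factor name, n_levels)`` pairs; the product of levels must
        equal the number of columns.
    gg_correction
        Apply Greenhouse-Geisser df correction to within effects with
        more than one numerator df (reported alongside uncorrected p).

    Returns
    -------
    DataFrame with one row per effect (group, each within effect, and its
    interaction with group) carrying SS, df, F, p, epsilon and corrected
    df/p.  Raises on missing cells or groups of size < 2.
    """
    Y = cell_values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        bad = cell_values.index[np.isnan(Y).any(axis=1)].tolist()
        raise ValueError(f"missing cells for subject(s): {bad}")
    names = [w[0] for w in within]
    levels = [int(w[1]) for w in within]
    p_cells = int(np.prod(levels))
    if Y.shape[1] != p_cells:
        raise ValueError(f"{Y.shape[1]} columns but within grid has {p_cells} cells")
    g = np.asarray(groups)
    if g.size != Y.shape[0]:
        raise ValueError("groups length must match number of subjects")
    labels = list(dict.fromkeys(g))
    G = len(labels)
    n_g = np.array([(g == lab).sum() for lab in labels])
    N = Y.shape[0]
    if N - G < 1 or (G > 1 and n_g.min() < 2):
        raise ValueError(
            f"insufficient degrees of freedom: group sizes {dict(zip(labels, n_g))}"
        )
    members = [np.flatnonzero(g == lab) for lab in labels]
    rows = []

    # between-subjects effect on the subject-mean score
    s = Y @ _orthonormal_effect_matrix(levels, [False] * len(levels))[0]
    m_g = np.array([s[idx].mean() for idx in members])
    resid = np.concatenate([s[idx] - m_g[i] for i, idx in enumerate(members)])
    ss_err_b = float(resid @ resid)
    if G > 1:
        grand = float(s.mean())
        ss_grp = float((n_g * (m_g - grand) ** 2).sum())
        df1, df2 = G - 1, N - G
        F = (ss_grp / df1) / (ss_err_b / df2)
        rows.append(
            dict(effect="group", ss=ss_grp, ss_error=ss_err_b, df1=float(df1),
                 df2=float(df2), F=F, p=float(ss.f.sf(F, df1, df2)),
                 eps_gg=np.nan, df1_corr=float(df1), df2_corr=float(df2),
                 p_corr=float(ss.f.sf(F, df1, df2)), correction="none")
        )

    # within effects and their interactions with group
    n_factors = len(levels)
    for mask in range(1, 2**n_factors):
        active = [(mask >> i) & 1 == 1 for i in range(n_factors)]
        eff_name = "*".join(n for n, a in zip(names, active) if a)
        K = _orthonormal_effect_matrix(levels, active)
        d = K.shape[0]
        Z = Y @ K.T  # N x d
        M = np.stack([Z[idx].mean(axis=0) for idx in members])  # G x d
        Zresid = np.concatenate([Z[idx] - M[i] for i, idx in enumerate(members)])
        ss_err = float((Zresid**2).sum())
        df_err = d * (N - G)
        eps = _gg_epsilon(Zresid, N - G) if gg_correction else 1.0
        # main within effect: unweighted mean of group means (Type III style)
        mu = M.mean(axis=0)
        scale = G**2 / float((1.0 / n_g).sum())
        ss_eff = float((mu**2).sum()) * scale
        F = (ss_eff / d) / (ss_err / df_err)
        p_unc = float(ss.f.sf(F, d, df_err))
        p_gg = float(ss.f.sf(F, d * eps, df_err * eps))
        rows.append(
            dict(effect=eff_name, ss=ss_eff, ss_error=ss_err, df1=float(d),
                 df2=float(df_err), F=F, p=p_unc, eps_gg=eps,
                 df1_corr=d * eps, df2_corr=df_err * eps, p_corr=p_gg,
                 correction="greenhouse_geisser" if (gg_correction and d > 1) else "none")
        )
        if G > 1:
            grand_w = Z.mean(axis=0)
            ss_int = float(sum(n_g[i] * ((M[i] - grand_w) ** 2).sum() for i in range(G)))
            df1 = d * (G - 1)
            F = (ss_int / df1) / (ss_err / df_err)
            p_unc = float(ss.f.sf(F, df1, df_err))
            p_gg = float(ss.f.sf(F, df1 * eps, df_err * eps))
            rows.append(
                dict(effect=f"{eff_name}*group", ss=ss_int, ss_error=ss_err,
                     df1=float(df1), df2=float(df_err), F=F, p=p_unc, eps_gg=eps,
                     df1_corr=df1 * eps, df2_corr=df_err * eps, p_corr=p_gg,
                     correction="greenhouse_geisser" if (gg_correction and d > 1) else "none")
            )
    return pd.DataFrame(rows).set_index("effect")


def _cell_frame(
    profiles: Mapping[str, Mapping[str, Mapping[str, float]]],
    regions: Sequence[str],
) -> pd.DataFrame:
    """Subjects x (region, hemisphere) cells, hemisphere fastest."""
    cols = [(r, h) for r in regions for h in ("left", "right")]
    data = {
        sid: [prof[r][h] for r, h in cols] for sid, prof in profiles.items()
    }
    frame = pd.DataFrame.from_dict(data, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(cols, names=["region", "hemisphere"])
    return frame


def full_anova(
    profiles: Mapping[str, Mapping[str, Mapping[str, float]]],
    groups: Mapping[str, str],
    regions: Sequence[str] = ("frontal", "central", "temporal", "parietal", "occipital"),
) -> pd.DataFrame:
    """Region x hemisphere x group mixed ANOVA on regional HFD.

    ``profiles`` maps subject -> region -> hemisphere -> HFD; every
    subject must provide all region x hemisphere cells.
    """
    frame = _cell_frame(profiles, regions)
    glabels = [groups[sid] for sid in frame.index]
    return mixed_rm_anova(
        frame, glabels, within=[("region", len(regions)), ("hemisphere", 2)]
    )


def posthoc_group_tests(
    values: Mapping[str, float],
    groups: Mapping[str, str],
    comparisons: Sequence[tuple[str, str]] = POSTHOC_FAMILY,
    name_prefix: str = "",
) -> list[StatResult]:
    """Bonferroni-corrected two-sample t-tests for the named group pairs.

    The family size is the number of feasible comparisons; corrected
    p = min(1, m * p_raw), with the uncorrected value retained.
    """
    series = pd.Series(values, dtype=float)
    glab = pd.Series({k: groups[k] for k in series.index})
    feasible = [
        (a, b) for a, b in comparisons
        if (glab == a).sum() >= 2 and (glab == b).sum() >= 2
    ]
    m = len(feasible)
    out = []
    for a, b in feasible:
        xa = series[glab == a].to_numpy()
        xb = series[glab == b].to_numpy()
        t, p = ss.ttest_ind(xa, xb)
        p_corr = min(1.0, m * float(p))
        out.append(
            StatResult(
                name=f"{name_prefix}{a} vs {b}",
                statistic=float(t),
                df=float(xa.size + xb.size - 2),
                p=p_corr,
                p_uncorrected=float(p),
                correction="bonferroni",
                effect={
                    "mean_diff": float(xa.mean() - xb.mean()),
                    "family_size": m,
                },
            )
        )
    logger.info("post-hoc family %s: m=%d", name_prefix or "(group)", m)
    return out


def reduced_anovas(
    profiles: Mapping[str, Mapping[str, Mapping[str, float]]],
    groups: Mapping[str, str],
    regions: Sequence[str] = ("frontal", "central", "temporal", "parietal", "occipital"),
) -> dict[str, dict]:
    """Per-region hemisphere x group models with post-hoc group contrasts.

    The post-hoc family per region is the adjacent-group pair set
    (YC vs EC, EC vs AD), Bonferroni-corrected with m = family size; the
    dependent value for the contrasts is the subject's region mean over
    hemispheres.
    """
    out: dict[str, dict] = {}
    for region in regions:
        frame = _cell_frame(profiles, [region])
        glabels = [groups[sid] for sid in frame.index]
        table = mixed_rm_anova(frame, glabels, within=[("hemisphere", 2)])
        region_mean = {sid: float(frame.loc[sid].mean()) for sid in frame.index}
        posthocs = posthoc_group_tests(
            region_mean, groups, name_prefix=f"{region} HFD: "
        )
        out[region] = {"anova": table, "posthoc": posthocs}
    return out


def hars_anova(
    hars_profiles: Mapping[str, Mapping[str, float]],
    groups: Mapping[str, str],
    covariates: pd.DataFrame | None = None,
    regions: Sequence[str] = ("frontal", "central", "temporal", "parietal", "occipital"),
) -> dict[str, dict]:
    """One-way group ANOVA of regional HArS, with companion correlations.

    Per region: the omnibus F over groups, the adjacent-pair post-hocs,
    and — when ``covariates`` (indexed by subject, with ``group``,
    ``age``, ``mmse`` columns) is supplied — the correlation of HArS with
    age among healthy subjects (YC + EC) and with MMSE among the elderly
    (EC + AD).
    """
    out: dict[str, dict] = {}
    for region in regions:
        vals = pd.Series(
            {sid: prof[region] for sid, prof in hars_profiles.items()}, dtype=float
        )
        glab = pd.Series({sid: groups[sid] for sid in vals.index})
        labels = [lab for lab in dict.fromkeys(glab) if (glab == lab).sum() >= 2]
        if len(labels) < 2:
            raise ValueError("need at least two groups with n >= 2")
        samples = [vals[glab == lab].to_numpy() for lab in labels]
        F, p = ss.f_oneway(*samples)
        n = vals.size
        omnibus = StatResult(
            name=f"{region} HArS omnibus",
            statistic=float(F),
            df=(float(len(labels) - 1), float(n - len(labels))),
            p=float(p),
            effect={"groups": labels},
        )
        entry: dict = {
            "omnibus": omnibus,
            "posthoc": posthoc_group_tests(
                vals.to_dict(), groups, name_prefix=f"{region} HArS: "
            ),
        }
        if covariates is not None:
            cov = covariates.loc[covariates.index.intersection(vals.index)]
            healthy = cov[cov["group"].isin(["YC", "EC"])]
            elderly = cov[cov["group"].isin(["EC", "AD"])]
            if len(healthy) >= 4 and "age" in cov:
                entry["corr_age"] = correlate(
                    healthy["age"], vals[healthy.index], method="pearson",
                    name=f"{region} HArS vs age (healthy)",
                )
            if "mmse" in cov and elderly["mmse"].notna().sum() >= 4:
                sub = elderly[elderly["mmse"].notna()]
                entry["corr_mmse"] = correlate(
                    sub["mmse"], vals[sub.index], method="pearson",
                    name=f"{region} HArS vs MMSE (elderly)",
                )
        out[region] = entry
    return out


def matching_tests(
    covariates: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = (("YC", "EC"), ("EC", "AD")),
    columns: Sequence[str] = ("age", "education_years", "mmse", "sex"),
) -> list[StatResult]:
    """Demographic matching: two-sample t-tests per group pair and column.

    Sex is coded 0/1 and compared by t-test (mirroring common practice in
    the clinical EEG literature); a chi-squared test on the 2x2 table is
    emitted alongside.  Missing columns are skipped with a log line.
    """
    out: list[StatResult] = []
    for a, b in pairs:
        for col in columns:
            if col not in covariates.columns:
                logger.info("matching_tests: column %r absent, skipped", col)
                continue
            sub = covariates[covariates["group"].isin([a, b])]
            if col == "sex":
                x = sub[col].map({"M": 0.0, "F": 1.0}).astype(float)
            else:
                x = pd.to_numeric(sub[col], errors="coerce")
            xa = x[sub["group"] == a].dropna().to_numpy()
            xb = x[sub["group"] == b].dropna().to_numpy()
            if xa.size < 2 or xb.size < 2:
                logger.info("matching_tests: %s %s-%s skipped (too few)", col, a, b)
                continue
            if np.ptp(np.concatenate([xa, xb])) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = ss.ttest_ind(xa, xb)
            out.append(
                StatResult(
                    name=f"{col}: {a} vs {b}",
                    statistic=float(t),
                    df=float(xa.size + xb.size - 2),
                    p=float(p),
                    effect={
                        "mean_a": float(xa.mean()), "mean_b": float(xb.mean()),
                        "n_a": int(xa.size), "n_b": int(xb.size),
                    },
                )
            )
            if col == "sex":
                table = pd.crosstab(sub["group"], sub[col])
                if table.shape == (2, 2) and (table.to_numpy() > 0).all():
                    chi2, pc, dof, _ = ss.chi2_contingency(table)
                    out.append(
                        StatResult(
                            name=f"sex chi2: {a} vs {b}",
                            statistic=float(chi2),
                            df=float(dof),
                            p=float(pc),
                        )
                    )
    return out
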