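"""Cohort statistics: demographics tests, group contrasts and the
RNFL association, mirroring a small-cohort optic-nerve study design.

The cohort table has one row per nerve (subject_id, group, eye, rnfl_um,
FA/MD/AD/RD). Controls' two eyes are averaged into one row per subject
before analysis. Group contrasts and the RNFL association are linear
mixed-effects models with a subject random intercept, fit by profiled
restricted maximum likelihood; the reported p-value is the ANOVA (Wald F)
test of the fixed effect and R^2 is the squared Pearson correlation between
the fixed-effect fitted values and the observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import PreconditionError

__all__ = [
    "MEASURES",
    "LMEResult",
    "average_control_eyes",
    "mann_whitney_u",
    "chi_square_prop",
    "fit_lme_rnfl",
    "fit_lme_group",
    "control_inter_eye_tests",
    "group_summary",
]

MEASURES = ("FA", "MD", "AD", "RD")
GROUPS = ("atrophic", "non_affected", "control")

_REQUIRED_COLS = ("subject_id", "group", "eye", "rnfl_um")


@dataclass(frozen=True)
class LMEResult:
    """Fit of Y ~ fixed + (1 | subject)."""

    intercept: float
    slope: float
    slope_se: float
    sigma2_subject: float
    sigma2_resid: float
    r2: float
    pvalue: float
    n_obs: int
    n_subjects: int


def _check_cohort(df: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise PreconditionError(f"cohort table missing columns: {missing}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise PreconditionError(f"unknown group labels: {sorted(bad)}")


def average_control_eyes(raw: pd.DataFrame) -> pd.DataFrame:
    """Replace each control subject's two eye rows by their per-subject mean
    (numeric columns averaged, eye set to ``both``); patient rows pass
    through untouched."""
    _check_cohort(raw)
    controls = raw[raw["group"] == "control"]
    patients = raw[raw["group"] != "control"]
    counts = controls.groupby("subject_id").size()
    if len(counts) and not np.all(counts.values == 2):
        bad = counts[counts != 2].index.tolist()
        raise PreconditionError(f"control subject(s) without exactly 2 eyes: {bad}")
    rows = []
    num_cols = [c for c in raw.columns if pd.api.types.is_numeric_dtype(raw[c])]
    for sid, sub in controls.groupby("subject_id", sort=False):
        row = {c: sub[c].iloc[0] for c in raw.columns}
        for c in num_cols:
            row[c] = float(sub[c].mean())
        row["eye"] = "both"
        row["subject_id"] = sid
        rows.append(row)
    out = pd.concat(
        [patients, pd.DataFrame(rows, columns=raw.columns)], ignore_index=True
    )
    return out


def mann_whitney_u(
    x, y, exact_threshold: int = 25
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact (permutation) p when both samples have at most ``exact_threshold``
    observations and there are no ties across the pooled sample; otherwise a
    tie-corrected normal approximation with continuity correction. Returns
    (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise PreconditionError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = (
        "exact"
        if (no_ties and len(x) <= exact_threshold and len(y) <= exact_threshold)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_prop(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df = 1, no continuity
    correction."""
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise PreconditionError("counts must be a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise PreconditionError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise PreconditionError("zero marginal in the 2x2 table")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    assert dof == 1
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# linear mixed-effects model (single random intercept), profiled REML


def _reml_fit(y: np.ndarray, X: np.ndarray, subject: np.ndarray) -> LMEResult:
    n, p = X.shape
    if n <= p:
        raise PreconditionError("too few observations for the fixed effects")
    _, subj_idx = np.unique(subject, return_inverse=True)
    n_subj = subj_idx.max() + 1
    Z = np.zeros((n, n_subj))
    Z[np.arange(n), subj_idx] = 1.0
    ZZt = Z @ Z.T
    I = np.eye(n)

    def pieces(theta: float):
        V = I + theta * ZZt
        Vi = np.linalg.inv(V)
        XtVX = X.T @ Vi @ X
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            raise PreconditionError("singular fixed-effect design")
        beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
        r = y - X @ beta
        q = float(r @ Vi @ r)
        _, logdet_v = np.linalg.slogdet(V)
        return V, Vi, XtVX, beta, q, logdet_v, logdet_xvx

    def reml_crit(theta: float) -> float:
        _, _, _, _, q, logdet_v, logdet_xvx = pieces(theta)
        q = max(q, 1e-300)
        return logdet_v + logdet_xvx + (n - p) * np.log(q)

    thetas = np.concatenate([[0.0], np.logspace(-4, 4, 33)])
    crits = np.array([reml_crit(t) for t in thetas])
    i_best = int(np.argmin(crits))
    lo = thetas[max(0, i_best - 1)]
    hi = thetas[min(len(thetas) - 1, i_best + 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            reml_crit, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        theta = float(res.x) if res.fun <= crits[i_best] else float(thetas[i_best])
    else:
        theta = float(thetas[i_best])
    # prefer the boundary when it is as good (variance pinned at zero)
    if reml_crit(0.0) <= reml_crit(theta) + 1e-10:
        theta = 0.0

    _, Vi, XtVX, beta, q, _, _ = pieces(theta)
    sigma2_e = q / (n - p)
    sigma2_u = theta * sigma2_e
    cov_beta = sigma2_e * np.linalg.inv(XtVX)
    se = float(np.sqrt(cov_beta[1, 1]))
    fitted = X @ beta
    if np.std(fitted) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    else:
        r2 = 0.0
    # containment-style denominator df for the fixed-effect ANOVA: a
    # within-subject effect is tested against n - n_subj - (p - 1) df, a
    # between-subject effect against n_subj - p
    varies_within = any(
        len(np.unique(X[subj_idx == s, 1])) > 1 for s in range(n_subj)
    )
    if varies_within:
        df_den = n - n_subj - (p - 1)
    else:
        df_den = n_subj - p
    df_den = max(df_den, 1)
    F = (beta[1] / se) ** 2 if se > 0 else np.inf
    pval = float(stats.f.sf(F, 1, df_den))
    return LMEResult(
        intercept=float(beta[0]), slope=float(beta[1]), slope_se=se,
        sigma2_subject=float(sigma2_u), sigma2_resid=float(sigma2_e),
        r2=r2, pvalue=pval, n_obs=n, n_subjects=int(n_subj),
    )


def fit_lme_rnfl(df: pd.DataFrame, measure: str) -> LMEResult:
    """Y_measure ~ RNFL + (1 | subject) on the given cohort rows."""
    if measure not in MEASURES:
        raise PreconditionError(f"measure must be one of {MEASURES}")
    _check_cohort(df)
    df = df.dropna(subset=[measure, "rnfl_um"])
    if df["subject_id"].nunique() < 4:
        raise PreconditionError("need at least 4 subjects")
    x = df["rnfl_um"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise PreconditionError("constant RNFL: singular design")
    y = df[measure].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(x)), x])
    return _reml_fit(y, X, df["subject_id"].to_numpy())


def fit_lme_group(df: pd.DataFrame, measure: str, contrast: str) -> LMEResult:
    """Y_measure ~ Group + (1 | subject) for one pairwise contrast.

    ``contrast`` is ``"atrophic_vs_control"`` or
    ``"atrophic_vs_nonaffected"``; the slope is the atrophic-minus-comparator
    difference (comparator coded 0, atrophic coded 1).
    """
    if measure not in MEASURES:
        raise PreconditionError(f"measure must be one of {MEASURES}")
    comparators = {
        "atrophic_vs_control": "control",
        "atrophic_vs_nonaffected": "non_affected",
    }
    if contrast not in comparators:
        raise PreconditionError(f"contrast must be one of {sorted(comparators)}")
    _check_cohort(df)
    other = comparators[contrast]
    sub = df[df["group"].isin(["atrophic", other])].dropna(subset=[measure])
    for g in ("atrophic", other):
        if not np.any(sub["group"] == g):
            raise PreconditionError(f"group {g!r} has no rows")
    y = sub[measure].to_numpy(dtype=float)
    x = (sub["group"] == "atrophic").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(x)), x])
    return _reml_fit(y, X, sub["subject_id"].to_numpy())


def control_inter_eye_tests(raw: pd.DataFrame) -> dict[str, float]:
    """Mann-Whitney p-values comparing the controls' two eyes for each
    measure and for RNFL (run before eye averaging)."""
    _check_cohort(raw)
    controls = raw[raw["group"] == "control"]
    eyes = sorted(controls["eye"].unique())
    if len(eyes) != 2:
        raise PreconditionError("controls must have two distinct eye labels")
    out = {}
    for col in list(MEASURES) + ["rnfl_um"]:
        if col not in controls.columns:
            continue
        a = controls[controls["eye"] == eyes[0]][col]
        b = controls[controls["eye"] == eyes[1]][col]
        _, p = mann_whitney_u(a, b)
        out[col] = p
    return out


def group_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD table of RNFL and each measure per group."""
    _check_cohort(df)
    cols = [c for c in list(MEASURES) + ["rnfl_um"] if c in df.columns]
    return df.groupby("group")[cols].agg(["mean", "std", "count"])
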