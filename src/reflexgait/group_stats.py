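"""Inferential layer: one-factor repeated-measures ANOVA, uncorrected
pairwise comparisons, and pooling of left/right nerve datasets.

Reflex responses are tested for a phase effect (10 levels) per condition
and modulation indexes for a condition effect (4 levels) with a classical
within-subjects F test; a significant main effect licenses paired two-sided
comparisons between levels, deliberately without multiple-comparison
adjustment (Rothman's argument: corrections inflate type II error).
Normality is assumed rather than gated; a Shapiro diagnostic is logged.
Sphericity is not corrected by default; a Greenhouse-Geisser correction is
available behind ``correction="gg"``.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def _as_matrix(table) -> tuple[np.ndarray, list, list]:
    """(subjects x levels) float matrix plus row/column labels; subjects
    with missing levels are dropped (listwise) with a log entry."""
    if isinstance(table, pd.DataFrame):
        mat, rows, cols = table.to_numpy(dtype=float), list(table.index), list(table.columns)
    else:
        mat = np.asarray(table, dtype=float)
        rows = list(range(mat.shape[0]))
        cols = list(range(mat.shape[1]))
    complete = np.all(np.isfinite(mat), axis=1)
    if not complete.all():
        dropped = [rows[i] for i in np.flatnonzero(~complete)]
        log.info("rm_anova: dropping incomplete subjects %s", dropped)
    mat = mat[complete]
    rows = [r for r, keep in zip(rows, complete) if keep]
    return mat, rows, cols


def _gg_epsilon(mat: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    S = np.cov(mat, rowvar=False, ddof=1)
    k = S.shape[0]
    C = np.eye(k) - np.ones((k, k)) / k
    V = C @ S @ C
    num = np.trace(V) ** 2
    den = (k - 1) * np.trace(V @ V)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0)) if den > 0 else 1.0


def rm_anova(table, correction: str = "none") -> dict:
    """One-factor within-subjects ANOVA.

    ``table``: subjects x levels (DataFrame or array); NaN rows are dropped
    listwise.  Returns F, df1, df2, p (and the Greenhouse-Geisser epsilon
    plus corrected p when ``correction='gg'``).  A zero between-level
    variance gives F = 0, p = 1.
    """
    mat, _, _ = _as_matrix(table)
    n, k = mat.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 complete subjects and >= 2 levels, got {n} x {k}")
    grand = mat.mean()
    ss_cond = n * np.sum((mat.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((mat.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((mat - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_err = ss_err / df2
    if ms_err <= 0:
        F = 0.0 if ss_cond <= 1e-300 else float("inf")
    else:
        F = float((ss_cond / df1) / ms_err)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    out = {"F": F, "df1": df1, "df2": df2, "p": p, "n_subjects": n}
    _, sw_p = _shapiro_diag(mat)
    if sw_p is not None and sw_p < 0.05:
        log.info("rm_anova: Shapiro-Wilk on residuals p = %.3g (normality doubtful)", sw_p)
    if correction == "gg":
        eps = _gg_epsilon(mat)
        out["gg_epsilon"] = eps
        out["p_gg"] = float(stats.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
    return out


def _shapiro_diag(mat: np.ndarray):
    resid = mat - mat.mean(axis=1, keepdims=True) - mat.mean(axis=0) + mat.mean()
    flat = resid.ravel()
    if flat.size < 3 or np.allclose(flat, flat[0]):
        return None, None
    try:
        w, p = stats.shapiro(flat)
        return float(w), float(p)
    except Exception:  # pragma: no cover - diagnostic only
        return None, None


def pairwise_comparisons(table) -> pd.DataFrame:
    """Paired two-sided t tests between every pair of levels, raw
    (uncorrected) p values.  Identical paired columns give t = 0, p = 1;
    a pair with zero within-pair variance and a nonzero shift is an error
    naming the pair."""
    mat, _, cols = _as_matrix(table)
    rows = []
    for i, j in itertools.combinations(range(len(cols)), 2):
        diff = mat[:, i] - mat[:, j]
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        elif np.std(diff, ddof=1) == 0:
            raise ValueError(
                f"zero within-pair variance for levels ({cols[i]}, {cols[j]})"
            )
        else:
            t, p = stats.ttest_rel(mat[:, i], mat[:, j])
        rows.append(
            {"level_a": cols[i], "level_b": cols[j], "t": float(t), "p": float(p), "n": mat.shape[0]}
        )
    return pd.DataFrame(rows)


def pool_nerve_datasets(
    left: pd.DataFrame, right: pd.DataFrame, value_col: str = "value"
) -> pd.DataFrame:
    """Pool left- and right-nerve datasets into one table of rows (up to
    two per subject), keeping only rows where the response was evoked
    (non-missing value): only evoked responses enter group statistics."""
    frames = []
    for side, df in (("left", left), ("right", right)):
        if len(df):
            d = df.copy()
            d["side"] = side
            frames.append(d)
    if not frames:
        return pd.DataFrame(columns=["side", value_col])
    pooled = pd.concat(frames, ignore_index=True)
    return pooled[np.isfinite(pooled[value_col].astype(float))].reset_index(drop=True)


def phase_effect_table(profiles: pd.DataFrame, value_col: str = "net_value") -> pd.DataFrame:
    """Per-(muscle, family, condition) phase-effect p values from
    rm-ANOVA across subjects; shaped like the per-class phase-modulation
    tables of a reflex study.  ``profiles`` needs columns subject,
    condition, muscle, family, bin, and the value column."""
    rows = []
    for (muscle, family, cond), sub in profiles.groupby(["muscle", "family", "condition"]):
        wide = sub.pivot_table(index="subject", columns="bin", values=value_col)
        try:
            res = rm_anova(wide)
        except ValueError:
            continue
        rows.append(
            {
                "muscle": muscle,
                "family": family,
                "condition": cond,
                "F": res["F"],
                "df1": res["df1"],
                "df2": res["df2"],
                "p": res["p"],
                "n_subjects": res["n_subjects"],
            }
        )
    return pd.DataFrame(rows)
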