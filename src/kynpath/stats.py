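"""Longitudinal association engine.

Mixed-model fits of responses (reaction activity scores, metabolites, ratios,
gene expression) against disease activity with a random intercept per patient,
log-decline imputation of missing activity scores, Benjamini-Hochberg
correction, remitter/non-remitter per-week contrasts, and Spearman
correlations with FDR.

Fixed-effect inference uses the Wald normal approximation throughout; a
non-converging fit is returned as a NaN-flagged row, never as an exception
that aborts a batch.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

from .synthetic import activity_scale_max, activity_zscore

__all__ = [
    "bh_adjust",
    "impute_activity_log_decline",
    "fit_activity_lmm",
    "timepoint_contrasts",
    "spearman_with_fdr",
]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adjusted_(i) = min_{j >= i} p_(j) * m / j`` on the sorted sequence,
    capped at 1.  NaNs are ignored for ranking and propagated.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[finite] = restored
    return out


def impute_activity_log_decline(cohort: pd.DataFrame) -> pd.DataFrame:
    """Fill unobserved activity scores from per-patient ``a + b*ln(1+week)`` fits.

    Patients with >= 2 observed visits get least-squares fits (clipped to their
    scale range); a single observed visit is carried forward/backward.
    Observed values are never altered.  Raises if any patient has no observed
    score at all.
    """
    out = cohort.copy()
    scale_max = activity_scale_max(out["diagnosis"])
    no_obs = []
    for pid, grp in out.groupby("patient_id", sort=False):
        obs = grp["observed_activity"] & grp["activity"].notna()
        if not obs.any():
            no_obs.append(pid)
            continue
        if obs.all():
            continue
        weeks = grp["week"].to_numpy(dtype=float)
        act = grp["activity"].to_numpy(dtype=float)
        if obs.sum() == 1:
            fitted = np.full(len(grp), act[obs.to_numpy()][0])
        else:
            X = np.column_stack([np.ones(obs.sum()), np.log1p(weeks[obs.to_numpy()])])
            coef, *_ = np.linalg.lstsq(X, act[obs.to_numpy()], rcond=None)
            fitted = coef[0] + coef[1] * np.log1p(weeks)
        hi = scale_max[out.index.get_indexer(grp.index)]
        fitted = np.clip(fitted, 0.0, hi)
        fill = ~obs.to_numpy()
        idx = grp.index[fill]
        out.loc[idx, "activity"] = fitted[fill]
    if no_obs:
        raise ValueError(f"patients with no observed activity score: {no_obs}")
    return out


def _resolve_predictor(
    cohort: pd.DataFrame, predictor: str | pd.Series
) -> tuple[str, np.ndarray]:
    if isinstance(predictor, pd.Series):
        name = predictor.name or "predictor"
        return str(name), predictor.reindex(cohort.index).to_numpy(dtype=float)
    if predictor == "activity_z" and "activity_z" not in cohort.columns:
        return "activity_z", activity_zscore(cohort).to_numpy()
    if predictor not in cohort.columns:
        raise KeyError(f"predictor column {predictor!r} not in cohort")
    return predictor, cohort[predictor].to_numpy(dtype=float)


def _covariate_columns(cohort: pd.DataFrame, covariates: Sequence[str]) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov not in cohort.columns:
            raise KeyError(f"covariate column {cov!r} not in cohort")
        if cov == "diagnosis":
            cols["diagnosis[CD]"] = (cohort[cov].to_numpy() == "CD").astype(float)
        else:
            cols[cov] = cohort[cov].to_numpy(dtype=float)
    return cols


def _fit_mixedlm(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool, np.ndarray | None]:
    """REML random-intercept fit; returns (estimates, SEs, converged, cov_fe).

    The response is standardized internally (fixed effects and their
    covariance are rescaled back afterwards; t and p are invariant) so
    convergence speed does not depend on the response's units.
    """
    k = X.shape[1]
    m_y, s_y = float(np.mean(y)), float(np.std(y))
    if not np.isfinite(s_y) or s_y == 0:
        return np.full(k, np.nan), np.full(k, np.nan), False, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = None
        # powell is ~3x faster than the default optimizer here and reaches an
        # equal-or-better REML optimum on boundary (zero-variance) responses;
        # the default optimizer remains as fallback.  (lbfgs was rejected: it
        # can silently stop at a non-optimum on these profiles.)
        for method in ("powell", None):
            try:
                mod = MixedLM((y - m_y) / s_y, X, groups=groups)
                res = mod.fit(reml=True, method=method) if method else mod.fit(reml=True)
                break
            except (np.linalg.LinAlgError, ValueError, OverflowError):
                res = None
        if res is None:
            return np.full(k, np.nan), np.full(k, np.nan), False, None
        fe = np.asarray(res.fe_params, dtype=float) * s_y
        se = np.asarray(res.bse_fe, dtype=float) * s_y
        fe[0] += m_y  # assumes column 0 is the intercept
        cov_fe = np.asarray(res.cov_params())[:k, :k] * s_y**2
        ok = bool(np.isfinite(fe).all() and np.isfinite(se).all())
        return fe, se, ok, cov_fe


def fit_activity_lmm(
    responses: pd.DataFrame,
    cohort: pd.DataFrame,
    predictor: str | pd.Series = "activity_z",
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-response linear mixed models ``response ~ sex * predictor + covariates``
    with a random intercept per patient.

    ``responses`` must be row-aligned with ``cohort`` (same sample index).  The
    predictor is disease activity (z-scored within scale) by default, or any
    cohort column / aligned Series such as a serum Kyn:Trp vector.

    Returns a tidy frame (response, term, estimate, se, t, p, p_adj, n,
    converged); p-values are BH-adjusted across responses within each term.
    """
    if not responses.index.equals(cohort.index):
        responses = responses.reindex(cohort.index)
    pred_name, pred = _resolve_predictor(cohort, predictor)
    sex = cohort["sex"].to_numpy(dtype=float)
    cov_cols = _covariate_columns(cohort, covariates)
    terms = ["Intercept", "sex", pred_name, f"sex:{pred_name}", *cov_cols]
    base = np.column_stack(
        [np.ones(len(cohort)), sex, pred, sex * pred, *cov_cols.values()]
    )
    groups_all = cohort["patient_id"].to_numpy()

    rows = []
    for col in responses.columns:
        y = responses[col].to_numpy(dtype=float)
        mask = np.isfinite(y) & np.isfinite(base).all(axis=1)
        n = int(mask.sum())
        if n < base.shape[1] + 2:
            fe = se = np.full(base.shape[1], np.nan)
            ok = False
        else:
            fe, se, ok, _ = _fit_mixedlm(y[mask], base[mask], groups_all[mask])
        with np.errstate(invalid="ignore", divide="ignore"):
            t = fe / se
            p = 2.0 * sps.norm.sf(np.abs(t))
        for j, term in enumerate(terms):
            rows.append(
                {
                    "response": col,
                    "term": term,
                    "estimate": fe[j],
                    "se": se[j],
                    "t": t[j],
                    "p": p[j] if ok else np.nan,
                    "n": n,
                    "converged": ok,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for term in terms:
        sel = out["term"] == term
        out.loc[sel, "p_adj"] = bh_adjust(out.loc[sel, "p"].to_numpy())
    return out[["response", "term", "estimate", "se", "t", "p", "p_adj", "n", "converged"]]


def timepoint_contrasts(
    response: pd.Series,
    cohort: pd.DataFrame,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Remission-group difference (remission - non-remission) at every visit week.

    Fits ``response ~ C(week) * remitter + covariates`` with a random intercept
    per patient and extracts the group difference per week by Wald contrast.
    Weeks where only one group is present yield NaN-flagged rows.  P-values are
    BH-adjusted across weeks.
    """
    weeks = sorted(cohort["week"].unique())
    rm = cohort["remitter"].to_numpy(dtype=float)
    y_all = response.reindex(cohort.index).to_numpy(dtype=float)
    ok_rows = np.isfinite(y_all)

    both_groups = []
    for w in weeks:
        at_w = ok_rows & (cohort["week"].to_numpy() == w)
        if len(np.unique(rm[at_w])) == 2:
            both_groups.append(w)

    result_rows: list[dict] = []
    if len(both_groups) >= 1:
        mask = ok_rows & cohort["week"].isin(both_groups).to_numpy()
        sub = cohort.loc[mask]
        y = y_all[mask]
        rm_s = rm[mask]
        wk = sub["week"].to_numpy()
        ref = both_groups[0]
        cov_cols = _covariate_columns(sub, covariates)
        dummies = [(wk == w).astype(float) for w in both_groups[1:]]
        X = np.column_stack(
            [np.ones(len(sub)), *dummies, rm_s, *[d * rm_s for d in dummies], *cov_cols.values()]
        )
        fe, se_all, ok, cov_fe = _fit_mixedlm(y, X, sub["patient_id"].to_numpy())
        rm_ix = 1 + len(dummies)
        for w in both_groups:
            if not ok:
                est = se = np.nan
            else:
                L = np.zeros(X.shape[1])
                L[rm_ix] = 1.0
                if w != ref:
                    L[rm_ix + 1 + both_groups[1:].index(w)] = 1.0
                est = float(L @ fe)
                se = float(np.sqrt(L @ cov_fe @ L))
            p = 2.0 * sps.norm.sf(abs(est / se)) if ok and se > 0 else np.nan
            result_rows.append(
                {"response": response.name, "week": w, "estimate": est, "se": se, "p": p}
            )
    for w in weeks:
        if w not in both_groups:
            result_rows.append(
                {"response": response.name, "week": w, "estimate": np.nan, "se": np.nan, "p": np.nan}
            )
    out = pd.DataFrame(result_rows).sort_values("week").reset_index(drop=True)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def spearman_with_fdr(features: pd.DataFrame, target: pd.Series) -> pd.DataFrame:
    """Spearman rho of every feature column against ``target``, BH across features.

    Pairwise-complete: NaNs are dropped per feature; fewer than 3 complete
    pairs yields a NaN-flagged row.  Rho is the Pearson correlation of
    mid-ranks; p comes from the t approximation.
    """
    tgt = target.reindex(features.index).to_numpy(dtype=float)
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(tgt)
        n = int(mask.sum())
        if n < 3:
            rows.append({"feature": col, "n": n, "rho": np.nan, "p": np.nan})
            continue
        rho, p = sps.spearmanr(x[mask], tgt[mask])
        rows.append({"feature": col, "n": n, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
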