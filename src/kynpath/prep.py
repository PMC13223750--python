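"""Targeted-metabolomics preprocessing and the derived metabolite-ratio panel.

A metabolite matrix is a pandas DataFrame, samples x metabolites, holding
concentrations (uM); NaN marks values below the limits of quantitation /
detection ("missing").  The preprocessing order is fixed:

1. :func:`apply_eighty_percent_rule`  (drop metabolites with too much missingness)
2. ratios on raw concentrations       (:func:`compute_ratio_panel`)
3. :func:`impute_half_minimum`        (left-censored imputation)
4. :func:`log10_autoscale`            (log10 then per-metabolite z-scaling)

Ratios are never computed from log-scaled values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "apply_eighty_percent_rule",
    "impute_half_minimum",
    "log10_autoscale",
    "compute_ratio_panel",
    "RATIO_NAMES",
    "SUMIDO_COMPONENTS",
]

#: metabolites in the denominator of the QA:sumIDO accumulation index
SUMIDO_COMPONENTS = ("3OHAnth", "3OHKyn", "KA", "Kyn", "PA", "QA", "Xanth")

RATIO_NAMES = ("Kyn:Trp", "PA:QA", "QA:Trp", "QA:sumIDO", "QA:3OHAnth")


def _check_matrix(m: pd.DataFrame) -> None:
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("empty metabolite matrix")
    if m.columns.duplicated().any():
        dup = sorted(m.columns[m.columns.duplicated()].unique())
        raise ValueError(f"duplicate metabolite names: {dup}")


def apply_eighty_percent_rule(m: pd.DataFrame, min_nonmissing: float = 0.8) -> pd.DataFrame:
    """Keep only metabolites with a non-missing fraction >= ``min_nonmissing``.

    The boundary is inclusive: exactly 8 observed out of 10 samples is kept at
    the default threshold.  Sample set and retained values are unchanged.
    """
    _check_matrix(m)
    if not 0 < min_nonmissing <= 1:
        raise ValueError(f"min_nonmissing must be in (0, 1], got {min_nonmissing}")
    frac = m.notna().mean(axis=0)
    keep = frac[frac >= min_nonmissing].index
    return m.loc[:, keep].copy()


def impute_half_minimum(m: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing cell with half the metabolite's minimum observed value."""
    _check_matrix(m)
    all_missing = m.columns[m.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"metabolites with no observed value: {sorted(all_missing)}; "
            "apply the missingness filter first"
        )
    return m.fillna(0.5 * m.min(axis=0))


def log10_autoscale(m: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """log10-transform then z-scale each metabolite to mean 0 / sd 1.

    ``ddof=1`` (sample sd) by default.  Raises on nonpositive values or on a
    zero-variance metabolite (named in the message); NaNs, if any remain, are
    skipped and propagated.
    """
    _check_matrix(m)
    vals = m.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        bad = m.columns[(m <= 0).any(axis=0)]
        raise ValueError(f"nonpositive concentrations in: {sorted(bad)}; impute before scaling")
    logged = np.log10(vals)
    mean = np.nanmean(logged, axis=0)
    sd = np.nanstd(logged, axis=0, ddof=ddof)
    zero_var = m.columns[(sd == 0) | ~np.isfinite(sd)]
    if len(zero_var):
        raise ValueError(f"zero-variance metabolites cannot be autoscaled: {sorted(zero_var)}")
    return pd.DataFrame((logged - mean) / sd, index=m.index, columns=m.columns)


def compute_ratio_panel(m: pd.DataFrame) -> pd.DataFrame:
    """Derived ratio panel on raw concentrations.

    Columns: Kyn:Trp, PA:QA, QA:Trp, QA:sumIDO (QA over the seven-metabolite
    sum), QA:3OHAnth.  A missing component propagates NaN for that sample.
    """
    _check_matrix(m)
    required = set(SUMIDO_COMPONENTS) | {"Trp"}
    missing = sorted(required - set(m.columns))
    if missing:
        raise ValueError(f"ratio panel requires metabolite columns: {missing}")
    sum_ido = sum(m[c] for c in SUMIDO_COMPONENTS)
    panel = pd.DataFrame(
        {
            "Kyn:Trp": m["Kyn"] / m["Trp"],
            "PA:QA": m["PA"] / m["QA"],
            "QA:Trp": m["QA"] / m["Trp"],
            "QA:sumIDO": m["QA"] / sum_ido,
            "QA:3OHAnth": m["QA"] / m["3OHAnth"],
        },
        index=m.index,
    )
    return panel[list(RATIO_NAMES)]
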