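"""Synthetic longitudinal cohorts with planted kynurenine-pathway effects.

Generates the three tables the analysis consumes, with the statistical
structure the downstream stages assume:

* a cohort sheet (patient x visit, covariates, activity score, remission
  label) where remitters follow ``activity(t) = a_i - b_i * ln(1 + week)``
  with ``b_i > 0`` and non-remitters have a flat trend;
* a serum metabolite matrix (lognormal around a pathway-coupled log-mean:
  Trp falls, Kyn rises and QA accumulates with activity when QPRT is
  suppressed) with optional below-LOD left-censoring;
* a mucosal expression matrix (lognormal TPM) where log-IDO1 rises with
  activity at slope ``beta_ido1``, log-QPRT falls at slope ``beta_qprt``, and
  every other pathway gene has zero planted slope.

Activity enters every generative log-mean through the within-scale z-score
(UC total Mayo 0-12 and CD HBI 0-16 are z-scored separately before pooling),
which is also the predictor used by the association stage; planted slopes are
therefore per standardized activity unit.

All generators are deterministic functions of their :class:`SyntheticConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "generate_metabolome",
    "generate_expression",
    "activity_zscore",
    "activity_scale_max",
    "KP_GENES",
    "KP_METABOLITES",
]

#: clinical activity scale ceilings
UC_SCALE_MAX = 12.0  # total Mayo
CD_SCALE_MAX = 16.0  # HBI

#: pathway genes and their baseline TPM (geometric means)
KP_GENES: dict[str, float] = {
    "IDO1": 30.0,
    "IDO2": 1.5,
    "TDO2": 2.0,
    "KYAT1": 20.0,
    "KYAT3": 15.0,
    "AADAT": 10.0,
    "KYNU": 25.0,
    "KMO": 12.0,
    "HAAO": 18.0,
    "ACMSD": 4.0,
    "QPRT": 40.0,
    "NMNAT1": 20.0,
    "NMNAT2": 5.0,
    "NMNAT3": 8.0,
    "NADSYN1": 15.0,
    "NAMPT": 60.0,
    "TPH1": 3.0,
    "TPH2": 1.2,
    "DDC": 10.0,
}

#: serum metabolites: (baseline uM, activity coefficient on the log scale).
#: QA's coefficient is config-dependent (qa_coupling * |beta_qprt|).
KP_METABOLITES: dict[str, tuple[float, float]] = {
    "Trp": (60.0, -0.10),
    "Kyn": (2.0, +0.15),
    "KA": (0.05, +0.05),
    "Anth": (0.02, +0.03),
    "3OHKyn": (0.04, +0.08),
    "Xanth": (0.03, +0.05),
    "3OHAnth": (0.01, +0.08),
    "QA": (0.40, 0.0),  # overwritten from config
    "PA": (0.06, 0.0),
    "NAM": (0.30, 0.0),
    "Sero": (0.80, 0.0),
    "5OHTrp": (0.02, 0.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_patients: int = 60
    frac_remitters: float = 0.5
    frac_uc: float = 0.5
    weeks: tuple[int, ...] = (0, 2, 6, 14, 52)
    beta_ido1: float = 0.15
    beta_qprt: float = -0.15
    qa_coupling: float = 1.0
    noise_sd_expr: float = 0.3
    noise_sd_met: float = 0.2
    noise_sd_activity: float = 0.5
    frac_missing_activity: float = 0.0
    lod_quantile: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError(f"n_patients must be >= 2, got {self.n_patients}")
        for name in ("frac_remitters", "frac_uc", "frac_missing_activity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError(f"lod_quantile must be in [0, 1), got {self.lod_quantile}")
        weeks = tuple(self.weeks)
        if len(weeks) < 2 or any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError(f"weeks must be strictly increasing, got {weeks}")
        if weeks[0] != 0:
            raise ValueError(f"weeks must start at 0, got {weeks}")
        for name in ("noise_sd_expr", "noise_sd_met", "noise_sd_activity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.beta_qprt > 0:
            raise ValueError(f"beta_qprt must be <= 0 (suppression), got {self.beta_qprt}")
        if self.qa_coupling < 0:
            raise ValueError(f"qa_coupling must be >= 0, got {self.qa_coupling}")


def activity_scale_max(diagnosis: pd.Series) -> np.ndarray:
    """Per-row scale ceiling (Mayo 12 for UC, HBI 16 for CD)."""
    return np.where(diagnosis.to_numpy() == "UC", UC_SCALE_MAX, CD_SCALE_MAX)


def activity_zscore(cohort: pd.DataFrame) -> pd.Series:
    """Activity z-scored within each diagnosis scale (pooling harmonization)."""
    z = cohort.groupby("diagnosis")["activity"].transform(
        lambda s: (s - s.mean()) / s.std(ddof=1)
    )
    return z.rename("activity_z")


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Patient x visit sheet with covariates, activity trajectory and remission label.

    Index is the sample id ``<patient>_w<week>``.
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_patients
    weeks = np.asarray(config.weeks, dtype=float)

    n_rem = int(round(config.frac_remitters * n))
    remitter = np.zeros(n, dtype=bool)
    remitter[rng.permutation(n)[:n_rem]] = True
    n_uc = int(round(config.frac_uc * n))
    is_uc = np.zeros(n, dtype=bool)
    is_uc[rng.permutation(n)[:n_uc]] = True

    sex = rng.integers(0, 2, size=n)
    age = np.clip(rng.normal(42.0, 12.0, size=n), 18.0, 80.0)
    bmi = np.clip(rng.normal(25.0, 4.0, size=n), 16.0, 45.0)

    scale_max = np.where(is_uc, UC_SCALE_MAX, CD_SCALE_MAX)
    a0 = rng.uniform(0.5, 0.95, size=n) * scale_max
    target = rng.uniform(0.0, 0.15, size=n) * scale_max
    b = np.where(remitter, (a0 - target) / np.log1p(weeks.max()), 0.0)

    rows = []
    for i in range(n):
        pid = f"P{i:03d}"
        noise = rng.normal(0.0, config.noise_sd_activity, size=len(weeks))
        observed = rng.random(size=len(weeks)) >= config.frac_missing_activity
        observed[0] = True  # baseline score always recorded
        for j, w in enumerate(weeks):
            act = float(np.clip(a0[i] - b[i] * np.log1p(w) + noise[j], 0.0, scale_max[i]))
            rows.append(
                {
                    "sample_id": f"{pid}_w{int(w):02d}",
                    "patient_id": pid,
                    "diagnosis": "UC" if is_uc[i] else "CD",
                    "sex": int(sex[i]),
                    "age": float(age[i]),
                    "bmi": float(bmi[i]),
                    "week": int(w),
                    "activity": act,
                    "observed_activity": bool(observed[j]),
                    "remitter": bool(remitter[i]),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_metabolome(cohort: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Serum concentrations (uM), lognormal around a pathway-coupled log-mean.

    QA's planted activity slope is ``qa_coupling * |beta_qprt|``; left-censoring
    masks, per metabolite, values strictly below the ``lod_quantile`` empirical
    quantile (the threshold is recorded in ``df.attrs["lod"]``).
    """
    config.validate()
    if cohort.empty:
        raise ValueError("empty cohort")
    rng = _rng(config, 2)
    z = activity_zscore(cohort).to_numpy()
    qa_slope = config.qa_coupling * abs(config.beta_qprt)

    cols: dict[str, np.ndarray] = {}
    for met in sorted(KP_METABOLITES):
        base, coef = KP_METABOLITES[met]
        if met == "QA":
            coef = qa_slope
        log_c = np.log(base) + coef * z + rng.normal(0.0, config.noise_sd_met, size=len(z))
        cols[met] = np.exp(log_c)
    df = pd.DataFrame(cols, index=cohort.index)

    lods: dict[str, float] = {}
    if config.lod_quantile > 0:
        for met in df.columns:
            thr = float(np.quantile(df[met].to_numpy(), config.lod_quantile))
            lods[met] = thr
            df.loc[df[met] < thr, met] = np.nan
    df.attrs["lod"] = lods
    return df


def generate_expression(cohort: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Mucosal TPM matrix with planted IDO1 (up) and QPRT (down) activity slopes."""
    config.validate()
    if cohort.empty:
        raise ValueError("empty cohort")
    rng = _rng(config, 3)
    z = activity_zscore(cohort).to_numpy()
    slopes = {"IDO1": config.beta_ido1, "QPRT": config.beta_qprt}

    cols: dict[str, np.ndarray] = {}
    for gene in sorted(KP_GENES):
        base = KP_GENES[gene]
        beta = slopes.get(gene, 0.0)
        log_tpm = np.log(base) + beta * z + rng.normal(0.0, config.noise_sd_expr, size=len(z))
        cols[gene] = np.exp(log_tpm)
    return pd.DataFrame(cols, index=cohort.index)
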