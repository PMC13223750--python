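"""End-to-end orchestration: simulate-or-load -> preprocess -> RAS -> associate
-> enrich -> bottleneck report.

Every intermediate table is written as TSV into the output directory; the
final report is JSON with embedded provenance (resolved config, config hash,
seed, package version).  Runs are bit-for-bit reproducible under a fixed
config: no timestamps, stable float formatting, sorted JSON keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrich import builtin_gene_sets, gsea_es, make_ranking, read_gmt, single_sample_score
from .pathway import PathwayModel, compute_ras_matrix, load_trp_subnetwork
from .prep import apply_eighty_percent_rule, compute_ratio_panel, impute_half_minimum, log10_autoscale
from .stats import fit_activity_lmm, impute_activity_log_decline, spearman_with_fdr, timepoint_contrasts
from .synthetic import SyntheticConfig, activity_zscore, generate_cohort, generate_expression, generate_metabolome

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "flag_bottlenecks"]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    mode: str = "simulate"  # "simulate" | "load"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    paths: dict[str, str] = field(default_factory=dict)  # cohort/metabolome/expression/model/gene_sets
    covariates: tuple[str, ...] = ("age", "bmi", "diagnosis")
    or_mode: str = "sum"
    alpha: float = 0.05
    min_nonmissing: float = 0.8
    n_perm: int = 1000
    run_enrichment: bool = True

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"mode must be 'simulate' or 'load', got {self.mode!r}")
        if self.mode == "load":
            missing = [k for k in ("cohort", "metabolome", "expression") if k not in self.paths]
            if missing:
                raise ValueError(f"mode='load' requires input paths: {missing}")
        if self.mode == "simulate":
            self.synthetic.validate()
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", {})
        if seed is not None:
            raw["seed"] = seed
        run_seed = raw.get("seed", 0)
        syn.setdefault("seed", run_seed)
        if "weeks" in syn:
            syn["weeks"] = tuple(syn["weeks"])
        cfg = cls(
            synthetic=SyntheticConfig(**syn),
            covariates=tuple(raw.pop("covariates", ("age", "bmi", "diagnosis"))),
            paths=dict(raw.pop("paths", {})),
            **raw,
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["weeks"] = list(d["synthetic"]["weeks"])
        d["covariates"] = list(d["covariates"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, lineterminator="\n")


def _read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("observed_activity", "remitter"):
        if df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
        else:
            df[col] = df[col].astype(bool)
    return df


def downstream_metabolites(model: PathwayModel, start: Sequence[str]) -> set[str]:
    """Metabolites reachable from ``start`` by directed substrate->product steps.

    Spontaneous (GPR-less) reactions conduct reachability.
    """
    consumers: dict[str, list] = {}
    for r in model.reactions:
        for s in r.substrates:
            consumers.setdefault(s, []).append(r)
    seen = set(start)
    frontier = list(start)
    while frontier:
        met = frontier.pop()
        for r in consumers.get(met, ()):
            for prod in r.products:
                if prod not in seen:
                    seen.add(prod)
                    frontier.append(prod)
    return seen


def flag_bottlenecks(
    assoc: pd.DataFrame,
    model: PathwayModel,
    alpha: float = 0.05,
    term: str = "activity_z",
) -> list[str]:
    """Reactions with a significant negative activity effect lying downstream
    of at least one reaction with a significant positive activity effect.

    "Downstream" is directed substrate->product reachability on the pathway
    graph; GPR-less reactions conduct reachability but are never flagged.
    This decision rule is artifact-defined (it formalizes reading the sign
    pattern off the fitted reaction map).
    """
    rows = assoc[assoc["term"] == term]
    if rows.empty:
        raise ValueError(f"no rows with term {term!r} in association table")
    known = set(model.reaction_ids)
    unknown = sorted(set(rows["response"]) - known)
    if unknown:
        raise ValueError(f"association responses not in the pathway model: {unknown}")
    sig = rows[rows["p_adj"] < alpha]
    pos = sig.loc[sig["estimate"] > 0, "response"].tolist()
    neg = sig.loc[sig["estimate"] < 0, "response"].tolist()
    if not pos or not neg:
        return []
    reachable: set[str] = set()
    for rid in pos:
        reachable |= downstream_metabolites(model, model.get(rid).products)
    flagged = [
        rid
        for rid in model.reaction_ids  # model order, deterministic
        if rid in neg
        and model.get(rid).gpr is not None
        and any(s in reachable for s in model.get(rid).substrates)
    ]
    return flagged


def _load_inputs(config: RunConfig):
    if config.mode == "simulate":
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        cohort = generate_cohort(syn)
        metabolome = generate_metabolome(cohort, syn)
        expression = generate_expression(cohort, syn)
    else:
        cohort = _read_cohort(config.paths["cohort"])
        metabolome = pd.read_csv(config.paths["metabolome"], sep="\t", index_col=0)
        expression = pd.read_csv(config.paths["expression"], sep="\t", index_col=0)
    if "model" in config.paths:
        model = PathwayModel.from_json(config.paths["model"])
    else:
        model = load_trp_subnetwork()
    return cohort, metabolome, expression, model


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages in fixed order; returns (and writes) the bottleneck report."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage input: mode=%s", config.mode)
    cohort, metabolome, expression, model = _load_inputs(config)
    if not metabolome.index.equals(cohort.index) or not expression.index.equals(cohort.index):
        raise ValueError("metabolome/expression sample ids do not match the cohort sheet")

    # --- activity: log-decline imputation of unobserved scores, then z-scoring
    n_missing = int((~cohort["observed_activity"]).sum())
    if n_missing:
        logger.info("stage activity: imputing %d unobserved scores", n_missing)
        cohort = impute_activity_log_decline(cohort)
    cohort = cohort.assign(activity_z=activity_zscore(cohort))
    _write_tsv(cohort, out / "cohort.tsv")

    # --- metabolomics preprocessing (ratios on raw, pre-imputation)
    _write_tsv(metabolome, out / "metabolome_raw.tsv")
    filtered = apply_eighty_percent_rule(metabolome, config.min_nonmissing)
    logger.info(
        "stage prep: retained %d/%d metabolites", filtered.shape[1], metabolome.shape[1]
    )
    _write_tsv(filtered, out / "metabolome_filtered.tsv")
    ratios = compute_ratio_panel(metabolome)
    _write_tsv(ratios, out / "ratios.tsv")
    imputed = impute_half_minimum(filtered)
    _write_tsv(imputed, out / "metabolome_imputed.tsv")
    scaled = log10_autoscale(imputed)
    _write_tsv(scaled, out / "metabolome_scaled.tsv")

    # --- reaction activity scores
    _write_tsv(expression, out / "expression.tsv")
    model.to_json(out / "pathway_model.json")
    ras = compute_ras_matrix(model, expression, or_mode=config.or_mode)
    _write_tsv(ras, out / "ras.tsv")

    # --- longitudinal associations with activity
    scorable = ras.dropna(axis=1, how="all")
    assoc_ras = fit_activity_lmm(scorable, cohort, covariates=config.covariates)
    _write_tsv(assoc_ras.set_index("response"), out / "assoc_ras.tsv")
    assoc_met = fit_activity_lmm(scaled, cohort, covariates=config.covariates)
    _write_tsv(assoc_met.set_index("response"), out / "assoc_metabolites.tsv")
    assoc_ratio = fit_activity_lmm(np.log(ratios), cohort, covariates=config.covariates)
    _write_tsv(assoc_ratio.set_index("response"), out / "assoc_ratios.tsv")
    n_bad = int((~assoc_ras["converged"]).sum() + (~assoc_met["converged"]).sum())
    if n_bad:
        logger.info("stage associate: %d non-converged fits flagged", n_bad)

    # --- remitter vs non-remitter contrasts per ratio
    contrasts = pd.concat(
        [timepoint_contrasts(np.log(ratios[c]), cohort, covariates=()) for c in ratios.columns],
        ignore_index=True,
    )
    _write_tsv(contrasts.set_index("response"), out / "contrasts_ratios.tsv")

    # --- Spearman at the widest-variance visit (week 14 when present)
    week = 14 if 14 in set(cohort["week"]) else sorted(cohort["week"].unique())[len(cohort["week"].unique()) // 2]
    at_week = cohort["week"] == week
    spear = spearman_with_fdr(metabolome.loc[at_week], ratios.loc[at_week, "Kyn:Trp"])
    _write_tsv(spear.set_index("feature"), out / f"spearman_week{week}.tsv")

    # --- gene-level models, ranking, enrichment, signature scores
    enrichment_rows: list[dict] = []
    scores = None
    if config.run_enrichment:
        log_expr = np.log(expression.where(expression > 0))
        assoc_genes = fit_activity_lmm(log_expr, cohort, covariates=config.covariates)
        _write_tsv(assoc_genes.set_index("response"), out / "assoc_genes.tsv")
        ranking = make_ranking(assoc_genes)
        _write_tsv(ranking.to_frame(), out / "ranking.tsv")
        sets = builtin_gene_sets()
        if "gene_sets" in config.paths:
            sets = sets + read_gmt(config.paths["gene_sets"])
        for gs in sets:
            overlap = set(gs.genes) & set(ranking.index)
            if not overlap or len(overlap) == len(ranking):
                logger.info("stage enrich: skipping set %s (overlap %d)", gs.name, len(overlap))
                continue
            r = gsea_es(ranking, gs, n_perm=config.n_perm, seed=config.seed)
            enrichment_rows.append(dataclasses.asdict(r))
        if enrichment_rows:
            _write_tsv(pd.DataFrame(enrichment_rows).set_index("name"), out / "enrichment.tsv")
        scores = pd.DataFrame(
            {
                gs.name: [single_sample_score(expression.loc[s], gs) for s in expression.index]
                for gs in sets
            },
            index=expression.index,
        )
        _write_tsv(scores, out / "signature_scores.tsv")

    # --- bottleneck flagging and report
    flagged = flag_bottlenecks(assoc_ras, model, alpha=config.alpha)
    logger.info("stage report: flagged bottleneck reactions: %s", flagged)

    act = assoc_ras[assoc_ras["term"] == "activity_z"].set_index("response")
    report = {
        "flagged_bottlenecks": flagged,
        "reaction_activity_effects": {
            rid: {
                "estimate": _jsonify(act.loc[rid, "estimate"]),
                "t": _jsonify(act.loc[rid, "t"]),
                "p_adj": _jsonify(act.loc[rid, "p_adj"]),
            }
            for rid in act.index
        },
        "metabolite_activity_effects": _effects_dict(assoc_met),
        "ratio_activity_effects": _effects_dict(assoc_ratio),
        "enrichment": enrichment_rows,
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "kynpath_version": __version__,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _jsonify(x) -> float | None:
    x = float(x)
    return None if not np.isfinite(x) else x


def _effects_dict(assoc: pd.DataFrame, term: str = "activity_z") -> dict:
    rows = assoc[assoc["term"] == term].set_index("response")
    return {
        str(r): {
            "estimate": _jsonify(rows.loc[r, "estimate"]),
            "t": _jsonify(rows.loc[r, "t"]),
            "p_adj": _jsonify(rows.loc[r, "p_adj"]),
        }
        for r in rows.index
    }
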