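"""Enrichment and signature machinery.

* ranking construction from mixed-model t-values (main effect + sex
  interaction, summed per gene);
* weighted Kolmogorov-Smirnov permutation GSEA (gene-label permutation null);
* hypergeometric overrepresentation;
* rank-based single-sample gene-set scoring (monotone-transform invariant,
  bounded in [-0.5, +0.5]);
* GMT gene-set parsing and the built-in IFN-gamma signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "make_ranking",
    "gsea_es",
    "hypergeom_overrepresentation",
    "single_sample_score",
    "builtin_gene_sets",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be nonempty")
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    es: float
    p: float
    size: int
    direction: str  # "up" | "down"
    n_perm: int


#: interferon-gamma response signature (6 genes)
IFNG_SET = GeneSet(
    name="IFNG",
    genes=("IFITM1", "MX1", "OAS3", "IFIT1", "IFI44L", "IFI16"),
    description="interferon-gamma response signature",
)


def builtin_gene_sets() -> list[GeneSet]:
    """Packaged gene sets.

    Only the IFN-gamma signature ships with the package; TNF and IL23 sets are
    user-supplied via GMT (their memberships are defined by external
    references and are never hard-coded here).
    """
    return [IFNG_SET]


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (name <TAB> description <TAB> gene...); duplicate
    symbols within a line are dropped with a warning."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        name, desc, *genes = parts
        seen: dict[str, None] = {}
        for g in genes:
            if not g:
                continue
            if g in seen:
                warnings.warn(f"{path}:{lineno}: duplicate symbol {g!r} in set {name!r}")
            seen[g] = None
        sets.append(GeneSet(name=name, genes=tuple(seen), description=desc))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, s.description, *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def make_ranking(
    assoc: pd.DataFrame,
    main_term: str = "activity_z",
    interaction_term: str | None = None,
) -> pd.Series:
    """Gene ranking statistic: t(main effect) + t(sex interaction), per gene.

    ``assoc`` is the tidy output of :func:`kynpath.stats.fit_activity_lmm`.
    Genes with a NaN t-value in either term are excluded (count logged).
    """
    if assoc.empty:
        raise ValueError("empty association table")
    if interaction_term is None:
        interaction_term = f"sex:{main_term}"
    wide = assoc.pivot_table(index="response", columns="term", values="t", aggfunc="first")
    for term in (main_term, interaction_term):
        if term not in wide.columns:
            raise KeyError(f"term {term!r} not present in association table")
    stat = wide[main_term] + wide[interaction_term]
    n_excluded = int(stat.isna().sum())
    if n_excluded:
        logger.info("ranking: excluded %d genes with NaN t-values", n_excluded)
    return stat.dropna().rename("rank_stat")


def _running_es(stats_sorted: np.ndarray, member: np.ndarray, exponent: float = 1.0) -> float:
    """Signed ES of the weighted KS running sum; ``stats_sorted`` descending."""
    w = np.abs(stats_sorted) ** exponent * member
    total = w.sum()
    n, s = member.size, int(member.sum())
    if total > 0:
        hit = np.cumsum(w) / total
    else:  # all member stats zero: fall back to unweighted steps
        hit = np.cumsum(member) / s
    miss = np.cumsum(1.0 - member) / (n - s) if n > s else np.zeros(n)
    running = hit - miss
    return float(running[np.argmax(np.abs(running))])


def gsea_es(
    ranking: Mapping[str, float] | pd.Series,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
) -> EnrichmentResult:
    """Weighted KS enrichment score with a gene-label permutation p-value.

    ``p = (1 + #{|ES*| >= |ES|}) / (n_perm + 1)``, so p is floored at
    ``1/(n_perm+1)``.  Deterministic under a fixed seed.
    """
    s = pd.Series(ranking, dtype=float).dropna()
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    # sort descending, gene name as deterministic tie-break
    s = s.sort_index().sort_values(ascending=False, kind="stable")
    genes = s.index.to_numpy()
    stats_sorted = s.to_numpy()
    member = np.isin(genes, list(gene_set.genes)).astype(float)
    size = int(member.sum())
    if size == 0:
        raise ValueError(f"gene set {gene_set.name!r} is disjoint from the ranking")
    if size == member.size:
        raise ValueError(f"gene set {gene_set.name!r} covers the whole ranking")
    es = _running_es(stats_sorted, member, exponent)

    rng = np.random.default_rng(seed)
    n = member.size
    count = 0
    for _ in range(n_perm):
        perm = np.zeros(n)
        perm[rng.choice(n, size=size, replace=False)] = 1.0
        if abs(_running_es(stats_sorted, perm, exponent)) >= abs(es):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return EnrichmentResult(
        name=gene_set.name,
        es=es,
        p=p,
        size=size,
        direction="up" if es >= 0 else "down",
        n_perm=n_perm,
    )


def hypergeom_overrepresentation(
    hits: Sequence[str], universe: Sequence[str], gene_set: GeneSet
) -> float:
    """Upper-tail hypergeometric probability of >= the observed overlap."""
    uni = set(universe)
    hit_set = set(hits)
    if not hit_set <= uni:
        raise ValueError(f"hits not a subset of the universe: {sorted(hit_set - uni)[:5]}")
    members = set(gene_set.genes) & uni
    overlap = len(hit_set & members)
    M, K, n = len(uni), len(members), len(hit_set)
    # P(X >= overlap), X ~ Hypergeom(M, K, n)
    return float(sps.hypergeom.sf(overlap - 1, M, K, n))


def single_sample_score(
    expr_sample: Mapping[str, float] | pd.Series, gene_set: GeneSet
) -> float:
    """Rank-based single-sample score for an up-set.

    All measured genes are mid-ranked ascending; the score is the centered mean
    rank of the set genes scaled so the extremes are exactly +/-0.5 (set genes
    occupying the top |S| ranks score +0.5, the bottom |S| score -0.5).
    Invariant under any strictly monotone transform of expression.
    """
    s = pd.Series(expr_sample, dtype=float).dropna()
    n = len(s)
    member = s.index.isin(gene_set.genes)
    size = int(member.sum())
    if size == 0:
        return float("nan")
    if size == n:
        return 0.0
    ranks = sps.rankdata(s.to_numpy(), method="average")
    mean_rank = float(ranks[member].mean())
    return (mean_rank - (n + 1) / 2.0) / (n - size)
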