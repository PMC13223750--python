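"""Pathway models (reactions + GPR rules) and reaction activity score matrices."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .gpr import GPRExpr, gpr_genes, gpr_to_string, parse_gpr, reaction_activity_score

__all__ = [
    "Reaction",
    "PathwayModel",
    "load_trp_subnetwork",
    "compute_ras_matrix",
]


@dataclass(frozen=True)
class Reaction:
    """A reaction: substrates -> products, optionally gated by a GPR rule.

    ``gpr is None`` marks a spontaneous (non-enzymatic) reaction; it conducts
    reachability in the pathway graph but carries no activity score.
    """

    reaction_id: str
    name: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    gpr: GPRExpr | None = None

    def __post_init__(self) -> None:
        if not self.reaction_id:
            raise ValueError("reaction_id must be nonempty")
        if not self.substrates or not self.products:
            raise ValueError(f"reaction {self.reaction_id}: substrate/product lists must be nonempty")


@dataclass(frozen=True)
class PathwayModel:
    name: str
    reactions: tuple[Reaction, ...]
    metabolites: dict[str, str] = field(default_factory=dict)  # id -> display name

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [r.reaction_id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate reaction ids: {dup}")
        declared = set(self.metabolites)
        for r in self.reactions:
            undeclared = (set(r.substrates) | set(r.products)) - declared
            if undeclared:
                raise ValueError(
                    f"reaction {r.reaction_id} references undeclared metabolites: {sorted(undeclared)}"
                )

    @property
    def reaction_ids(self) -> list[str]:
        return [r.reaction_id for r in self.reactions]

    def get(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.reaction_id == reaction_id:
                return r
        raise KeyError(reaction_id)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= gpr_genes(r.gpr)
        return out

    # --- JSON round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "metabolites": dict(self.metabolites),
            "reactions": [
                {
                    "id": r.reaction_id,
                    "name": r.name,
                    "substrates": list(r.substrates),
                    "products": list(r.products),
                    "gpr": None if r.gpr is None else gpr_to_string(r.gpr),
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayModel":
        reactions = tuple(
            Reaction(
                reaction_id=r["id"],
                name=r.get("name", r["id"]),
                substrates=tuple(r["substrates"]),
                products=tuple(r["products"]),
                gpr=None if r.get("gpr") in (None, "") else parse_gpr(r["gpr"]),
            )
            for r in d["reactions"]
        )
        return cls(name=d.get("name", "pathway"), reactions=reactions, metabolites=dict(d.get("metabolites", {})))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_trp_subnetwork() -> PathwayModel:
    """The packaged tryptophan-degradation subnetwork.

    Covers the kynurenine arm Trp -> Kyn -> ... -> QA -> NAMN -> NAD+ (with
    ``R24a`` = QA -> NAMN gated by QPRT), the serotonin branch, and the
    nicotinamide salvage entry.  Reaction ids other than ``R24a`` are local to
    this fixture.
    """
    text = resources.files("kynpath.data").joinpath("trp_subnetwork.json").read_text()
    return PathwayModel.from_dict(json.loads(text))


def compute_ras_matrix(
    model: PathwayModel,
    expression: pd.DataFrame,
    or_mode: str = "sum",
) -> pd.DataFrame:
    """Reaction activity scores for every (sample, reaction).

    Parameters
    ----------
    model : PathwayModel
    expression : DataFrame
        Samples x genes, nonnegative TPM.  Genes missing from the matrix are
        treated as unmeasured (see :func:`kynpath.gpr.reaction_activity_score`).
    or_mode : {"sum", "max"}

    Returns a samples x reactions DataFrame; GPR-less reactions yield a NaN
    column.
    """
    if not model.reactions:
        raise ValueError("empty pathway model")
    vals = expression.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("expression matrix must be nonnegative")
    out = pd.DataFrame(
        np.nan, index=expression.index, columns=model.reaction_ids, dtype=float
    )
    records = expression.to_dict("index")
    for r in model.reactions:
        if r.gpr is None:
            continue
        col = np.empty(len(expression), dtype=float)
        for i, sample in enumerate(expression.index):
            col[i] = reaction_activity_score(r.gpr, records[sample], or_mode=or_mode)
        out[r.reaction_id] = col
    return out
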