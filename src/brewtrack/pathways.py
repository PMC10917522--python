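"""Pathway perturbation scoring (DRPS / DPPS).

For a reaction, the differential reaction perturbation score (DRPS) is the
largest between-sample spread among the reaction's measured entities:
``max over entities of (max sample value - min sample value)``, computed on
row-mean-normalized log2 abundances. A pathway's differential pathway
perturbation score (DPPS) is the root mean square of its reaction DRPS
values::

    DPPS = sqrt( sum(DRPS_i^2) / n_reactions )

where ``n_reactions`` is by default the *total* reaction count of the
pathway — reactions without any measured entity score 0 but still enlarge
the divisor (``measured_only=True`` flips to dividing by reactions with
data). Multi-enzyme reactions take the maximum over their isozymes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .matrix import AbundanceMatrix


@dataclass(frozen=True)
class PathwayModel:
    """A pathway as an ordered mapping reaction id -> entity (protein) ids."""

    pathway_id: str
    reactions: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        if not self.reactions:
            raise InputError(f"pathway {self.pathway_id} has no reactions")
        for rid, entities in self.reactions.items():
            if not entities:
                raise InputError(f"reaction {rid} of {self.pathway_id} has no entities")


@dataclass
class PerturbationScore:
    pathway_id: str
    dpps: float
    n_reactions: int
    n_reactions_with_data: int
    drps_by_reaction: dict[str, float] = field(default_factory=dict)
    no_data_reactions: list[str] = field(default_factory=list)


def pathways_from_table(table: pd.DataFrame) -> list[PathwayModel]:
    """Build PathwayModels from a (pathway_id, reaction_id, protein_id) table."""
    for col in ("pathway_id", "reaction_id", "protein_id"):
        if col not in table.columns:
            raise InputError(f"pathway table lacks column {col!r}")
    models = []
    for pid, sub in table.groupby("pathway_id", sort=True):
        reactions = {
            rid: frozenset(g["protein_id"])
            for rid, g in sub.groupby("reaction_id", sort=True)
        }
        models.append(PathwayModel(pathway_id=pid, reactions=reactions))
    return models


def _profile_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, AbundanceMatrix):
        return profiles.values
    return profiles


def drps(entities: Iterable[str], profiles, exclude: frozenset = frozenset()) -> tuple[float, bool]:
    """DRPS of one reaction: max entity range across samples.

    Entities without data (or excluded) are skipped; returns ``(score,
    has_data)`` where ``has_data`` is False when no entity was measured
    (score 0, flagged).
    """
    df = _profile_frame(profiles)
    best = 0.0
    has_data = False
    for ent in entities:
        if ent in exclude or ent not in df.index:
            continue
        row = df.loc[ent].dropna()
        if row.empty:
            continue
        has_data = True
        best = max(best, float(row.max() - row.min()))
    return (best if has_data else 0.0), has_data


def dpps(pathway: PathwayModel, profiles, exclude: Iterable[str] = (),
         measured_only: bool = False) -> PerturbationScore:
    """Score one pathway; see module docstring for the formula."""
    exclude = frozenset(exclude)
    drps_by_reaction: dict[str, float] = {}
    no_data: list[str] = []
    for rid, entities in pathway.reactions.items():
        score, has_data = drps(entities, profiles, exclude=exclude)
        drps_by_reaction[rid] = score
        if not has_data:
            no_data.append(rid)
    n_total = len(pathway.reactions)
    n_with_data = n_total - len(no_data)
    divisor = n_with_data if measured_only else n_total
    if divisor == 0:
        value = 0.0
    else:
        value = float(np.sqrt(sum(v * v for v in drps_by_reaction.values()) / divisor))
    return PerturbationScore(pathway_id=pathway.pathway_id, dpps=value,
                             n_reactions=n_total, n_reactions_with_data=n_with_data,
                             drps_by_reaction=drps_by_reaction, no_data_reactions=no_data)


def score_pathways(pathways: Sequence[PathwayModel], profiles,
                   exclude: Iterable[str] = (), measured_only: bool = False) -> pd.DataFrame:
    """Score every pathway; one row per pathway with DPPS and reaction counts."""
    if not pathways:
        raise InputError("at least one pathway is required")
    rows = []
    for pw in pathways:
        s = dpps(pw, profiles, exclude=exclude, measured_only=measured_only)
        rows.append({"pathway_id": s.pathway_id, "dpps": s.dpps,
                     "n_reactions": s.n_reactions,
                     "n_reactions_with_data": s.n_reactions_with_data})
    return pd.DataFrame(rows)


def rank_pathways(scores: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Order pathways by descending DPPS, ties broken by pathway id.

    Adds a 1-based ``rank`` column; ``top_n`` truncates the table.
    """
    if scores.empty:
        raise InputError("no scored pathways to rank")
    ranked = scores.sort_values(["dpps", "pathway_id"],
                                ascending=[False, True], kind="stable").reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    if top_n is not None:
        ranked = ranked.head(top_n)
    return ranked


def leave_out_rerank(pathways: Sequence[PathwayModel], profiles,
                     excluded: Iterable[str],
                     measured_only: bool = False) -> pd.DataFrame:
    """Re-rank pathways with a set of proteins removed from every reaction.

    Returns one row per pathway with old/new DPPS and rank and the rank
    delta (positive = demoted). Pathways whose reactions lose all measured
    entities score 0 and are flagged ``emptied``.
    """
    excluded = frozenset(excluded)
    if not excluded:
        raise InputError("excluded protein set must be non-empty")
    before = rank_pathways(score_pathways(pathways, profiles, measured_only=measured_only))
    after = rank_pathways(score_pathways(pathways, profiles, exclude=excluded,
                                         measured_only=measured_only))
    merged = before.merge(after, on="pathway_id", suffixes=("_before", "_after"))
    merged["rank_delta"] = merged["rank_after"] - merged["rank_before"]
    merged["emptied"] = merged["n_reactions_with_data_after"] == 0
    cols = ["pathway_id", "dpps_before", "dpps_after", "rank_before", "rank_after",
            "rank_delta", "emptied"]
    return merged[cols].sort_values("rank_before").reset_index(drop=True)
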