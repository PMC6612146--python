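"""Candidate ranking, stereoisomer collapse, and Top-k evaluation metrics.

Candidate lists are cleaned (disconnected structures and non-natural
isotopes removed), scored, collapsed so that only the best-scoring
stereoisomer of each molecular skeleton (InChIKey first block) remains,
and ranked by consensus score. Evaluation reports Top1/Top3/Top10 counts
plus mean and median rank of the correct candidate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from rdkit import Chem

from .annotation import AnnotationModel
from .spectra import Candidate, Spectrum

__all__ = [
    "RankedCandidateList",
    "filter_candidates",
    "collapse_stereoisomers",
    "rank_of_correct",
    "summarize",
    "rank_candidates",
]

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("s_metfrag", "s_peak", "s_loss", "s_fin")


@dataclass
class RankedCandidateList:
    """Scored, stereo-collapsed, ranked candidates of one query."""

    query_id: str
    rows: pd.DataFrame  # candidate_id, inchikey_block1, scores, correct, rank

    @property
    def correct_rank(self) -> int:
        return rank_of_correct(self.rows)


def filter_candidates(cands: Sequence[Candidate]) -> list[Candidate]:
    """Drop candidates with disconnected structures or isotope labels."""
    out = []
    for c in cands:
        if len(Chem.GetMolFrags(c.structure)) != 1:
            logger.warning("candidate %s: disconnected structure, dropped", c.id)
            continue
        if any(a.GetIsotope() != 0 for a in c.structure.GetAtoms()):
            logger.warning("candidate %s: non-natural isotope, dropped", c.id)
            continue
        out.append(c)
    return out


def collapse_stereoisomers(rows: pd.DataFrame) -> pd.DataFrame:
    """Keep only the best-scoring row per InChIKey first block, then re-rank.

    The ``correct`` flag survives if any member of the collapsed group was
    correct.
    """
    df = rows.copy()
    keep_idx = df.groupby("inchikey_block1")["s_fin"].idxmax()
    collapsed = df.loc[sorted(keep_idx)].copy()
    if "correct" in df.columns:
        correct_blocks = set(df.loc[df["correct"], "inchikey_block1"])
        collapsed["correct"] = collapsed["inchikey_block1"].isin(correct_blocks)
    collapsed = collapsed.sort_values("s_fin", ascending=False, kind="stable")
    collapsed["rank"] = range(1, len(collapsed) + 1)
    return collapsed.reset_index(drop=True)


def rank_of_correct(rows: pd.DataFrame, tie_convention: str = "worst") -> int:
    """Rank of the correct candidate among the (collapsed) rows.

    ``worst`` (default) counts score ties as better (rank = 1 + #greater +
    #tied); ``mid`` places the correct candidate at the rounded-up middle
    of its tie group.
    """
    correct = rows[rows["correct"]]
    if len(correct) != 1:
        raise ValueError(f"expected exactly one correct row, got {len(correct)}")
    s = float(correct["s_fin"].iloc[0])
    greater = int((rows["s_fin"] > s).sum())
    tied = int((rows["s_fin"] == s).sum()) - 1
    if tie_convention == "worst":
        return 1 + greater + tied
    if tie_convention == "mid":
        return 1 + greater + math.ceil(tied / 2)
    raise ValueError(f"unknown tie convention {tie_convention!r}")


def summarize(ranks: Sequence[int]) -> dict:
    """Top1/Top3/Top10 counts and mean/median rank of a rank list."""
    if not ranks:
        raise ValueError("summarize needs at least one rank")
    if min(ranks) < 1:
        raise ValueError("ranks must be >= 1")
    s = pd.Series(list(ranks), dtype=float)
    return {
        "n": len(ranks),
        "top1": int((s <= 1).sum()),
        "top3": int((s <= 3).sum()),
        "top10": int((s <= 10).sum()),
        "mean_rank": float(s.mean()),
        "median_rank": float(s.median()),
    }


def rank_candidates(model: AnnotationModel, spectrum: Spectrum,
                    candidates: Sequence[Candidate],
                    correct_block1: str | None = None,
                    tie_convention: str = "worst") -> RankedCandidateList:
    """Filter, score, collapse, and rank a candidate list for one query."""
    cands = filter_candidates(candidates)
    if not cands:
        raise ValueError(f"no scoreable candidates for query {spectrum.id!r}")
    rows = model.score_query(spectrum, cands)
    if correct_block1 is not None:
        rows["correct"] = rows["inchikey_block1"] == correct_block1
    collapsed = collapse_stereoisomers(rows)
    return RankedCandidateList(query_id=spectrum.id, rows=collapsed)
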