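"""Consensus aggregation of docking scores across methods.

Two aggregations hedge single-method outliers: the consensus score (CS),
the per-ligand arithmetic mean of the method scores (kJ/mol, more negative
is better), and the consensus rank (CR), the per-ligand mean of the
within-method ranks.  Ranking is ascending by score (most negative = rank
1) with average ranks on ties; the final CS/CR orderings break remaining
ties deterministically by ligand id.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = ["consensus_score", "consensus_rank", "consensus_table"]


def _score_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c not in ("CS", "CS_rank", "CR_rank", "RMSD")]
    if not cols:
        raise ValueError("score table has no method columns")
    return cols


def _check(table: pd.DataFrame) -> pd.DataFrame:
    scores = table[_score_columns(table)]
    empty = scores.isna().all(axis=1)
    if empty.any():
        warnings.warn(
            f"ligands with no scores are excluded: {list(table.index[empty])}",
            stacklevel=3,
        )
    if scores.notna().sum(axis=1).lt(len(scores.columns)).any() and not empty.all():
        missing = scores.isna().any(axis=1) & ~empty
        if missing.any():
            warnings.warn(
                f"missing scores for ligands {list(table.index[missing])}; "
                "their consensus uses the available methods only",
                stacklevel=3,
            )
    return table[~empty]


def consensus_score(table: pd.DataFrame) -> pd.Series:
    """Per-ligand consensus score: mean over available method scores."""
    table = _check(table)
    return table[_score_columns(table)].mean(axis=1).rename("CS")


def consensus_rank(table: pd.DataFrame) -> pd.Series:
    """Per-ligand consensus (mean) rank across methods."""
    table = _check(table)
    ranks = table[_score_columns(table)].rank(axis=0, method="average", ascending=True)
    return ranks.mean(axis=1).rename("CR")


def consensus_table(table: pd.DataFrame) -> pd.DataFrame:
    """CS, CR and their final orderings for a ligand x method score table.

    Returns a DataFrame indexed like the input with columns ``CS``, ``CS_rank``,
    ``CR``, ``CR_rank``; final rank ties are broken by ligand id.
    """
    cs = consensus_score(table)
    cr = consensus_rank(table)
    out = pd.DataFrame({"CS": cs, "CR": cr})
    out["CS_rank"] = _id_tiebreak_rank(out["CS"])
    out["CR_rank"] = _id_tiebreak_rank(out["CR"])
    return out[["CS", "CS_rank", "CR", "CR_rank"]]


def _id_tiebreak_rank(values: pd.Series) -> pd.Series:
    order = sorted(values.index, key=lambda lig: (values[lig], lig))
    rank = {lig: i + 1 for i, lig in enumerate(order)}
    return pd.Series([rank[lig] for lig in values.index], index=values.index, dtype=int)
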