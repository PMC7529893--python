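"""Proteome scanning for degron-consensus matches and matrix-scored ranking."""

from __future__ import annotations

import io
import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .degron import AMINO_ACIDS, MOTIF_LENGTH, AffinityMatrix, DegronPattern, score_window

HIT_COLUMNS = ["protein_id", "offset", "window", "consensus_match", "score", "annotation"]


def _iter_fasta(proteome) -> Iterable:
    """Yield Biopython SeqRecords from a path, open handle, or FASTA text."""
    if hasattr(proteome, "read"):
        handle = proteome
    elif isinstance(proteome, os.PathLike) or (
        isinstance(proteome, str)
        and not proteome.lstrip().startswith(">")
        and os.path.exists(proteome)
    ):
        handle = open(proteome)
    else:
        handle = io.StringIO(str(proteome))
    with handle:
        idx = 0
        for record in SeqIO.parse(handle, "fasta"):
            if not record.id:
                raise ValueError(f"malformed FASTA: record {idx} has no identifier")
            yield record
            idx += 1


def scan(
    pattern: DegronPattern,
    proteome,
    matrix: AffinityMatrix | None = None,
    score_min: float | None = None,
) -> pd.DataFrame:
    """Report every 13-mer window matching the consensus pattern.

    Parameters
    ----------
    pattern
        The per-position residue-class consensus.
    proteome
        FASTA path, open handle, or FASTA-formatted text.
    matrix
        Optional affinity matrix; when given, each hit carries its additive
        log2 score.
    score_min
        Optional score threshold (requires ``matrix``); hits scoring below it
        are dropped.

    Windows are strictly intra-protein, offsets 1-based.  Overlapping hits are
    all reported.  Output is sorted by (protein_id, offset).
    """
    if score_min is not None and matrix is None:
        raise ValueError("score_min requires a matrix")

    rows = []
    for record in _iter_fasta(proteome):
        seq = str(record.seq).upper()
        for start in range(len(seq) - MOTIF_LENGTH + 1):
            window = seq[start : start + MOTIF_LENGTH]
            if not all(res in cls_ for res, cls_ in zip(window, pattern.classes)):
                continue
            score = score_window(matrix, window) if matrix is not None else None
            if score_min is not None and score < score_min:
                continue
            rows.append(
                {
                    "protein_id": record.id,
                    "offset": start + 1,
                    "window": window,
                    "consensus_match": True,
                    "score": score,
                    "annotation": "",
                }
            )
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return hits.sort_values(["protein_id", "offset"], kind="stable").reset_index(drop=True)


def rank_candidates(hits: pd.DataFrame, per_protein: str = "all") -> pd.DataFrame:
    """Rank scored hits by descending score, stable tie-break by (protein_id, offset).

    With ``per_protein="best"`` only the top-scoring window of each protein is
    kept (first by offset on ties).
    """
    if per_protein not in ("all", "best"):
        raise ValueError("per_protein must be 'all' or 'best'")
    if hits.empty:
        return hits.copy()
    if hits["score"].isna().any():
        raise ValueError("hits must be scored before ranking")
    # stable two-stage sort: tie-break keys first, then primary key
    ranked = hits.sort_values(["protein_id", "offset"], kind="stable")
    ranked = ranked.sort_values("score", ascending=False, kind="stable")
    if per_protein == "best":
        ranked = ranked.groupby("protein_id", sort=False).head(1)
    return ranked.reset_index(drop=True)
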