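"""Position-specific affinity matrix and consensus pattern for a 13-mer degron.

A saturation substitution array measures the binding potency (IC50-equivalent,
nM) of every single-residue variant of a 13-mer degron peptide.  From those
measurements this module builds a 13 x 20 position-specific affinity weight
matrix, identifies the key binding positions from the alanine-scan subset,
derives a bracket-class consensus pattern such as
``[FLWY]-X6-[IV]-[KR]-X-[ILMV]-[FLWY]``, and scores arbitrary 13-mer windows
by additive log2 weights.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Length of the degron window.
MOTIF_LENGTH = 13

#: PCF11 degron 13-mer (PCF11 residues 682-694).
PCF11_DEGRON = "FLVVVHQIRQLFQ"


def _check_window(window: str) -> str:
    window = str(window).upper()
    if len(window) != MOTIF_LENGTH:
        raise ValueError(f"window must be a {MOTIF_LENGTH}-mer, got {len(window)} residues")
    return window


@dataclass
class AffinityMatrix:
    """Per-position-normalized relative binding affinities of a 13-mer degron.

    ``weights`` is a 13 x 20 table (index = 1-based position, columns = the
    standard amino acids) of relative affinities in [0, 1].  Each position is
    normalized so its strongest binder has weight exactly 1.  No-binding
    measurements are assigned ``no_binding_floor`` (a fraction of the
    per-position maximum raw affinity) before normalization.
    """

    wild_type: str
    weights: pd.DataFrame
    reference_potency: float
    no_binding_floor: float = 1e-3

    def __post_init__(self) -> None:
        self.wild_type = _check_window(self.wild_type)
        if list(self.weights.index) != list(range(1, MOTIF_LENGTH + 1)):
            raise ValueError("weights index must be positions 1..13")
        if list(self.weights.columns) != list(AMINO_ACIDS):
            raise ValueError("weights columns must be the 20 standard residues")
        w = self.weights.to_numpy()
        if np.any(w < 0) or np.any(w > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        if not np.allclose(w.max(axis=1), 1.0):
            raise ValueError("each position's maximum weight must equal 1")

    def weight(self, position: int, residue: str) -> float:
        """Weight of ``residue`` at 1-based ``position``; floor for non-standard letters."""
        residue = residue.upper()
        if residue not in AMINO_ACIDS:
            return float(self.no_binding_floor)
        return float(self.weights.at[position, residue])

    def to_tsv(self, path) -> None:
        self.weights.to_csv(path, sep="\t", index_label="position")


@dataclass
class DegronPattern:
    """Ordered per-position residue classes of a degron consensus.

    A class equal to the full 20-residue alphabet renders as the wildcard
    ``X``; runs of wildcards are collapsed (``X6``); multi-residue classes
    render as alphabetical bracket sets, single residues as bare letters.
    A trailing wildcard run is omitted (the motif is anchored at its first
    constrained position, so unconstrained tail positions carry no
    information); parsing pads short patterns back to 13 classes, making the
    render/parse round trip an identity.
    """

    classes: list = field(default_factory=list)

    FULL = frozenset(AMINO_ACIDS)

    def __post_init__(self) -> None:
        if len(self.classes) != MOTIF_LENGTH:
            raise ValueError(f"pattern must have exactly {MOTIF_LENGTH} classes")
        self.classes = [frozenset(c) for c in self.classes]
        for i, c in enumerate(self.classes, start=1):
            if not c:
                raise ValueError(f"class at position {i} is empty")
            bad = set(c) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"non-standard residues {sorted(bad)} at position {i}")

    def render(self) -> str:
        classes = list(self.classes)
        # drop an uninformative trailing wildcard run, unless all-wildcard
        if any(c != self.FULL for c in classes):
            while classes and classes[-1] == self.FULL:
                classes.pop()
        tokens: list[str] = []
        i = 0
        while i < len(classes):
            c = classes[i]
            if c == self.FULL:
                j = i
                while j < len(classes) and classes[j] == self.FULL:
                    j += 1
                run = j - i
                tokens.append("X" if run == 1 else f"X{run}")
                i = j
            else:
                letters = "".join(sorted(c))
                tokens.append(letters if len(letters) == 1 else f"[{letters}]")
                i += 1
        return "-".join(tokens)

    @classmethod
    def parse(cls, text: str) -> "DegronPattern":
        classes: list[frozenset] = []
        for token in text.strip().split("-"):
            m = re.fullmatch(r"X(\d*)", token)
            if m:
                run = int(m.group(1)) if m.group(1) else 1
                classes.extend([cls.FULL] * run)
                continue
            m = re.fullmatch(r"\[([A-Z]+)\]", token)
            if m:
                classes.append(frozenset(m.group(1)))
                continue
            if re.fullmatch(r"[A-Z]", token):
                classes.append(frozenset(token))
                continue
            raise ValueError(f"unparseable pattern token: {token!r}")
        if len(classes) > MOTIF_LENGTH:
            raise ValueError(f"pattern longer than {MOTIF_LENGTH} positions")
        classes.extend([cls.FULL] * (MOTIF_LENGTH - len(classes)))
        return cls(classes)

    def matches(self, window: str) -> bool:
        """True when every residue of the 13-mer is in its position's class.

        Non-standard letters (U, X, B, Z, ...) are absent from every class and
        therefore never match.
        """
        window = _check_window(window)
        return all(res in cls_ for res, cls_ in zip(window, self.classes))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def aggregate_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean aggregation of replicate potencies per (position, sub).

    Assay noise is multiplicative (log-normal), so replicate potencies are
    combined on the log scale.  Rows with missing potency (no binding) force
    the aggregate to missing only if all replicates are missing.
    """
    def gmean(s: pd.Series) -> float:
        vals = s.dropna()
        if vals.empty:
            return np.nan
        return float(np.exp(np.log(vals.astype(float)).mean()))

    out = (
        records.groupby(["position", "wt", "sub"], as_index=False)
        .agg(potency_nM=("potency_nM", gmean))
    )
    return out


def build_affinity_matrix(
    records: pd.DataFrame,
    wild_type: str,
    reference_potency: float,
    no_binding_floor: float = 1e-3,
) -> AffinityMatrix:
    """Build the per-position-normalized affinity matrix from substitution records.

    Parameters
    ----------
    records
        Table with columns ``position`` (1-based), ``wt``, ``sub`` and
        ``potency_nM``; a missing potency encodes a no-binding measurement.
        At most one record per (position, sub) is allowed — aggregate
        replicates first with :func:`aggregate_replicates`.
    wild_type
        The reference 13-mer sequence.
    reference_potency
        Wild-type potency in nM; wild-type cells without an explicit record
        are implied at this potency.
    no_binding_floor
        Fraction of the per-position maximum raw affinity assigned to
        no-binding (and unmeasured) cells before normalization.

    The raw affinity of cell (p, r) is ``reference_potency / potency(p, r)``
    and weights are these raw affinities divided by the per-position maximum,
    so the strongest binder at every position has weight exactly 1.
    """
    wild_type = _check_window(wild_type)
    if reference_potency <= 0:
        raise ValueError("reference_potency must be positive")
    if not 0 < no_binding_floor < 1:
        raise ValueError("no_binding_floor must be in (0, 1)")

    dup = records.duplicated(subset=["position", "sub"])
    if dup.any():
        pairs = records.loc[dup, ["position", "sub"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (position, residue) records: {pairs}")

    raw = pd.DataFrame(
        np.nan, index=range(1, MOTIF_LENGTH + 1), columns=list(AMINO_ACIDS), dtype=float
    )
    # wild-type cells implied at the reference potency
    for pos, res in enumerate(wild_type, start=1):
        raw.at[pos, res] = 1.0

    for row in records.itertuples(index=False):
        pos = int(row.position)
        sub = str(row.sub).upper()
        if not 1 <= pos <= MOTIF_LENGTH:
            raise ValueError(f"position {pos} outside 1..{MOTIF_LENGTH}")
        if sub not in AMINO_ACIDS:
            raise ValueError(f"non-standard residue {sub!r}")
        potency = row.potency_nM
        if pd.isna(potency):
            continue  # no binding: filled with the floor below
        if potency <= 0:
            raise ValueError(f"non-positive potency at position {pos} residue {sub}")
        raw.at[pos, sub] = reference_potency / float(potency)

    arr = raw.to_numpy()
    pos_max = np.nanmax(arr, axis=1)
    floor_vals = no_binding_floor * pos_max
    arr = np.where(np.isnan(arr), floor_vals[:, None], arr)
    weights = arr / arr.max(axis=1, keepdims=True)
    wdf = pd.DataFrame(weights, index=raw.index, columns=raw.columns)
    return AffinityMatrix(
        wild_type=wild_type,
        weights=wdf,
        reference_potency=float(reference_potency),
        no_binding_floor=float(no_binding_floor),
    )


def identify_key_positions(
    records: pd.DataFrame,
    fold_threshold: float = 10.0,
    reference_potency: float | None = None,
) -> set[int]:
    """Positions whose alanine substitution loses >= ``fold_threshold`` in potency.

    Only alanine-substitution records are considered.  The wild-type potency
    is taken from a record with ``sub == wt`` if present, otherwise from
    ``reference_potency``.  A no-binding alanine record (missing potency)
    counts as an infinite fold loss.  The comparison is inclusive (>=).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")

    wt_rows = records[records["sub"] == records["wt"]]
    if not wt_rows.empty:
        ref = float(np.exp(np.log(wt_rows["potency_nM"].astype(float)).mean()))
    elif reference_potency is not None:
        ref = float(reference_potency)
    else:
        raise ValueError("no wild-type record present; pass reference_potency")

    ala = records[(records["sub"] == "A") & (records["wt"] != "A")]
    keys: set[int] = set()
    for row in ala.itertuples(index=False):
        fold = math.inf if pd.isna(row.potency_nM) else float(row.potency_nM) / ref
        if fold >= fold_threshold:
            keys.add(int(row.position))
    return keys


def derive_consensus(
    matrix: AffinityMatrix,
    tolerance: float = 0.25,
    wildcard_min: int = 8,
) -> DegronPattern:
    """Collapse the affinity matrix into a bracket-class consensus pattern.

    A position's class is the set of residues with weight >= ``tolerance``;
    classes with at least ``wildcard_min`` members are treated as fully
    tolerant and collapse to the wildcard ``X``.  Since the per-position
    maximum weight is exactly 1, every class is non-empty for any tolerance
    in (0, 1).
    """
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    if wildcard_min < 2:
        raise ValueError("wildcard_min must be at least 2")
    classes = []
    for pos in range(1, MOTIF_LENGTH + 1):
        row = matrix.weights.loc[pos]
        members = frozenset(row.index[row >= tolerance])
        if len(members) >= wildcard_min:
            members = DegronPattern.FULL
        classes.append(members)
    return DegronPattern(classes)


def score_window(matrix: AffinityMatrix, window: str) -> float:
    """Additive log2-weight score of a 13-mer window.

    ``score = sum_p log2 w(p, window_p)``.  A window made entirely of
    weight-1 residues scores 0; every deviation contributes a negative term.
    Non-standard residues score as the no-binding floor.
    """
    window = _check_window(window)
    return float(
        sum(math.log2(matrix.weight(pos, res)) for pos, res in enumerate(window, start=1))
    )
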