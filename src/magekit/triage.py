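"""Screen hit calling, scaffold grouping for SAR, and compound property math."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

NO_RING_KEY = "no-ring"


def call_hits(results: pd.DataFrame, threshold: float = 30.0) -> tuple[pd.DataFrame, float]:
    """Call primary-screen hits at strictly greater-than ``threshold`` %inhibition.

    Returns the hit subset (with an ``is_hit`` column added to a copy of the
    input) and the hit rate as a percentage rounded to 2 decimals.
    """
    if results.empty:
        raise ValueError("empty screen result table")
    if results["pct_inhibition"].isna().any():
        raise ValueError("pct_inhibition missing for some compound wells")
    flagged = results.assign(is_hit=results["pct_inhibition"] > threshold)
    hits = flagged[flagged["is_hit"]].reset_index(drop=True)
    hit_rate = round(100.0 * len(hits) / len(flagged), 2)
    return hits, hit_rate


@dataclass
class ScaffoldGroups:
    """Compounds keyed by canonical Bemis-Murcko ring framework."""

    assignments: pd.DataFrame  # columns: compound_id, smiles, scaffold_key
    failures: list = field(default_factory=list)  # (compound_id, smiles) unparseable

    @property
    def groups(self) -> dict[str, list[str]]:
        return {
            key: grp["compound_id"].tolist()
            for key, grp in self.assignments.groupby("scaffold_key", sort=False)
        }


def murcko_key(smiles: str) -> str | None:
    """Canonical Bemis-Murcko framework SMILES; ``no-ring`` for acyclic molecules.

    Exocyclic substituents are removed while ring-ring linkers are kept, so
    analogs differing only in side chains share a key.  Returns None for
    unparseable SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    key = Chem.MolToSmiles(scaffold)
    return key if key else NO_RING_KEY


def group_scaffolds(compounds: pd.DataFrame) -> ScaffoldGroups:
    """Group a (compound_id, smiles) table by Bemis-Murcko framework.

    Unparseable SMILES are collected in ``failures``, never silently dropped.
    Grouping is permutation-invariant and idempotent.
    """
    rows = []
    failures = []
    for row in compounds.itertuples(index=False):
        key = murcko_key(row.smiles)
        if key is None:
            failures.append((row.compound_id, row.smiles))
        else:
            rows.append({"compound_id": row.compound_id, "smiles": row.smiles, "scaffold_key": key})
    return ScaffoldGroups(
        assignments=pd.DataFrame(rows, columns=["compound_id", "smiles", "scaffold_key"]),
        failures=failures,
    )


def compute_papp(dq_dt: float, area: float, c0: float) -> float:
    """Apparent permeability ``Papp = (dQ/dt) / (A * C0)`` in cm/s.

    ``dq_dt`` is the flux of compound across the monolayer (amount/s), ``area``
    the insert surface area (cm^2) and ``c0`` the initial donor concentration
    (amount/cm^3).
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if c0 <= 0:
        raise ValueError("initial donor concentration must be positive")
    return dq_dt / (area * c0)


def efflux_ratio(papp_ab: float, papp_ba: float) -> tuple[float, bool]:
    """B->A over A->B permeability ratio; the flag marks active transport (ratio > 2)."""
    if papp_ab <= 0:
        raise ValueError("papp_ab must be positive")
    ratio = papp_ba / papp_ab
    return ratio, ratio > 2.0


def estimate_solubility(
    sample_auc: float,
    reference_auc: float,
    reference_conc: float,
    dilution_correction: float = 2.0,
) -> float:
    """Kinetic solubility from UV areas of sample vs reference plates (uM).

    ``solubility = reference_conc * dilution_correction * sample_auc / reference_auc``.
    The default dilution correction of 2 reflects mixing the filtrate 1:1 with
    1-propanol before the UV read; vendor-software internals differ, so the
    factor is exposed.
    """
    if reference_auc <= 0:
        raise ValueError("reference_auc must be positive")
    return reference_conc * dilution_correction * sample_auc / reference_auc
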