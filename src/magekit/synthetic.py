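"""Seeded synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here under a known truth:
the 13 x 19 + wild-type (248 peptide) substitution array from a
position-energy model, 384-well primary-screen plates with reserved control
columns, four-parameter logistic dose-response series, Boltzmann melt curves
(single- and dual-channel), proteomes with planted degron motifs, and APA
event tables with a stated shifted fraction.  Generators are pure functions
of (parameters, seed): identical inputs reproduce identical output.

Noise conventions: potencies and responses receive multiplicative log-normal
noise (assays span orders of magnitude); raw plate-reader channel counts
receive additive Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
import string
import textwrap
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .degron import AMINO_ACIDS, MOTIF_LENGTH, PCF11_DEGRON
from .trfret import design_dilution_series, four_param_logistic


@dataclass
class GroundTruth:
    """The recorded truth accompanying a generated dataset."""

    kind: str  # array | screen | dose_response | melt | proteome | apa | structure
    parameters: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        return cls(kind=data["kind"], parameters=data["parameters"], seed=data["seed"])


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit median and the stated CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size))


# ---------------------------------------------------------------------------
# peptide substitution array
# ---------------------------------------------------------------------------

def pcf11_energy_model(
    wild_type: str = PCF11_DEGRON,
    out_of_class_affinity: float = 0.01,
    in_class_affinity: float = 0.8,
    tolerated_affinity: float = 0.6,
) -> pd.DataFrame:
    """Ground-truth per-position log-affinity table for the PCF11-like degron.

    Encodes the selectivity structure of the PCF11 degron: position 1 prefers
    aromatics [FLWY], position 8 requires [IV], position 9 tolerates only
    basics [KR], position 11 prefers large hydrophobics [ILMV], position 12
    prefers aromatics [FLWY]; the remaining positions tolerate any residue.
    Entries are natural-log relative affinities (wild-type residue = 0 at its
    position); out-of-class substitutions at key positions lose
    ``1/out_of_class_affinity``-fold (default 100x, inside the 10-200x range
    seen in alanine scans of such degrons).
    """
    key_classes = {
        1: set("FLWY"), 8: set("IV"), 9: set("KR"),
        11: set("ILMV"), 12: set("FLWY"),
    }
    table = pd.DataFrame(
        0.0, index=range(1, MOTIF_LENGTH + 1), columns=list(AMINO_ACIDS)
    )
    for pos in range(1, MOTIF_LENGTH + 1):
        wt = wild_type[pos - 1]
        for res in AMINO_ACIDS:
            if res == wt:
                value = 0.0
            elif pos in key_classes:
                value = math.log(
                    in_class_affinity if res in key_classes[pos] else out_of_class_affinity
                )
            else:
                value = math.log(tolerated_affinity)
            table.at[pos, res] = value
    return table


def gen_peptide_array(
    wild_type: str = PCF11_DEGRON,
    energy_model: pd.DataFrame | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    reference_potency: float = 59.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Saturation substitution array: 13 x 19 single substitutions + wild type.

    Each record's potency derives from the energy model —
    ``potency(p, r) = reference_potency * exp(E(p, wt_p) - E(p, r))`` — with
    multiplicative log-normal noise of the stated CV.  Exactly 248 rows.
    The default reference potency (59 nM) is the wild-type degron peptide's
    measured binding potency.
    """
    wild_type = str(wild_type).upper()
    if len(wild_type) != MOTIF_LENGTH:
        raise ValueError(f"wild type must be a {MOTIF_LENGTH}-mer")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if energy_model is None:
        energy_model = pcf11_energy_model(wild_type)
    if set(energy_model.columns) != set(AMINO_ACIDS):
        raise ValueError("energy model must cover all 20 residues")

    rng = np.random.default_rng(seed)
    rows = [{"position": 0, "wt": "-", "sub": "-", "potency_nM": reference_potency}]
    # the wild-type row carries position 0 and '-' residues as a whole-peptide record
    for pos in range(1, MOTIF_LENGTH + 1):
        wt = wild_type[pos - 1]
        for res in AMINO_ACIDS:
            if res == wt:
                continue
            e_wt = float(energy_model.at[pos, wt])
            e_sub = float(energy_model.at[pos, res])
            potency = reference_potency * math.exp(e_wt - e_sub)
            rows.append({"position": pos, "wt": wt, "sub": res, "potency_nM": potency})
    df = pd.DataFrame(rows)
    df["potency_nM"] = df["potency_nM"].to_numpy() * _lognormal_factor(rng, noise_cv, len(df))
    truth = GroundTruth(
        kind="array",
        parameters={
            "wild_type": wild_type,
            "reference_potency_nM": reference_potency,
            "noise_cv": noise_cv,
            "energy_model": {
                str(p): {r: float(energy_model.at[p, r]) for r in AMINO_ACIDS}
                for p in energy_model.index
            },
        },
        seed=seed,
    )
    return df, truth


def substitution_records(array: pd.DataFrame) -> pd.DataFrame:
    """Drop the whole-peptide wild-type row, leaving the 13x19 substitution records."""
    return array[array["position"] > 0].reset_index(drop=True)


# ---------------------------------------------------------------------------
# primary screen plates
# ---------------------------------------------------------------------------

PLATE_ROWS = string.ascii_uppercase[:16]          # A..P, 384-well format
CONTROL_COLUMNS = (1, 2, 13, 14)                  # reserved for controls
NEG_COLUMNS = (1, 13)                             # DMSO, 0% inhibition
POS_COLUMNS = (2, 14)                             # DMSO without donor protein
COMPOUND_COLUMNS = tuple(c for c in range(1, 25) if c not in CONTROL_COLUMNS)


@dataclass
class PlateLayout:
    """384-well screen layout with reserved control columns."""

    neg_columns: tuple = NEG_COLUMNS
    pos_columns: tuple = POS_COLUMNS
    compound_columns: tuple = COMPOUND_COLUMNS

    def __post_init__(self) -> None:
        ctrl = set(self.neg_columns) | set(self.pos_columns)
        if ctrl & set(self.compound_columns):
            raise ValueError("layout places compounds in control columns")

    @property
    def compounds_per_plate(self) -> int:
        return len(PLATE_ROWS) * len(self.compound_columns)


def gen_primary_screen(
    n_compounds: int,
    n_actives: int,
    active_inhibition_range: tuple[float, float] = (35.0, 95.0),
    plate_format: PlateLayout | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    neg_signal: float = 20000.0,
    pos_signal: float = 2000.0,
    ch490_counts: float = 10000.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-channel 384-well primary-screen reads with planted actives.

    Actives are drawn with true %inhibition uniform inside
    ``active_inhibition_range``; inactives sit at 0%.  Channel counts carry
    additive Gaussian noise of ``noise_sd``; at zero noise the number of
    compound wells whose %inhibition exceeds 30 equals ``n_actives`` whenever
    the range lies strictly above 30.
    """
    if n_actives > n_compounds:
        raise ValueError("n_actives cannot exceed n_compounds")
    layout = plate_format or PlateLayout()
    rng = np.random.default_rng(seed)

    ids = np.array([f"C{i + 1:06d}" for i in range(n_compounds)])
    active_idx = rng.choice(n_compounds, size=n_actives, replace=False)
    lo, hi = active_inhibition_range
    true_inh = np.zeros(n_compounds)
    true_inh[active_idx] = rng.uniform(lo, hi, size=n_actives)

    n_plates = math.ceil(n_compounds / layout.compounds_per_plate) if n_compounds else 1
    # hierarchical per-plate streams so partial regeneration is stable
    plate_rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_plates)]
    rows: list[dict] = []
    k = 0
    for plate_no in range(1, n_plates + 1):
        plate_id = f"PLATE{plate_no:03d}"
        plate_seed_rng = plate_rngs[plate_no - 1]
        for col in range(1, 25):
            for row_letter in PLATE_ROWS:
                well = f"{row_letter}{col:02d}"
                if col in layout.neg_columns:
                    role, inh, cid, conc = "neg_ctrl", 0.0, "", np.nan
                elif col in layout.pos_columns:
                    role, inh, cid, conc = "pos_ctrl", 100.0, "", np.nan
                elif col in layout.compound_columns:
                    if k >= n_compounds:
                        continue
                    role, inh, cid, conc = "compound", true_inh[k], ids[k], 15000.0
                    k += 1
                else:
                    continue
                signal = neg_signal - inh / 100.0 * (neg_signal - pos_signal)
                ch490 = ch490_counts + plate_seed_rng.normal(0.0, noise_sd)
                ch520 = signal * ch490_counts / 10000.0 + plate_seed_rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "plate_id": plate_id, "well": well, "role": role,
                        "channel_520": ch520, "channel_490": ch490,
                        "compound_id": cid, "conc_nM": conc,
                    }
                )
    df = pd.DataFrame(rows)
    truth = GroundTruth(
        kind="screen",
        parameters={
            "n_compounds": n_compounds,
            "n_actives": n_actives,
            "active_inhibition_range": list(active_inhibition_range),
            "noise_sd": noise_sd,
            "neg_signal": neg_signal,
            "pos_signal": pos_signal,
            "active_ids": sorted(ids[active_idx].tolist()),
            "true_inhibition": {
                ids[i]: float(true_inh[i]) for i in sorted(active_idx.tolist())
            },
        },
        seed=seed,
    )
    return df, truth


# ---------------------------------------------------------------------------
# dose response
# ---------------------------------------------------------------------------

def gen_dose_response(
    true_ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    design: np.ndarray | None = None,
    replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Concentration-response table sampled from a four-parameter logistic.

    The default design is the screen's follow-up series: 10 levels, 1:3
    dilution from 70 uM.  Responses carry multiplicative log-normal noise of
    the stated CV.
    """
    if true_ic50 <= 0:
        raise ValueError("true_ic50 must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if design is None:
        design = design_dilution_series(70000.0, 3.0, 10)
    design = np.asarray(design, dtype=float)
    if np.any(design <= 0):
        raise ValueError("concentrations must be positive")
    diffs = np.diff(design)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("concentrations must be strictly monotone")

    rng = np.random.default_rng(seed)
    conc = np.repeat(design, replicates)
    ideal = four_param_logistic(conc, bottom, top, true_ic50, hill)
    response = ideal * _lognormal_factor(rng, noise_cv, conc.size)
    df = pd.DataFrame(
        {
            "conc_nM": conc,
            "replicate": np.tile(np.arange(1, replicates + 1), design.size),
            "response": response,
        }
    )
    truth = GroundTruth(
        kind="dose_response",
        parameters={
            "true_ic50_nM": true_ic50, "hill": hill, "top": top, "bottom": bottom,
            "noise_cv": noise_cv, "replicates": replicates,
            "design_nM": design.tolist(),
        },
        seed=seed,
    )
    return df, truth


# ---------------------------------------------------------------------------
# melt curves
# ---------------------------------------------------------------------------

def gen_melt_curve(
    tm: float,
    slope: float = 1.5,
    baselines: dict | None = None,
    temp_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dual_channel: bool = False,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Thermal-denaturation curve with a sigmoidal transition at ``tm``.

    Single-channel mode emulates dye-based DSF; ``dual_channel=True`` emulates
    nanoDSF with a falling 330 nm and rising 350 nm intrinsic-fluorescence
    channel, so the 350/330 ratio rises monotonically through the transition.
    ``baselines`` may carry ``pre``/``post`` levels and optional linear
    ``pre_drift``/``post_drift`` (signal per degC).  The default grid mirrors
    a 25-95 degC ramp read every 0.5 degC.
    """
    if temp_grid is None:
        temp_grid = np.arange(25.0, 95.0 + 1e-9, 0.5)
    temp_grid = np.asarray(temp_grid, dtype=float)
    if not temp_grid[0] < tm < temp_grid[-1]:
        raise ValueError("tm must lie inside the temperature grid span")
    b = {"pre": 1000.0, "post": 3000.0, "pre_drift": 0.0, "post_drift": 0.0}
    if baselines:
        b.update(baselines)

    rng = np.random.default_rng(seed)
    frac = 1.0 / (1.0 + np.exp((tm - temp_grid) / slope))  # unfolded fraction
    t0 = temp_grid[0]

    def channel(pre, post, pre_drift=0.0, post_drift=0.0):
        pre_line = pre + pre_drift * (temp_grid - t0)
        post_line = post + post_drift * (temp_grid - t0)
        return pre_line + (post_line - pre_line) * frac

    if dual_channel:
        # the instrument analyzes the 350/330 ratio; emulate channels whose
        # ratio is exactly a Boltzmann sigmoid with midpoint at tm
        f330 = channel(3000.0, 1500.0)
        ratio = 0.5 + 1.5 * frac
        f350 = ratio * f330
        f330 = f330 + rng.normal(0.0, noise_sd, temp_grid.size)
        f350 = f350 + rng.normal(0.0, noise_sd, temp_grid.size)
        df = pd.DataFrame({"temperature": temp_grid, "f330": f330, "f350": f350})
    else:
        y = channel(b["pre"], b["post"], b["pre_drift"], b["post_drift"])
        y = y + rng.normal(0.0, noise_sd, temp_grid.size)
        df = pd.DataFrame({"temperature": temp_grid, "signal": y})
    truth = GroundTruth(
        kind="melt",
        parameters={
            "tm_C": tm, "slope_C": slope, "baselines": b,
            "noise_sd": noise_sd, "dual_channel": dual_channel,
        },
        seed=seed,
    )
    return df, truth


# ---------------------------------------------------------------------------
# proteome with planted motifs
# ---------------------------------------------------------------------------

def gen_proteome(
    n_proteins: int,
    length_law: tuple = ("uniform", 200, 500),
    planted: list[tuple[str, int, int]] | None = None,
    background_freqs: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[str, GroundTruth]:
    """FASTA text of random proteins with degron motifs planted at known offsets.

    ``planted`` lists (13-mer, 0-based protein index, 1-based offset) triples;
    the full motif must fit inside the protein.  Background residues are drawn
    from ``background_freqs`` (uniform over the 20 standard residues by
    default).  ``length_law`` is ("constant", L) or ("uniform", lo, hi).
    """
    planted = planted or []
    rng = np.random.default_rng(seed)

    if background_freqs is None:
        probs = np.full(20, 1.0 / 20.0)
    else:
        probs = np.array([background_freqs.get(r, 0.0) for r in AMINO_ACIDS], dtype=float)
        total = probs.sum()
        if total <= 0:
            raise ValueError("background frequencies sum to zero")
        probs = probs / total

    kind = length_law[0]
    if kind == "constant":
        lengths = np.full(n_proteins, int(length_law[1]))
    elif kind == "uniform":
        lengths = rng.integers(int(length_law[1]), int(length_law[2]) + 1, size=n_proteins)
    else:
        raise ValueError(f"unknown length law {kind!r}")

    letters = np.array(list(AMINO_ACIDS))
    seqs = ["".join(rng.choice(letters, size=n, p=probs)) for n in lengths]

    for motif, idx, offset in planted:
        motif = str(motif).upper()
        if len(motif) != MOTIF_LENGTH:
            raise ValueError("planted motifs must be 13-mers")
        if not 0 <= idx < n_proteins:
            raise ValueError(f"protein index {idx} out of range")
        if offset < 1 or offset + MOTIF_LENGTH - 1 > len(seqs[idx]):
            raise ValueError(f"offset {offset} overflows protein {idx}")
        s = seqs[idx]
        seqs[idx] = s[: offset - 1] + motif + s[offset - 1 + MOTIF_LENGTH :]

    records = []
    for i, s in enumerate(seqs):
        records.append(f">P{i + 1:04d}")
        records.append(textwrap.fill(s, width=60) if s else "")
    fasta = "\n".join(records) + ("\n" if records else "")
    truth = GroundTruth(
        kind="proteome",
        parameters={
            "n_proteins": n_proteins,
            "length_law": list(length_law),
            "planted": [[m, i, o] for m, i, o in planted],
            "planted_ids": [[f"P{i + 1:04d}", o] for _, i, o in planted],
        },
        seed=seed,
    )
    return fasta, truth


# ---------------------------------------------------------------------------
# APA event tables
# ---------------------------------------------------------------------------

def gen_apa_table(
    n_genes: int,
    shifted_fraction: float,
    delta_pdui: float = 0.3,
    coverage_law: tuple = ("lognormal", 4.0, 0.5),
    reps_per_group: int = 3,
    replicate_sd: float = 0.05,
    direction: str = "lengthened",
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene-level APA event table with a stated fraction of shifted genes.

    Shifted genes receive a mean dPDUI of ``delta_pdui`` magnitude in the
    stated direction (positive = distal-site usage increases in group 2, i.e.
    3'-UTR lengthening); replicate PDUIs scatter with SD ``replicate_sd`` and
    are clamped to [0, 1] (with a warning when the effect pushes a mean
    outside the unit interval).  Per-gene p-values come from a two-sample
    t-test on the replicate PDUIs.  ``reps_per_group`` defaults to 3,
    mirroring a three-tumors-per-group design.
    """
    if not 0 <= shifted_fraction <= 1:
        raise ValueError("shifted_fraction must be in [0, 1]")
    if direction not in ("lengthened", "shortened"):
        raise ValueError("direction must be 'lengthened' or 'shortened'")
    if reps_per_group < 2:
        raise ValueError("need at least 2 replicates per group for a t-test")
    rng = np.random.default_rng(seed)

    n_shifted = int(round(shifted_fraction * n_genes))
    shifted_idx = rng.choice(n_genes, size=n_shifted, replace=False)
    shifted_mask = np.zeros(n_genes, dtype=bool)
    shifted_mask[shifted_idx] = True

    # sample baselines leaving headroom for the shift so clamping is exceptional
    signed_delta = delta_pdui if direction == "lengthened" else -delta_pdui
    lo = 0.05 + max(0.0, -signed_delta)
    hi = 0.95 - max(0.0, signed_delta)
    if lo >= hi:  # effect too large for the unit interval; clamp below will warn
        lo, hi = 0.15, 0.85
    base = rng.uniform(lo, hi, size=n_genes)
    mean2 = base + np.where(shifted_mask, signed_delta, 0.0)
    if np.any((mean2 < 0) | (mean2 > 1)):
        warnings.warn("delta_pdui pushes some mean PDUIs outside [0, 1]; clamping")
        mean2 = np.clip(mean2, 0.0, 1.0)

    g1 = np.clip(
        base[:, None] + rng.normal(0.0, replicate_sd, (n_genes, reps_per_group)), 0.0, 1.0
    )
    g2 = np.clip(
        mean2[:, None] + rng.normal(0.0, replicate_sd, (n_genes, reps_per_group)), 0.0, 1.0
    )
    pvals = ttest_ind(g1, g2, axis=1).pvalue

    if coverage_law[0] == "constant":
        coverage = np.full(n_genes, float(coverage_law[1]))
    elif coverage_law[0] == "lognormal":
        coverage = np.exp(rng.normal(coverage_law[1], coverage_law[2], n_genes))
    else:
        raise ValueError(f"unknown coverage law {coverage_law[0]!r}")

    data = {"gene_id": [f"G{i + 1:05d}" for i in range(n_genes)]}
    for r in range(reps_per_group):
        data[f"pdui_g1_{r + 1}"] = g1[:, r]
    for r in range(reps_per_group):
        data[f"pdui_g2_{r + 1}"] = g2[:, r]
    data["coverage"] = coverage
    data["p_value"] = pvals
    df = pd.DataFrame(data)
    truth = GroundTruth(
        kind="apa",
        parameters={
            "n_genes": n_genes,
            "shifted_fraction": shifted_fraction,
            "delta_pdui": delta_pdui,
            "direction": direction,
            "reps_per_group": reps_per_group,
            "replicate_sd": replicate_sd,
            "shifted_genes": sorted(f"G{i + 1:05d}" for i in shifted_idx.tolist()),
        },
        seed=seed,
    )
    return df, truth
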