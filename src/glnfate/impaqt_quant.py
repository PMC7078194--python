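"""Spike-in MRM absolute quantification and enzyme panel summaries.

Targeted proteomics with heavy (isotope-coded) synthetic peptide spike-ins:
the endogenous amount of a peptide is the ratio of summed light to summed
heavy transition intensities times the known spiked amount.  Protein
abundance is the mean +/- s.d. over peptides and replicate cultures; copy
numbers per cell follow from the protein amount per cell.  Panel summaries
(per-protein z-scores across samples; the PPAT/GLS1 abundance ratio) express
the balance between the two glutamine-consuming enzymes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "TransitionRecord",
    "PeptideQuant",
    "ProteinQuant",
    "quantify_peptide",
    "aggregate_protein",
    "copies_per_cell",
    "EnzymePanel",
    "panel_summary",
    "quantify_table",
]

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class TransitionRecord:
    protein: str
    peptide: str
    transition: str
    light_intensity: float
    heavy_intensity: float

    def __post_init__(self):
        for name in ("light_intensity", "heavy_intensity"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass(frozen=True)
class PeptideQuant:
    peptide: str
    spike_fmol: float
    endogenous_fmol: Optional[float]
    flagged: bool = False  # heavy sum zero -> undefined ratio


@dataclass(frozen=True)
class ProteinQuant:
    protein: str
    mean_fmol: float
    sd_fmol: float
    n: int
    copies_per_cell: Optional[float] = None
    low_evidence: bool = False


def quantify_peptide(records: Sequence[TransitionRecord], spike_fmol: float) -> PeptideQuant:
    """Endogenous amount = (sum light / sum heavy) x spiked amount.

    Intensities are summed over transitions *before* taking the ratio, so the
    estimate is invariant to a common intensity rescaling.  A zero heavy sum
    leaves the ratio undefined and is flagged rather than producing infinity.
    """
    if not records:
        raise ValueError("need at least one transition")
    if spike_fmol <= 0:
        raise ValueError("spiked amount must be positive")
    peptide = records[0].peptide
    light = sum(r.light_intensity for r in records)
    heavy = sum(r.heavy_intensity for r in records)
    if heavy == 0:
        return PeptideQuant(peptide=peptide, spike_fmol=spike_fmol, endogenous_fmol=None, flagged=True)
    return PeptideQuant(
        peptide=peptide,
        spike_fmol=spike_fmol,
        endogenous_fmol=(light / heavy) * spike_fmol,
    )


def aggregate_protein(
    protein: str,
    quants: Sequence[PeptideQuant],
    protein_per_cell_ug: Optional[float] = None,
) -> ProteinQuant:
    """Mean and sample s.d. over peptide x replicate estimates for one protein.

    Flagged peptides (undefined ratio) are excluded; a single usable estimate
    yields s.d. 0 by convention and is marked low-evidence.
    """
    values = [q.endogenous_fmol for q in quants if not q.flagged and q.endogenous_fmol is not None]
    if not values:
        raise ValueError(f"no usable peptide estimates for {protein}")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    cpc = None
    if protein_per_cell_ug is not None:
        cpc = copies_per_cell(mean, protein_per_cell_ug) if mean > 0 else 0.0
    return ProteinQuant(
        protein=protein,
        mean_fmol=mean,
        sd_fmol=sd,
        n=arr.size,
        copies_per_cell=cpc,
        low_evidence=arr.size == 1,
    )


def copies_per_cell(abundance_fmol_per_ug: float, protein_per_cell_ug: float) -> float:
    """copies/cell = abundance [fmol/ug] x 1e-15 mol/fmol x protein/cell [ug] x N_A."""
    if abundance_fmol_per_ug < 0:
        raise ValueError("abundance must be non-negative")
    if protein_per_cell_ug <= 0:
        raise ValueError("protein amount per cell must be positive")
    return abundance_fmol_per_ug * 1e-15 * protein_per_cell_ug * AVOGADRO


@dataclass
class EnzymePanel:
    """Protein x sample abundance matrix (rows: proteins, columns: samples)."""

    abundance: pd.DataFrame

    def __post_init__(self):
        if self.abundance.shape[1] < 1:
            raise ValueError("panel needs at least one sample")


@dataclass
class PanelSummary:
    zscores: pd.DataFrame
    ppat_gls1_ratio: pd.Series
    constant_rows: List[str]


def panel_summary(
    panel: EnzymePanel,
    ddof: int = 1,
    ppat: str = "PPAT",
    gls1: str = "GLS1",
) -> PanelSummary:
    """Row z-scores across samples plus the per-sample PPAT/GLS1 ratio.

    Sample standard deviation (ddof=1) by default; constant rows have no
    defined z-score and are emitted as zeros with a flag.  A zero GLS1
    abundance yields an infinite ratio (flagged by the inf itself).
    """
    ab = panel.abundance
    mean = ab.mean(axis=1)
    sd = ab.std(axis=1, ddof=ddof) if ab.shape[1] > ddof else ab.std(axis=1, ddof=0)
    constant = sd[sd == 0].index.tolist()
    safe_sd = sd.replace(0, np.nan)
    z = ab.sub(mean, axis=0).div(safe_sd, axis=0).fillna(0.0)
    ratio = None
    if ppat in ab.index and gls1 in ab.index:
        with np.errstate(divide="ignore"):
            ratio = ab.loc[ppat] / ab.loc[gls1]
        if np.isinf(ratio).any():
            warnings.warn("zero GLS1 abundance: PPAT/GLS1 ratio infinite for some samples")
    else:
        raise ValueError(f"panel must contain rows {ppat!r} and {gls1!r} for the ratio")
    return PanelSummary(zscores=z, ppat_gls1_ratio=ratio, constant_rows=constant)


def quantify_table(
    transitions: pd.DataFrame,
    protein_per_cell_ug: Optional[float] = None,
) -> pd.DataFrame:
    """Run the full quantification on a transition table.

    Expected columns: protein, peptide, transition, light_intensity,
    heavy_intensity, spike_fmol, sample, replicate.  Returns one row per
    (sample, protein) with mean, sd, n and (optionally) copies per cell;
    peptides with zero heavy sums are excluded and counted.
    """
    required = {
        "protein", "peptide", "transition", "light_intensity",
        "heavy_intensity", "spike_fmol", "sample", "replicate",
    }
    if not required <= set(transitions.columns):
        raise ValueError(f"transition table must have columns {sorted(required)}")
    rows = []
    for (sample, protein), grp in transitions.groupby(["sample", "protein"], sort=True):
        quants: List[PeptideQuant] = []
        n_excluded = 0
        for (_, _), pep_grp in grp.groupby(["peptide", "replicate"], sort=True):
            recs = [
                TransitionRecord(
                    protein=str(protein),
                    peptide=str(r.peptide),
                    transition=str(r.transition),
                    light_intensity=float(r.light_intensity),
                    heavy_intensity=float(r.heavy_intensity),
                )
                for r in pep_grp.itertuples()
            ]
            spike = float(pep_grp["spike_fmol"].iloc[0])
            q = quantify_peptide(recs, spike)
            if q.flagged:
                n_excluded += 1
            else:
                quants.append(q)
        if not quants:
            continue
        pq = aggregate_protein(str(protein), quants, protein_per_cell_ug)
        rows.append(
            {
                "sample": sample,
                "protein": protein,
                "mean_fmol_per_ug": pq.mean_fmol,
                "sd_fmol_per_ug": pq.sd_fmol,
                "n_estimates": pq.n,
                "n_excluded_peptides": n_excluded,
                "copies_per_cell": pq.copies_per_cell,
                "low_evidence": pq.low_evidence,
            }
        )
    return pd.DataFrame(rows)
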