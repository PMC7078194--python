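"""Forward generators emulating every input the pipeline consumes.

Each generator returns ground truth alongside observations so downstream
modules have closed-loop recovery tests: centroided MS peak lists from the
kinetic labeling model plus natural-abundance convolution and instrument
resolution; MRM transition tables consistent with the spike-in quantification
model; multi-cohort survival tables with exponential hazards, a group hazard
ratio, censoring and between-cohort heterogeneity on the log-HR scale.

Scenario presets encode the study contrasts: a premalignant-like state
("TSM-like": high glutaminolysis, low de novo purine flux), a malignant-like
state ("AIG3-like": the reverse), and a physiological-medium variant
(0.6 mM rather than 2 mM glutamine, scaling turnover but not enrichment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .impaqt_quant import AVOGADRO
from .isotope_core import (
    DEFAULT_ISOTOPES,
    CentroidPeakList,
    CorrectionMatrix,
    MIDGrid,
    ResolutionModel,
    build_correction,
    enumerate_grid,
    forward_convolve,
    merge_groups,
    parse_formula,
    read_metabolite_registry,
)
from .survival_meta import Cohort
from .tracer_flux import (
    AtomTransitionMap,
    LabelingTimeCourse,
    PoolModel,
    load_default_atom_map,
    simulate_labeling,
)

__all__ = [
    "ScenarioPreset",
    "scenario_presets",
    "get_preset",
    "gen_ms_peaklists",
    "gen_transition_table",
    "gen_cohorts",
    "write_cohorts",
    "tumor_volume",
    "default_registry",
]

#: Copies per cell for the enzyme panel under each scenario (ground truth for
#: the MRM generator).  The malignant-like state has the purine pathway up
#: (PPAT, GART, GMPS, PRPS2) and glutaminolysis (GLS1) down.
_TSM_PANEL = {
    "PPAT": 6.0e4, "GLS1": 9.0e5, "GART": 1.2e5, "GMPS": 1.5e5, "PRPS2": 8.0e4,
    "UMPS": 2.0e5, "HK2": 3.0e5, "ENO1": 4.0e6, "LDHA": 5.0e6, "PDHA1": 6.0e5,
}
_AIG3_PANEL = {
    "PPAT": 5.0e5, "GLS1": 2.0e5, "GART": 7.0e5, "GMPS": 8.0e5, "PRPS2": 4.0e5,
    "UMPS": 5.0e5, "HK2": 9.0e5, "ENO1": 8.0e6, "LDHA": 1.2e7, "PDHA1": 1.5e6,
}

#: True hazard ratios for the survival generator, anchored to the pooled
#: neuroendocrine estimates (PPAT 5.21, GLS1 0.38) with the purine pathway
#: deleterious and glutaminolysis protective.
_SURVIVAL_TRUTH = {"PPAT": 5.21, "GLS1": 0.38, "GART": 2.5, "GMPS": 2.2, "UMPS": 1.3}


@dataclass(frozen=True)
class ScenarioPreset:
    """Named parameter bundle driving all three synthetic generators."""

    name: str
    pool_model: PoolModel
    mrm_copies_per_cell: Mapping[str, float]
    survival_true_hr: Mapping[str, float]
    baseline_hazard_per_month: float = math.log(2.0) / 36.0
    censor_rate: float = 0.3
    tau2: float = 0.0
    glutamine_mm: float = 2.0


def scenario_presets() -> Dict[str, ScenarioPreset]:
    """The named presets; by construction the malignant-like state has the
    higher v_PPAT/v_GLS ratio."""
    tsm = PoolModel(v_gls=12.0, v_ppat=1.0, v_ta=4.0, v_pyr=0.6, v_glc=4.0)
    aig3 = PoolModel(v_gls=4.0, v_ppat=5.0, v_ta=4.0, v_pyr=1.8, v_glc=8.0)
    # 0.6 mM glutamine: ~3x lower medium pool slows glutamine-consuming
    # turnover (uptake-limited); enrichment of the tracer pool is unchanged.
    phys = replace(aig3, v_gls=aig3.v_gls * 0.6, v_ppat=aig3.v_ppat * 0.6,
                   v_pyr=aig3.v_pyr * 0.6)
    return {
        "TSM-like": ScenarioPreset(
            name="TSM-like", pool_model=tsm,
            mrm_copies_per_cell=_TSM_PANEL, survival_true_hr=_SURVIVAL_TRUTH,
        ),
        "AIG3-like": ScenarioPreset(
            name="AIG3-like", pool_model=aig3,
            mrm_copies_per_cell=_AIG3_PANEL, survival_true_hr=_SURVIVAL_TRUTH,
        ),
        "physiological-medium": ScenarioPreset(
            name="physiological-medium", pool_model=phys,
            mrm_copies_per_cell=_AIG3_PANEL, survival_true_hr=_SURVIVAL_TRUTH,
            glutamine_mm=0.6,
        ),
    }


def get_preset(name: str) -> ScenarioPreset:
    presets = scenario_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}") from None


def default_registry():
    from importlib import resources

    with resources.as_file(resources.files("glnfate.data") / "metabolites.csv") as p:
        return read_metabolite_registry(str(p))


@dataclass
class PeaklistTruth:
    """Ground truth accompanying generated peak lists."""

    true_mids: Dict[float, Dict[str, MIDGrid]]       # before natural abundance
    observed_mids: Dict[float, Dict[str, MIDGrid]]   # after convolution, pre-noise
    merged: Dict[Tuple[float, str], List[List]]      # unresolved species groups


def gen_ms_peaklists(
    preset: ScenarioPreset,
    resolution: ResolutionModel = ResolutionModel(),
    noise_cv: float = 0.0,
    seed: int = 0,
    times: Sequence[float] = (0.25, 6.0, 24.0),
    metabolites: Optional[Sequence[str]] = None,
    amap: Optional[AtomTransitionMap] = None,
    tracer: str = "gln-13C5-15N2",
    total_intensity: float = 1e6,
    purity: Optional[Mapping[str, float]] = None,
) -> Tuple[List[CentroidPeakList], PeaklistTruth]:
    """Forward model of the dual-tracer measurements.

    simulate_labeling -> natural-abundance convolution -> theoretical m/z per
    isotopologue -> merge species closer than the instrument FWHM (flagged)
    -> multiplicative log-normal noise -> one centroid peak list per time
    point.  CV 0 with sufficient resolution makes assignment + correction an
    exact round trip.
    """
    if noise_cv < 0:
        raise ValueError("noise CV must be non-negative")
    rng = np.random.default_rng(seed)
    registry = default_registry()
    amap = amap or load_default_atom_map()
    mets = list(metabolites) if metabolites is not None else [
        m for m in registry if m in amap.carbon
    ]
    tc = simulate_labeling(preset.pool_model, amap, times, tracer, mets)
    sigma = math.sqrt(math.log1p(noise_cv**2))

    peaklists: List[CentroidPeakList] = []
    true_mids: Dict[float, Dict[str, MIDGrid]] = {}
    observed_mids: Dict[float, Dict[str, MIDGrid]] = {}
    merged_flags: Dict[Tuple[float, str], List[List]] = {}
    for t in tc.times:
        true_mids[t] = {}
        observed_mids[t] = {}
        for met in mets:
            entry = registry[met]
            true = tc.grid(t, met)
            nc, nn = true.f.shape[0] - 1, true.f.shape[1] - 1
            corr = build_correction(entry.formula, DEFAULT_ISOTOPES, purity=purity,
                                    max_c=nc, max_n=nn)
            observed = forward_convolve(true, corr).normalized()
            grid = enumerate_grid(entry.formula, nc, nn, entry.charge)
            groups = merge_groups(grid, resolution)
            merged_flags[(t, met)] = [g for g in groups if len(g) > 1]
            obs_flat = observed.f
            mz_met: List[float] = []
            int_met: List[float] = []
            for group in groups:
                inten = float(sum(obs_flat[iso.state.n13c, iso.state.n15n] for iso in group))
                if inten <= 1e-12:
                    continue
                weights = np.array(
                    [obs_flat[iso.state.n13c, iso.state.n15n] for iso in group]
                )
                mzs = np.array([iso.mz for iso in group])
                centroid = float((weights * mzs).sum() / weights.sum())
                noisy = inten * total_intensity
                if noise_cv > 0:
                    noisy *= float(rng.lognormal(-0.5 * sigma**2, sigma))
                mz_met.append(centroid)
                int_met.append(noisy)
            order = np.argsort(mz_met)
            # one peak list per chromatographic (metabolite) channel, as in
            # IC/LC-MS where analytes are separated before the mass analyzer
            peaklists.append(
                CentroidPeakList(
                    sample_id=preset.name,
                    time_h=t,
                    mz=np.asarray(mz_met)[order],
                    intensity=np.asarray(int_met)[order],
                    metabolite=met,
                )
            )
            true_mids[t][met] = true
            observed_mids[t][met] = observed
    return peaklists, PeaklistTruth(true_mids, observed_mids, merged_flags)


def gen_transition_table(
    preset: ScenarioPreset,
    n_proteins: Optional[int] = None,
    peptides_per_protein: int = 3,
    transitions_per_peptide: int = 3,
    replicates: int = 3,
    cv: float = 0.1,
    seed: int = 0,
    protein_per_cell_ug: float = 2.5e-4,
    spike_fmol: float = 10.0,
    sample: Optional[str] = None,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Transition intensity table consistent with the spike-in inverse model.

    Ground-truth copy numbers come from the preset panel (optionally padded
    with random proteins up to ``n_proteins``); light/heavy intensity ratios
    encode the endogenous amount with per-transition log-normal noise of the
    given CV.  Returns (table, true copies per cell).
    """
    if peptides_per_protein < 1 or transitions_per_peptide < 1 or replicates < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    truth = dict(preset.mrm_copies_per_cell)
    if n_proteins is not None:
        i = 0
        while len(truth) < n_proteins:
            truth[f"ENZ{i:04d}"] = float(rng.lognormal(math.log(2e5), 1.0))
            i += 1
    sigma = math.sqrt(math.log1p(cv**2)) if cv > 0 else 0.0
    rows = []
    for protein, copies in truth.items():
        # invert copies_per_cell: fmol/ug = copies / (1e-15 * ppc * N_A)
        fmol_per_ug = copies / (1e-15 * protein_per_cell_ug * AVOGADRO)
        for pep_i in range(peptides_per_protein):
            for rep in range(1, replicates + 1):
                for tr_i in range(transitions_per_peptide):
                    heavy = 1e5 * (1.0 + 0.5 * tr_i)
                    light = heavy * fmol_per_ug / spike_fmol
                    if sigma > 0:
                        light *= float(rng.lognormal(-0.5 * sigma**2, sigma))
                        heavy *= float(rng.lognormal(-0.5 * sigma**2, sigma))
                    rows.append(
                        {
                            "protein": protein,
                            "peptide": f"{protein}_pep{pep_i+1}",
                            "transition": f"t{tr_i+1}",
                            "light_intensity": light,
                            "heavy_intensity": heavy,
                            "spike_fmol": spike_fmol,
                            "sample": sample or preset.name,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows), truth


_DEFAULT_ORGANS = ("lung", "breast", "brain", "neuroendocrine", "colorectal")


def gen_cohorts(
    preset: ScenarioPreset,
    k_cohorts: int = 10,
    n_per_cohort: int = 500,
    true_hr: Optional[Mapping[str, float]] = None,
    censor_rate: Optional[float] = None,
    tau2: Optional[float] = None,
    seed: int = 0,
    organs: Sequence[str] = _DEFAULT_ORGANS,
    followup_cap_months: float = 180.0,
) -> List[Cohort]:
    """Multi-cohort survival tables with known ground truth.

    Per gene, expression is log-normal; subjects above the cohort median have
    their exponential hazard multiplied by a cohort-specific HR drawn as
    log HR ~ Normal(log true HR, tau^2) (heterogeneity on the log scale).
    Independent exponential censoring approximately achieves the target
    censoring fraction; follow-up is capped administratively.
    """
    if n_per_cohort < 10:
        raise ValueError("need n >= 10 per cohort")
    censor_rate = preset.censor_rate if censor_rate is None else censor_rate
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor rate must lie in [0, 1)")
    tau2 = preset.tau2 if tau2 is None else tau2
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    true_hr = dict(true_hr if true_hr is not None else preset.survival_true_hr)
    rng = np.random.default_rng(seed)
    lam0 = preset.baseline_hazard_per_month
    cohorts = []
    for ci in range(k_cohorts):
        organ = organs[ci % len(organs)]
        expr = {g: rng.lognormal(0.0, 1.0, n_per_cohort) for g in true_hr}
        log_rate = np.full(n_per_cohort, math.log(lam0))
        for g, hr in true_hr.items():
            cohort_log_hr = rng.normal(math.log(hr), math.sqrt(tau2))
            high = expr[g] > np.median(expr[g])
            log_rate = log_rate + np.where(high, cohort_log_hr, 0.0)
        rate = np.exp(log_rate)
        t_event = rng.exponential(1.0 / rate)
        if censor_rate > 0:
            mu = censor_rate / (1.0 - censor_rate) * rate.mean()
            t_cens = rng.exponential(1.0 / mu, n_per_cohort)
        else:
            t_cens = np.full(n_per_cohort, np.inf)
        t_cens = np.minimum(t_cens, followup_cap_months)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        time = np.maximum(time, 1e-6)
        df = pd.DataFrame({"subject_id": [f"c{ci}s{i}" for i in range(n_per_cohort)],
                           "time_months": time, "event": event})
        for g in true_hr:
            df[g] = expr[g]
        cohorts.append(Cohort(cohort_id=f"SIM{ci:03d}", organ=organ, data=df))
    return cohorts


def write_cohorts(cohorts: Sequence[Cohort], out_dir: str) -> str:
    """Write one CSV per cohort plus a manifest CSV; returns the manifest path."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for c in cohorts:
        fname = f"{c.cohort_id}.csv"
        c.data.to_csv(os.path.join(out_dir, fname), index=False, float_format="%.10g")
        rows.append({"cohort_id": c.cohort_id, "organ": c.organ, "filename": fname})
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Tumor volume (mm^3) = length x width^2 / 2, width being the smaller axis.

    Swapped arguments are auto-corrected with a warning.
    """
    import warnings

    if length_mm < 0 or width_mm < 0:
        raise ValueError("dimensions must be non-negative")
    if width_mm > length_mm:
        warnings.warn("width larger than length: axes swapped by convention")
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm**2 / 2.0
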