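"""Two-pathway kinetic labeling model for [13C5/15N2]glutamine tracing.

Glutamine feeds two competing fates: catabolism via glutaminase (GLS1,
glutaminolysis -> glutamate -> alpha-ketoglutarate -> TCA cycle), which is read
out by early-time 13C labeling of alpha-KG/fumarate, and anabolism via
amidophosphoribosyltransferase (PPAT, de novo purine synthesis), which is read
out by late-time 15N labeling of IMP/AMP/GMP/UMP.  The model tracks the tracer
enrichment of *position classes* (the intact C5/C4 carbon backbone as one
unit; each nitrogen position by its biosynthetic donor) through well-mixed
pools of constant size with first-order turnover:

    d x_p / dt = sum_i v_i (s_i(t) - x_p) / P

where the v_i are the influxes into the pool, s_i their source enrichments,
and P the pool size.  The system is linear and time-invariant, so it is
solved exactly by the matrix exponential of the augmented system.

Positions are treated as independent when assembling 2-D mass isotopomer
grids (adequate for first-order well-mixed pools); the nitrogen axis is the
Poisson-binomial of per-position enrichments and the carbon axis an
all-or-none backbone unit.  The nitrogen wiring (which donor feeds which
position of IMP/AMP/GMP/UMP) comes from an editable atom-transition map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

from .isotope_core import MIDGrid, percent_labeled

__all__ = [
    "PoolModel",
    "AtomTransitionMap",
    "load_default_atom_map",
    "LabelingTimeCourse",
    "simulate_labeling",
    "ShiftScores",
    "pathway_scores",
    "FluxFit",
    "fit_fluxes",
    "paired_ttest",
    "DEFAULT_TIMES",
    "TRACERS",
]

DEFAULT_TIMES = (0.0, 0.25, 6.0, 24.0)
TRACERS = ("gln-13C5-15N2", "glc-13C6")

#: (carbon count, nitrogen count) used to size the MID grids.
_FORMULA_DIMS: Dict[str, Tuple[int, int]] = {
    "glutamine": (5, 2),
    "glutamate": (5, 1),
    "aspartate": (4, 1),
    "alpha-ketoglutarate": (5, 0),
    "fumarate": (4, 0),
    "IMP": (10, 4),
    "AMP": (10, 5),
    "GMP": (10, 5),
    "UMP": (9, 2),
}

_PRODUCT_METABOLITES = ("IMP", "AMP", "GMP", "UMP")


def _default_pools() -> Dict[str, float]:
    # Relative pool sizes (amount units per dish); nucleotide pools are small
    # relative to amino acid pools, glutamate is the largest free pool.
    return {
        "glutamine": 2.0,
        "glutamate": 8.0,
        "aspartate": 4.0,
        "alpha-ketoglutarate": 0.3,
        "fumarate": 0.5,
        "IMP": 0.15,
        "AMP": 2.0,
        "GMP": 0.8,
        "UMP": 0.6,
    }


def _default_dilution() -> Dict[str, float]:
    # Unlabeled influx per pool (amount/h): salvage synthesis keeps nucleotide
    # pools partially unlabeled at steady state; amino acid and TCA pools are
    # diluted through v_glc instead.
    return {
        "glutamine": 0.0,
        "glutamate": 0.0,
        "aspartate": 0.0,
        "alpha-ketoglutarate": 0.0,
        "fumarate": 0.0,
        "IMP": 2.0,
        "AMP": 2.0,
        "GMP": 2.0,
        "UMP": 2.0,
    }


@dataclass
class PoolModel:
    """Pool sizes, pathway fluxes and tracer context for the labeling model.

    Fluxes (amount/h): ``v_gls`` glutaminolysis (GLS1, gln -> glu -> alpha-KG),
    ``v_ppat`` de novo purine entry (PPAT, IMP synthesis), ``v_ta``
    transamination to aspartate, ``v_pyr`` pyrimidine entry (UMP synthesis),
    ``v_glc`` glucose-derived (pyruvate-route) anaplerosis into alpha-KG.
    ``alpha_amp``/``alpha_gmp`` partition IMP consumption into AMP/GMP
    synthesis.  ``dilution`` is unlabeled influx per pool.  ``enrichment`` is
    the tracer fraction of the medium pool (1.0 for 2 mM pure tracer).
    """

    pools: Dict[str, float] = field(default_factory=_default_pools)
    v_gls: float = 10.0
    v_ppat: float = 2.0
    v_ta: float = 4.0
    v_pyr: float = 1.0
    v_glc: float = 5.0
    alpha_amp: float = 0.5
    alpha_gmp: float = 0.3
    dilution: Dict[str, float] = field(default_factory=_default_dilution)
    enrichment: float = 1.0

    def __post_init__(self):
        for met, p in self.pools.items():
            if p <= 0:
                raise ValueError(f"pool size for {met} must be positive")
        for name in ("v_gls", "v_ppat", "v_ta", "v_pyr", "v_glc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for met, d in self.dilution.items():
            if d < 0:
                raise ValueError(f"dilution for {met} must be non-negative")
        if not (0.0 <= self.enrichment <= 1.0):
            raise ValueError("medium enrichment must lie in [0, 1]")

    def synthesis_flux(self, metabolite: str) -> float:
        return {
            "IMP": self.v_ppat,
            "AMP": self.alpha_amp * self.v_ppat,
            "GMP": self.alpha_gmp * self.v_ppat,
            "UMP": self.v_pyr,
        }[metabolite]


@dataclass(frozen=True)
class AtomTransitionMap:
    """Per-metabolite nitrogen position sources and carbon backbone tag.

    ``nitrogen[met]`` lists one source tag per nitrogen atom of the formula;
    ``carbon[met]`` is ``(tag, n_backbone)``.
    """

    nitrogen: Mapping[str, Tuple[str, ...]]
    carbon: Mapping[str, Tuple[str, int]]

    def __post_init__(self):
        for met, positions in self.nitrogen.items():
            dims = _FORMULA_DIMS.get(met)
            if dims is not None and len(positions) != dims[1]:
                raise ValueError(
                    f"{met}: {len(positions)} mapped N positions, formula has {dims[1]}"
                )

    def without_aspartate_routing(self) -> "AtomTransitionMap":
        """Variant with every aspartate-donated position made unlabeled
        (disables the M+3 channel of the purine nitrogen distribution)."""
        nitro = {
            met: tuple(
                "unlabeled" if tag in ("aspartate", "imp-aspartate", "asp-N") else tag
                for tag in tags
            )
            for met, tags in self.nitrogen.items()
        }
        return AtomTransitionMap(nitrogen=nitro, carbon=dict(self.carbon))


def load_atom_map(path: str) -> AtomTransitionMap:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    mets = raw["metabolites"]
    nitrogen = {m: tuple(v.get("nitrogen", ())) for m, v in mets.items()}
    carbon = {
        m: (v["carbon"]["tag"], int(v["carbon"]["n_backbone"])) for m, v in mets.items()
    }
    return AtomTransitionMap(nitrogen=nitrogen, carbon=carbon)


def load_default_atom_map() -> AtomTransitionMap:
    with resources.as_file(resources.files("glnfate.data") / "atom_map.yaml") as p:
        return load_atom_map(str(p))


# ---------------------------------------------------------------------------
# Linear enrichment-balance system.

_CORE_STATES = ("gC", "gN", "eC", "eN", "kC", "fC", "aC", "aN")
_CARBON_TAG_STATE = {
    "gln-backbone": "gC",
    "glu-backbone": "eC",
    "akg-backbone": "kC",
    "fum-backbone": "fC",
    "asp-backbone": "aC",
    "unlabeled": None,
}
_CORE_N_TAG_STATE = {"gln-N": "gN", "glu-N": "eN", "asp-N": "aN", "unlabeled": None}


def _build_system(model: PoolModel, amap: AtomTransitionMap, tracer: str):
    """Assemble x' = A x + c over core + product position-class states."""
    if tracer not in TRACERS:
        raise ValueError(f"unknown tracer {tracer!r}; choose from {TRACERS}")
    e_gln = model.enrichment if tracer == "gln-13C5-15N2" else 0.0
    e_glc = model.enrichment if tracer == "glc-13C6" else 0.0

    names: List[str] = list(_CORE_STATES)
    for met in _PRODUCT_METABOLITES:
        for tag in amap.nitrogen.get(met, ()):
            if tag == "unlabeled":
                continue
            key = f"{met}:{tag}"
            if key not in names:
                names.append(key)
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    A = np.zeros((n, n))
    c = np.zeros(n)

    def add_flow(state: str, v: float, source: Optional[str], source_const: float = 0.0):
        """Influx v into `state`'s pool from `source` (state name) or a constant."""
        i = idx[state]
        pool = _state_pool(state, model)
        A[i, i] -= v / pool
        if source is not None:
            A[i, idx[source]] += v / pool
        else:
            c[i] += v * source_const / pool

    def _state_pool(state: str, model: PoolModel) -> float:
        met = {
            "gC": "glutamine", "gN": "glutamine",
            "eC": "glutamate", "eN": "glutamate",
            "kC": "alpha-ketoglutarate", "fC": "fumarate",
            "aC": "aspartate", "aN": "aspartate",
        }.get(state)
        if met is None:
            met = state.split(":", 1)[0]
        return model.pools[met]

    v_up = model.v_gls + model.v_ppat + model.v_pyr
    d = model.dilution
    # glutamine: tracer uptake plus unlabeled turnover
    for st in ("gC", "gN"):
        add_flow(st, v_up, None, e_gln)
        add_flow(st, d.get("glutamine", 0.0), None, 0.0)
    # glutamate: the C5 backbone and amine nitrogen pass from glutamine via
    # both GLS1 and PPAT (PPAT transfers the amide N and releases glutamate)
    add_flow("eC", model.v_gls + model.v_ppat, "gC")
    add_flow("eC", d.get("glutamate", 0.0), None)
    add_flow("eN", model.v_gls + model.v_ppat, "gN")
    add_flow("eN", d.get("glutamate", 0.0), None)
    # alpha-KG: glutaminolysis carbon plus glucose-derived anaplerosis
    add_flow("kC", model.v_gls, "eC")
    add_flow("kC", model.v_glc, None, e_glc)
    add_flow("kC", d.get("alpha-ketoglutarate", 0.0), None)
    # fumarate inherits the TCA carbon flow
    add_flow("fC", model.v_gls + model.v_glc, "kC")
    add_flow("fC", d.get("fumarate", 0.0), None)
    # aspartate: carbon from the fumarate/OAA pool, nitrogen by transamination
    add_flow("aC", model.v_ta, "fC")
    add_flow("aC", d.get("aspartate", 0.0), None)
    add_flow("aN", model.v_ta, "eN")
    add_flow("aN", d.get("aspartate", 0.0), None)
    # nucleotide position classes
    src_map = {
        "gln-amide": "gN",
        "aspartate": "aN",
        "imp-amide": "IMP:gln-amide",
        "imp-aspartate": "IMP:aspartate",
    }
    for met in _PRODUCT_METABOLITES:
        v_syn = model.synthesis_flux(met)
        for tag in amap.nitrogen.get(met, ()):
            if tag == "unlabeled":
                continue
            key = f"{met}:{tag}"
            src = src_map.get(tag)
            if src is None:
                raise ValueError(f"unknown nitrogen source tag {tag!r} for {met}")
            if src not in idx:
                raise ValueError(f"source state {src!r} missing (map wiring broken)")
            add_flow(key, v_syn, src)
            add_flow(key, d.get(met, 0.0), None)
    return names, idx, A, c


def _solve_linear(A: np.ndarray, c: np.ndarray, times: Sequence[float]) -> np.ndarray:
    """Exact solution of x' = A x + c, x(0) = 0, via the augmented exponential."""
    n = A.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = c
    x0 = np.zeros(n + 1)
    x0[n] = 1.0
    out = np.empty((len(times), n))
    for k, t in enumerate(times):
        out[k] = (expm(M * t) @ x0)[:n]
    return np.clip(out, 0.0, 1.0)


def _poisson_binomial(ps: Sequence[float]) -> np.ndarray:
    dist = np.array([1.0])
    for p in ps:
        dist = np.convolve(dist, [1.0 - p, p])
    return dist


@dataclass
class LabelingTimeCourse:
    """MIDGrids per metabolite over labeling time points (hours)."""

    times: Tuple[float, ...]
    grids: Dict[float, Dict[str, MIDGrid]]

    def __post_init__(self):
        t = tuple(self.times)
        if any(x < 0 for x in t):
            raise ValueError("time points must be non-negative")
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("time points must be strictly ascending")
        self.times = t

    def grid(self, time_h: float, metabolite: str) -> MIDGrid:
        try:
            return self.grids[time_h][metabolite]
        except KeyError:
            raise KeyError(f"no grid for {metabolite!r} at t={time_h} h") from None

    def metabolites(self) -> List[str]:
        first = self.grids[self.times[0]]
        return list(first)


def simulate_labeling(
    model: PoolModel,
    amap: Optional[AtomTransitionMap] = None,
    times: Sequence[float] = DEFAULT_TIMES,
    tracer: str = "gln-13C5-15N2",
    metabolites: Optional[Sequence[str]] = None,
) -> LabelingTimeCourse:
    """Deterministic labeling time course under the two-pathway pool model."""
    amap = amap or load_default_atom_map()
    times = tuple(float(t) for t in times)
    if any(t < 0 for t in times):
        raise ValueError("times must be non-negative")
    mets = list(metabolites) if metabolites is not None else list(_FORMULA_DIMS)
    names, idx, A, c = _build_system(model, amap, tracer)
    traj = _solve_linear(A, c, times)

    def enrichment_at(k: int, state: Optional[str]) -> float:
        return 0.0 if state is None else float(traj[k, idx[state]])

    grids: Dict[float, Dict[str, MIDGrid]] = {}
    for k, t in enumerate(times):
        per_met: Dict[str, MIDGrid] = {}
        for met in mets:
            max_c, max_n = _FORMULA_DIMS[met]
            ctag, n_backbone = amap.carbon[met]
            ce = enrichment_at(k, _CARBON_TAG_STATE.get(ctag))
            cmarg = np.zeros(max_c + 1)
            if n_backbone > 0:
                cmarg[0] = 1.0 - ce
                cmarg[n_backbone] += ce
            else:
                cmarg[0] = 1.0
            ps = []
            for tag in amap.nitrogen.get(met, ()):
                if tag in _CORE_N_TAG_STATE:
                    ps.append(enrichment_at(k, _CORE_N_TAG_STATE[tag]))
                elif tag == "unlabeled":
                    ps.append(0.0)
                else:
                    ps.append(enrichment_at(k, f"{met}:{tag}"))
            nmarg = np.zeros(max_n + 1)
            pb = _poisson_binomial(ps)
            nmarg[: len(pb)] += pb
            per_met[met] = MIDGrid(met, np.outer(cmarg, nmarg))
        grids[t] = per_met
    return LabelingTimeCourse(times=times, grids=grids)


@dataclass(frozen=True)
class ShiftScores:
    """Early-time glutaminolysis activity vs late-time de novo purine entry.

    ``glutaminolysis_score``: carbon atom fraction of alpha-KG labeled at the
    early time point (GLS1 readout).  ``denovo_score``: nitrogen atom fraction
    of IMP labeled at the late time point (PPAT readout).
    ``nitrogen_shift_index``: log2(denovo / glutaminolysis).
    """

    glutaminolysis_score: float
    denovo_score: float
    nitrogen_shift_index: float


def pathway_scores(
    tc: LabelingTimeCourse,
    early: float = 0.25,
    late: float = 6.0,
    glutaminolysis_metabolite: str = "alpha-ketoglutarate",
    denovo_metabolite: str = "IMP",
) -> ShiftScores:
    g_grid = tc.grid(early, glutaminolysis_metabolite)
    d_grid = tc.grid(late, denovo_metabolite)
    gc, _ = _FORMULA_DIMS[glutaminolysis_metabolite]
    _, dn = _FORMULA_DIMS[denovo_metabolite]
    g = percent_labeled(g_grid, "C", gc)
    dnv = percent_labeled(d_grid, "N", dn)
    if g > 0 and dnv > 0:
        index = math.log2(dnv / g)
    else:
        index = math.inf if dnv > g else (-math.inf if g > dnv else 0.0)
    return ShiftScores(glutaminolysis_score=g, denovo_score=dnv, nitrogen_shift_index=index)


_DEFAULT_FIT_METABOLITES = (
    "glutamate",
    "alpha-ketoglutarate",
    "fumarate",
    "IMP",
    "AMP",
    "GMP",
    "UMP",
)


@dataclass
class FluxFit:
    estimates: Dict[str, float]
    rss: float
    converged: bool
    message: str


def fit_fluxes(
    observed: LabelingTimeCourse,
    skeleton: PoolModel,
    amap: Optional[AtomTransitionMap] = None,
    free: Sequence[str] = ("v_gls", "v_ppat"),
    metabolites: Sequence[str] = _DEFAULT_FIT_METABOLITES,
    tracer: str = "gln-13C5-15N2",
    x0: Optional[Sequence[float]] = None,
    upper: float = 1e3,
) -> FluxFit:
    """Least-squares recovery of free fluxes from an observed time course.

    Residuals are the stacked differences between observed and simulated MID
    grids for the chosen metabolites at the observed time points; estimates
    are bounded non-negative.  Non-convergence is reported, not silent.
    """
    if len(observed.times) < 2:
        raise ValueError("need at least two time points to fit fluxes")
    if len(metabolites) < 2:
        raise ValueError("need at least two metabolites spanning both pathways")
    amap = amap or load_default_atom_map()
    free = tuple(free)

    target = np.concatenate(
        [
            observed.grid(t, m).f.reshape(-1)
            for t in observed.times
            for m in metabolites
        ]
    )

    def residuals(theta: np.ndarray) -> np.ndarray:
        model = replace(skeleton, **{name: float(v) for name, v in zip(free, theta)})
        tc = simulate_labeling(model, amap, observed.times, tracer, metabolites)
        sim = np.concatenate(
            [tc.grid(t, m).f.reshape(-1) for t in observed.times for m in metabolites]
        )
        return sim - target

    start = np.asarray(x0 if x0 is not None else [1.0] * len(free), dtype=float)
    res = least_squares(
        residuals,
        start,
        bounds=(np.zeros(len(free)), np.full(len(free), upper)),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    return FluxFit(
        estimates={name: float(v) for name, v in zip(free, res.x)},
        rss=float(2 * res.cost),
        converged=bool(res.success),
        message=res.message,
    )


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    p: float
    n: int
    zero_variance: bool


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> PairedTTestResult:
    """Paired two-tailed Student's t-test on the differences x - y.

    Zero variance of the differences is flagged: identical samples give
    (t=0, p=1); a constant non-zero shift gives an infinite statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedTTestResult(t=0.0, p=1.0, n=n, zero_variance=True)
        t = math.copysign(math.inf, d.mean())
        return PairedTTestResult(t=t, p=0.0, n=n, zero_variance=True)
    from scipy.stats import t as t_dist

    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), df=n - 1)
    return PairedTTestResult(t=float(t), p=float(p), n=n, zero_variance=False)
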