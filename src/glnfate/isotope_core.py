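"""Exact-mass isotopologue arithmetic for dual 13C/15N stable-isotope tracing.

High-resolution Orbitrap instruments resolve a single 13C substitution
(+1.0033548 Da) from a single 15N substitution (+0.9970349 Da): the two differ
by the mass defect induced by nuclear binding energy (0.0063199 Da), which at
m/z ~150 requires a resolving power of only ~23,000 (FWHM definition).  This
module enumerates theoretical isotopologues of a metabolite over a 2-D grid of
(number of 13C, number of 15N) substitutions, assigns centroided peaks to that
grid within a ppm tolerance, corrects the resulting mass isotopomer
distribution (MID) for natural isotope abundance and tracer impurity, and
computes the atom-fraction "percent labeled" statistic.

The correction operates per element ("high-resolution mode"): when an element
is in the *resolved* set, only its own natural abundance contributes along its
grid axis, and the full correction matrix is the Kronecker product of
per-element binomial convolution matrices.  Heavy isotopes of H, O, P and S
are folded into nominal-mass bins only for axes that are not resolved.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

__all__ = [
    "ELEMENTS",
    "DEFAULT_ISOTOPES",
    "PROTON_MASS",
    "DELTA_13C",
    "DELTA_15N",
    "ElementalFormula",
    "parse_formula",
    "load_isotope_table",
    "validate_isotope_table",
    "monoisotopic_mass",
    "IsotopologueState",
    "TheoreticalIsotopologue",
    "isotopologue_mz",
    "ResolutionModel",
    "separability",
    "enumerate_grid",
    "merge_groups",
    "MIDGrid",
    "CentroidPeakList",
    "assign_peaks",
    "CorrectionMatrix",
    "build_correction",
    "forward_convolve",
    "correct_mid",
    "percent_labeled",
    "molecule_labeled_fraction",
    "read_peaklists_tsv",
    "read_metabolite_registry",
    "write_mid_csv",
]

ELEMENTS = ("C", "H", "N", "O", "P", "S")

#: (exact mass in Da, natural abundance fraction) per isotope, lightest first.
#: Masses from the standard atomic-mass evaluation; abundances are the usual
#: terrestrial values (13C 1.07%, 15N 0.364%, 2H 0.0115%, ...).
DEFAULT_ISOTOPES: Dict[str, List[Tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.003354835, 0.0107)],
    "H": [(1.0078250319, 0.999885), (2.0141017781, 0.000115)],
    "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
    "O": [(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)],
    "P": [(30.97376151, 1.0)],
    "S": [(31.97207069, 0.9499), (32.97145850, 0.0075), (33.96786683, 0.0425), (35.96708088, 0.0001)],
}

PROTON_MASS = 1.00727646

#: Mass increments for a single tracer substitution.
DELTA_13C = DEFAULT_ISOTOPES["C"][1][0] - DEFAULT_ISOTOPES["C"][0][0]
DELTA_15N = DEFAULT_ISOTOPES["N"][1][0] - DEFAULT_ISOTOPES["N"][0][0]


def validate_isotope_table(table: Mapping[str, Sequence[Tuple[float, float]]]) -> None:
    """Check abundance normalization and mass ordering per element."""
    for el, isos in table.items():
        masses = [m for m, _ in isos]
        abunds = [a for _, a in isos]
        if any(m <= 0 for m in masses):
            raise ValueError(f"non-positive isotope mass for element {el}")
        if any(masses[i] >= masses[i + 1] for i in range(len(masses) - 1)):
            raise ValueError(f"isotope masses not strictly increasing for {el}")
        if abs(sum(abunds) - 1.0) > 1e-9:
            raise ValueError(f"isotope abundances for {el} sum to {sum(abunds)!r}, not 1")


validate_isotope_table(DEFAULT_ISOTOPES)


def load_isotope_table(path: str) -> Dict[str, List[Tuple[float, float]]]:
    """Load an isotope table override from YAML: ``{element: [[mass, abundance], ...]}``."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    table = {el: [(float(m), float(a)) for m, a in isos] for el, isos in raw.items()}
    validate_isotope_table(table)
    return table


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map over C,H,N,O,P,S.  At least one atom, counts >= 0."""

    counts: Mapping[str, int]

    def __post_init__(self):
        counts = dict(self.counts)
        for el, n in counts.items():
            if el not in ELEMENTS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if not (isinstance(n, (int, np.integer)) and n >= 0):
                raise ValueError(f"invalid count for {el}: {n!r}")
        if sum(counts.values()) < 1:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    @property
    def n_carbon(self) -> int:
        return self["C"]

    @property
    def n_nitrogen(self) -> int:
        return self["N"]


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-like molecular formula restricted to C,H,N,O,P,S.

    >>> parse_formula("C5H10N2O3").counts
    {'C': 5, 'H': 10, 'N': 2, 'O': 3}
    """
    if not text or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", text):
        raise ValueError(f"malformed formula: {text!r}")
    counts: Dict[str, int] = {}
    for el, num in _FORMULA_RE.findall(text):
        if not el:
            continue
        if el not in ELEMENTS:
            raise ValueError(f"unknown element symbol: {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula, table: Mapping = DEFAULT_ISOTOPES) -> float:
    """Neutral monoisotopic mass: every atom on its lightest isotope."""
    return sum(n * table[el][0][0] for el, n in formula.counts.items())


class IsotopologueState(NamedTuple):
    n13c: int
    n15n: int


@dataclass(frozen=True)
class TheoreticalIsotopologue:
    state: IsotopologueState
    neutral_mass: float
    mz: Optional[float]
    charge: int


def isotopologue_mz(
    formula: ElementalFormula,
    state: IsotopologueState,
    charge: int = 0,
    table: Mapping = DEFAULT_ISOTOPES,
) -> TheoreticalIsotopologue:
    """Exact neutral mass and m/z of one (n13C, n15N) isotopologue.

    Ion convention: protonation/deprotonation, m/z = (M + z*m_proton)/|z|,
    so charge=-1 gives [M-H]- and charge=+1 gives [M+H]+.  charge=0 returns
    the neutral mass only.
    """
    state = IsotopologueState(*state)
    if not (0 <= state.n13c <= formula.n_carbon):
        raise ValueError(f"n13C={state.n13c} out of bounds for C{formula.n_carbon}")
    if not (0 <= state.n15n <= formula.n_nitrogen):
        raise ValueError(f"n15N={state.n15n} out of bounds for N{formula.n_nitrogen}")
    d13 = table["C"][1][0] - table["C"][0][0] if len(table["C"]) > 1 else DELTA_13C
    d15 = table["N"][1][0] - table["N"][0][0] if len(table["N"]) > 1 else DELTA_15N
    neutral = monoisotopic_mass(formula, table) + state.n13c * d13 + state.n15n * d15
    mz = None
    if charge != 0:
        mz = (neutral + charge * PROTON_MASS) / abs(charge)
    return TheoreticalIsotopologue(state=state, neutral_mass=neutral, mz=mz, charge=charge)


@dataclass(frozen=True)
class ResolutionModel:
    """FWHM resolving power R(m/z) = r_ref * (mz_ref / mz) ** exponent.

    ``separation_factor`` is the number of FWHM widths required between two
    species before they are called resolved (>= comparison at the boundary).
    """

    r_ref: float = 70000.0
    mz_ref: float = 200.0
    exponent: float = 0.5
    separation_factor: float = 1.0

    def __post_init__(self):
        if self.r_ref <= 0:
            raise ValueError("r_ref must be positive")
        if not (0.0 <= self.exponent <= 1.0):
            raise ValueError("exponent must lie in [0, 1]")
        if self.separation_factor < 1.0:
            raise ValueError("separation factor must be >= 1")

    def resolving_power(self, mz: float) -> float:
        return self.r_ref * (self.mz_ref / mz) ** self.exponent

    def fwhm(self, mz: float) -> float:
        return mz / self.resolving_power(mz)


def separability(mza: float, mzb: float, model: ResolutionModel) -> Tuple[float, bool]:
    """Resolving power required to separate two m/z values, and whether the
    instrument achieves it at their mean m/z."""
    if mza <= 0 or mzb <= 0:
        raise ValueError("m/z values must be positive")
    if mza == mzb:
        raise ValueError("identical m/z values cannot be separated")
    mean = 0.5 * (mza + mzb)
    required = mean / abs(mza - mzb) * model.separation_factor
    # ">=" at the boundary, robust to float representation of the inputs
    resolved = model.resolving_power(mean) >= required * (1.0 - 1e-12)
    return required, resolved


def enumerate_grid(
    formula: ElementalFormula,
    max_c: int,
    max_n: int,
    charge: int,
    table: Mapping = DEFAULT_ISOTOPES,
) -> List[TheoreticalIsotopologue]:
    """All (n13C, n15N) isotopologues up to (max_c, max_n), sorted by m/z."""
    if max_c > formula.n_carbon:
        raise ValueError(f"max_c={max_c} exceeds carbon count {formula.n_carbon}")
    if max_n > formula.n_nitrogen:
        raise ValueError(f"max_n={max_n} exceeds nitrogen count {formula.n_nitrogen}")
    grid = [
        isotopologue_mz(formula, IsotopologueState(c, n), charge, table)
        for c in range(max_c + 1)
        for n in range(max_n + 1)
    ]
    key = (lambda t: t.mz) if charge != 0 else (lambda t: t.neutral_mass)
    return sorted(grid, key=key)


def merge_groups(
    grid: Sequence[TheoreticalIsotopologue], model: ResolutionModel
) -> List[List[TheoreticalIsotopologue]]:
    """Group m/z-sorted isotopologues closer than the instrument FWHM.

    Species in the same group co-elute into a single centroid at the stated
    resolution (e.g. 13C1 and 15N1 below the mass-defect threshold).
    """
    groups: List[List[TheoreticalIsotopologue]] = []
    for iso in grid:
        mz = iso.mz if iso.mz is not None else iso.neutral_mass
        if groups:
            last = groups[-1][-1]
            last_mz = last.mz if last.mz is not None else last.neutral_mass
            if abs(mz - last_mz) < model.fwhm(0.5 * (mz + last_mz)) * model.separation_factor:
                groups[-1].append(iso)
                continue
        groups.append([iso])
    return groups


@dataclass
class MIDGrid:
    """2-D mass isotopomer distribution f[n13C, n15N] for one metabolite."""

    metabolite: str
    f: np.ndarray  # shape (max_c+1, max_n+1)

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 2:
            raise ValueError("MID grid must be 2-D (carbon axis x nitrogen axis)")
        if (self.f < -1e-12).any():
            raise ValueError("MID fractions must be non-negative")

    @property
    def total(self) -> float:
        return float(self.f.sum())

    def normalized(self) -> "MIDGrid":
        s = self.total
        if s <= 0:
            return MIDGrid(self.metabolite, np.array(self.f, copy=True))
        return MIDGrid(self.metabolite, self.f / s)

    def marginal(self, element: str) -> np.ndarray:
        """Marginal distribution over substitutions of one tracer element."""
        if element == "C":
            return self.f.sum(axis=1)
        if element == "N":
            return self.f.sum(axis=0)
        raise ValueError("element must be 'C' or 'N'")


@dataclass
class CentroidPeakList:
    """Centroided peaks for one sample/time: strictly ascending m/z, intensities >= 0.

    ``metabolite`` is an optional chromatographic identity: IC/LC separates
    metabolites before MS, so a peak list usually belongs to one analyte.
    Species that are near-isobaric across metabolites (e.g. IMP + 2x13C vs
    AMP + 3x15N, ~1 ppm apart) are only assignable when this identity is known.
    """

    sample_id: str
    time_h: float
    mz: np.ndarray
    intensity: np.ndarray
    metabolite: Optional[str] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if len(self.mz) > 1 and not (np.diff(self.mz) > 0).all():
            raise ValueError("m/z values must be strictly ascending")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass
class PeakAssignment:
    mid: MIDGrid
    raw_intensity: np.ndarray
    unassigned: List[int]
    ambiguous: List[int]


def assign_peaks(
    peaks: CentroidPeakList,
    grid: Sequence[TheoreticalIsotopologue],
    tolerance_ppm: float,
    metabolite: str = "",
) -> PeakAssignment:
    """Match each centroid to the nearest theoretical m/z within a ppm window.

    Intensities accumulate per isotopologue state; the result is normalized to
    sum 1 when any signal was assigned.  A peak with two theoreticals inside
    the window is assigned to the nearest (ties toward the lower substitution
    count) and flagged ambiguous.
    """
    if not grid:
        raise ValueError("theoretical grid is empty")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    max_c = max(t.state.n13c for t in grid)
    max_n = max(t.state.n15n for t in grid)
    raw = np.zeros((max_c + 1, max_n + 1))
    theo_mz = np.array([t.mz if t.mz is not None else t.neutral_mass for t in grid])
    unassigned: List[int] = []
    ambiguous: List[int] = []
    for i, (mz, inten) in enumerate(zip(peaks.mz, peaks.intensity)):
        ppm = np.abs(theo_mz - mz) / mz * 1e6
        inside = np.flatnonzero(ppm <= tolerance_ppm)
        if inside.size == 0:
            unassigned.append(i)
            continue
        if inside.size > 1:
            ambiguous.append(i)
        best = min(
            inside,
            key=lambda j: (ppm[j], grid[j].state.n13c + grid[j].state.n15n),
        )
        st = grid[best].state
        raw[st.n13c, st.n15n] += inten
    if raw.sum() == 0:
        warnings.warn(f"no peaks assigned for {metabolite or 'metabolite'}; all-zero MID")
        return PeakAssignment(MIDGrid(metabolite, raw), raw, unassigned, ambiguous)
    return PeakAssignment(MIDGrid(metabolite, raw / raw.sum()), raw, unassigned, ambiguous)


@dataclass
class CorrectionMatrix:
    """Maps a true flattened MID (row-major over (c, n)) to the observed one."""

    matrix: np.ndarray
    shape: Tuple[int, int]  # (max_c+1, max_n+1)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if (m < -1e-12).any():
            raise ValueError("correction matrix entries must be non-negative")
        if (m.sum(axis=0) > 1 + 1e-9).any():
            raise ValueError("correction matrix columns must sum to <= 1")
        self.matrix = m


def _tracer_axis_matrix(n_atoms: int, axis_size: int, p_heavy: float, purity: float) -> np.ndarray:
    """Column j: distribution of the observed substitution count given j true
    tracer substitutions -- binomial purity thinning of the j labeled atoms,
    then binomial natural-abundance gain over the remaining atoms."""
    M = np.zeros((axis_size, axis_size))
    for j in range(axis_size):
        for jp in range(j + 1):
            w = binom.pmf(jp, j, purity) if j > 0 else 1.0
            free = n_atoms - jp
            ks = np.arange(0, axis_size - jp)
            gain = binom.pmf(ks, free, p_heavy)
            M[jp : jp + len(ks), j] += w * gain
    return M


def _nominal_shift_distribution(
    formula: ElementalFormula,
    table: Mapping,
    elements: Iterable[str],
    max_shift: int,
) -> np.ndarray:
    """Distribution of the summed nominal-mass shift contributed by heavy
    isotopes of the given (non-tracer) elements."""
    dist = np.zeros(max_shift + 1)
    dist[0] = 1.0
    for el in elements:
        n = formula[el]
        if n == 0 or el not in table:
            continue
        isos = table[el]
        base = isos[0][0]
        atom = np.zeros(max_shift + 1)
        for m, p in isos:
            s = int(round(m - base))
            if s <= max_shift:
                atom[s] += p
        for _ in range(n):
            dist = np.convolve(dist, atom)[: max_shift + 1]
    return dist


def _shift_matrix(dist: np.ndarray, size: int) -> np.ndarray:
    T = np.zeros((size, size))
    for j in range(size):
        for s, p in enumerate(dist):
            if j + s < size:
                T[j + s, j] += p
    return T


def build_correction(
    formula: ElementalFormula,
    table: Mapping = DEFAULT_ISOTOPES,
    purity: Optional[Mapping[str, float]] = None,
    resolved: Iterable[str] = ("C", "N"),
    max_c: Optional[int] = None,
    max_n: Optional[int] = None,
) -> CorrectionMatrix:
    """Natural-abundance + tracer-purity correction matrix in high-resolution mode.

    For each tracer element (C along the first axis, N along the second) the
    per-axis matrix uses only that element's own natural abundance over the
    non-tracer atoms.  With both elements resolved the full matrix is the
    Kronecker product of the two per-axis matrices.  Heavy isotopes of
    H, O, P, S are folded into nominal-mass bins of an axis only when that
    tracer element is NOT in the resolved set.
    """
    purity = dict(purity or {})
    resolved = set(resolved)
    if not resolved <= {"C", "N"}:
        raise ValueError("resolved elements must be a subset of {'C', 'N'}")
    for el, p in purity.items():
        if not (0 < p <= 1):
            raise ValueError(f"tracer purity for {el} must be in (0, 1]")
    nc = formula.n_carbon if max_c is None else max_c
    nn = formula.n_nitrogen if max_n is None else max_n
    p13 = table["C"][1][1] if len(table["C"]) > 1 else 0.0
    p15 = table["N"][1][1] if len(table["N"]) > 1 else 0.0
    Mc = _tracer_axis_matrix(formula.n_carbon, nc + 1, p13, purity.get("C", 1.0))
    Mn = _tracer_axis_matrix(formula.n_nitrogen, nn + 1, p15, purity.get("N", 1.0))
    others = [el for el in ("H", "O", "P", "S") if formula[el] > 0]
    if others:
        if "C" not in resolved:
            dist = _nominal_shift_distribution(formula, table, others, nc)
            Mc = _shift_matrix(dist, nc + 1) @ Mc
        elif "N" not in resolved:
            dist = _nominal_shift_distribution(formula, table, others, nn)
            Mn = _shift_matrix(dist, nn + 1) @ Mn
    return CorrectionMatrix(np.kron(Mc, Mn), (nc + 1, nn + 1))


def forward_convolve(true_mid: MIDGrid, correction: CorrectionMatrix) -> MIDGrid:
    """Apply the forward natural-abundance model: observed = matrix @ true."""
    flat = true_mid.f.reshape(-1)
    if flat.size != correction.matrix.shape[1]:
        raise ValueError("grid shape does not match correction matrix")
    obs = correction.matrix @ flat
    return MIDGrid(true_mid.metabolite, obs.reshape(correction.shape))


@dataclass
class CorrectedMID:
    mid: MIDGrid
    residual_norm: float
    condition_number: float


def correct_mid(raw: MIDGrid, correction: CorrectionMatrix, cond_limit: float = 1e10) -> CorrectedMID:
    """Invert the forward model by non-negative least squares and renormalize.

    NNLS (rather than a plain matrix inverse) guarantees a non-negative MID;
    the residual norm and the condition number of the matrix are reported so
    an ill-conditioned correction is visible rather than silent.
    """
    y = raw.f.reshape(-1)
    M = correction.matrix
    if y.size != M.shape[0]:
        raise ValueError("grid shape does not match correction matrix")
    cond = float(np.linalg.cond(M))
    if not np.isfinite(cond) or cond > cond_limit:
        raise np.linalg.LinAlgError(
            f"correction matrix ill-conditioned (condition number {cond:.3g})"
        )
    x, rnorm = nnls(M, y)
    if x.sum() > 0:
        x = x / x.sum()
    return CorrectedMID(MIDGrid(raw.metabolite, x.reshape(correction.shape)), float(rnorm), cond)


def percent_labeled(mid: MIDGrid, element: str, n_atoms: int) -> float:
    """Atom fraction of an element derived from the tracer.

    The abundance-weighted mean substitution count divided by the number of
    atoms of that element: sum_k k * f_k / n_atoms, with the marginal taken
    over the requested axis.  This is the "percent labeled" statistic of the
    tracing figures (proportion of atoms, not of molecules).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    marg = mid.marginal(element)
    s = marg.sum()
    if s <= 0:
        return 0.0
    marg = marg / s
    return float(np.arange(len(marg)) @ marg / n_atoms)


def molecule_labeled_fraction(mid: MIDGrid, element: str) -> float:
    """Fraction of molecules carrying at least one tracer atom of the element."""
    marg = mid.marginal(element)
    s = marg.sum()
    if s <= 0:
        return 0.0
    return float(1.0 - marg[0] / s)


# ---------------------------------------------------------------------------
# External interfaces: TSV peak lists, metabolite registry, long-format MIDs.

def read_peaklists_tsv(path: str) -> List[CentroidPeakList]:
    """Read the canonical peak-list TSV (sample_id, time_h, mz, intensity),
    one CentroidPeakList per (sample, time)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_h", "mz", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"peak list must have columns {sorted(required)}")
    if df.empty:
        raise ValueError(f"peak list {path!r} is empty")
    keys = ["sample_id", "time_h"]
    has_met = "metabolite" in df.columns
    if has_met:
        keys.append("metabolite")
    out = []
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("mz")
        out.append(
            CentroidPeakList(
                sample_id=str(key[0]),
                time_h=float(key[1]),
                mz=grp["mz"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                metabolite=str(key[2]) if has_met else None,
            )
        )
    return out


def read_peaklists_mzml(path: str, sample_id: Optional[str] = None) -> List[CentroidPeakList]:
    """Optional mzML reader producing the same structure as the TSV reader.

    One CentroidPeakList per spectrum; the scan start time (minutes in mzML)
    is converted to hours.  Requires pyteomics.
    """
    from pyteomics import mzml as _mzml  # deferred: optional dependency

    out = []
    with _mzml.MzML(path) as reader:
        for i, spec in enumerate(reader):
            scan = spec.get("scanList", {}).get("scan", [{}])[0]
            t_min = float(scan.get("scan start time", 0.0))
            mz = np.asarray(spec["m/z array"], dtype=float)
            inten = np.asarray(spec["intensity array"], dtype=float)
            order = np.argsort(mz)
            out.append(
                CentroidPeakList(
                    sample_id=sample_id or spec.get("id", f"scan{i}"),
                    time_h=t_min / 60.0,
                    mz=mz[order],
                    intensity=inten[order],
                )
            )
    return out


@dataclass(frozen=True)
class MetaboliteEntry:
    metabolite: str
    formula: ElementalFormula
    charge: int


def read_metabolite_registry(path: str) -> Dict[str, MetaboliteEntry]:
    """Registry CSV with columns metabolite, formula, polarity, charge."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"metabolite", "formula", "charge"}
    if not required <= set(df.columns):
        raise ValueError(f"registry must have columns {sorted(required)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["metabolite"])] = MetaboliteEntry(
            metabolite=str(row["metabolite"]),
            formula=parse_formula(str(row["formula"])),
            charge=int(row["charge"]),
        )
    return out


def write_mid_csv(path: str, rows: Iterable[Mapping]) -> None:
    """Long-format MID CSV: sample, time_h, metabolite, n13C, n15N,
    fraction_raw, fraction_corrected."""
    import pandas as pd

    df = pd.DataFrame(list(rows))
    cols = ["sample", "time_h", "metabolite", "n13C", "n15N", "fraction_raw", "fraction_corrected"]
    df = df[cols]
    df.to_csv(path, index=False, float_format="%.10g")
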