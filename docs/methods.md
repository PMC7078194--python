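# Methods

`glnfate` implements the quantitative machinery for asking where glutamine's
carbon and nitrogen go in a cell: into the TCA cycle via glutaminase
(GLS1-mediated anaplerosis, read out as early 13C labeling of
alpha-ketoglutarate and fumarate) or into de novo nucleotide biosynthesis via
amidophosphoribosyltransferase (PPAT, read out as late 15N labeling of IMP,
AMP, GMP and UMP). Four components feed that question: a dual-tracer
isotopologue engine, a kinetic labeling model, spike-in MRM quantification,
and a survival meta-analysis. This note records the models, the defaults and
the choices made where the design was open.

## Dual 13C/15N isotopologue analysis (`isotope_core`)

**Model.** A metabolite labeled from [13C5/15N2]glutamine occupies a 2-D mass
isotopomer distribution (MID) over (number of 13C, number of 15N)
substitutions. The two single substitutions differ by the nuclear mass defect
(13C adds 1.0033548 Da, 15N adds 0.9970349 Da; gap 0.0063199 Da), so a
high-resolution instrument separates the carbon and nitrogen axes directly.
Resolving power is modeled as FWHM-defined with Orbitrap-like scaling
R(m/z) = R_ref (m/z_ref / m/z)^0.5; the default setting is 70,000 at m/z 200.
Two species are "resolved" when the instrument's R at their mean m/z is at
least mean(m/z)/|dm| times a separation factor (default 1 FWHM, >= at the
boundary). A practical consequence worth knowing: at m/z ~347 (nucleotide
monophosphates, [M-H]-) the 13C1/15N1 gap needs R ~ 55,000 while the
modeled instrument delivers ~53,000, so those species merge into a single
centroid and are flagged; at m/z ~146 (glutamate) the requirement is
~23,000 against ~82,000 available.

**Ion convention.** Protonation/deprotonation with proton mass 1.00727646 Da:
[M-H]- for anionic metabolites (ion chromatography channel: organic acids,
nucleotides), [M+H]+ for cationic (amino acids), configurable per metabolite
in the registry CSV.

**Peak assignment.** Each centroid is matched to the nearest theoretical m/z
within a ppm tolerance (default 5 ppm). Two theoreticals inside the window
make the assignment ambiguous: the nearest wins, ties break toward the lower
substitution count, and the peak is flagged. Peak lists may carry a
`metabolite` column (chromatographic identity); without it, near-isobaric
species across metabolites (IMP + 2x13C vs AMP + 3x15N differ by ~1 ppm)
cannot be told apart at any practical tolerance.

**Natural-abundance correction.** The correction matrix maps a true flattened
MID to the observed one. In high-resolution mode each tracer element is
corrected along its own axis using only its own natural abundance over the
atoms not carrying tracer label: column j of the per-axis matrix is the
binomial thinning of j labeled atoms by the tracer purity (default 1.0;
purity is not part of the experimental record) convolved with binomial
natural-abundance gain over the remaining atoms. With both C and N resolved
the full matrix is the Kronecker product of the two per-axis matrices —
verified in tests against exhaustive per-atom multinomial enumeration. Heavy
isotopes of H, O, P and S are folded into nominal-mass bins of an axis only
when that axis is *not* resolved (they fold into the carbon axis when C is
unresolved, else the nitrogen axis). The inversion uses non-negative least
squares rather than a matrix inverse, guaranteeing a non-negative MID; the
residual norm and matrix condition number are reported, and an
ill-conditioned matrix (cond > 1e10) is an error rather than a silent
garbage result. The upstream processing pipeline this emulates does not
document its correction procedure, so the per-element high-resolution scheme
is this package's own documented choice.

**Percent labeled.** The headline statistic is the *atom* fraction: the
abundance-weighted mean substitution count divided by the number of atoms of
the element (sum_k k f_k / n_atoms). It is invariant under renormalization
and linear in mixtures. Because figure-style readouts sometimes mean the
fraction of *molecules* carrying any label, `molecule_labeled_fraction`
(1 - M0 of the marginal) is computed alongside and reported separately.

## Kinetic labeling model (`tracer_flux`)

**Model.** Well-mixed pools of constant size with first-order turnover. The
tracked quantities are tracer enrichments of *position classes*, not full
isotopomer vectors: the C5/C4 carbon backbone travels as one intact unit
(glutamine -> glutamate -> alpha-KG; the C4 unit on to fumarate and the
OAA/aspartate pool), and each nitrogen position is tagged by its biosynthetic
donor. For a position class x in a pool of size P with influxes v_i of
enrichment s_i:

    dx/dt = sum_i v_i (s_i(t) - x) / P

The wiring: glutamine turns over by uptake (v_GLS + v_PPAT + v_pyr) at medium
enrichment; glutamate receives the backbone and amine nitrogen through both
GLS1 *and* PPAT (PPAT transfers the amide nitrogen and releases glutamate);
alpha-KG receives glutaminolysis carbon (v_GLS) plus glucose-derived
anaplerosis (v_glc, unlabeled under the glutamine tracer — this is what keeps
steady-state alpha-KG labeling below the medium enrichment); fumarate
inherits the TCA flow; aspartate gets carbon from the fumarate/OAA pool and
nitrogen by transamination (v_TA) from glutamate. Purine nitrogen positions
follow the canonical donors — IMP: two glutamine amides (N3, N9), one
aspartate (N1), one glycine (N7, untraced); AMP adds an aspartate nitrogen
(N6), GMP a glutamine amide (N2); UMP: one carbamoyl (glutamine amide via
CPS-II) and one aspartate. The donor map lives in an editable YAML file
(`data/atom_map.yaml`), not in code; disabling the aspartate route there is
what removes the M+3 channel of the purine nitrogen distribution.

**Solution.** The system is linear and time-invariant, so rather than running
a numerical integrator it is solved exactly by the matrix exponential of the
augmented system [[A, c], [0, 0]] — machine-precision accuracy at any time
point, no tolerance knobs, and fast enough that the flux fit evaluates
thousands of forward models per second.

**MID assembly.** Positions are treated as independent (adequate for
first-order well-mixed pools; positional correlations from intact multi-N
transfer are not tracked): the nitrogen axis is the Poisson-binomial over
per-position enrichments and the carbon axis all-or-none at the backbone
size. Grids always normalize to 1.

**Defaults.** Time grid {0, 0.25, 6, 24} h (early point isolates
glutaminolysis before de novo synthesis contributes; late points read the
nucleotide pathway). Pool sizes (relative amount units): glutamine 2,
glutamate 8, aspartate 4, alpha-KG 0.3, fumarate 0.5, IMP 0.15, AMP 2,
GMP 0.8, UMP 0.6 — nucleotide pools small against amino acid pools,
glutamate the largest free pool. Nucleotide pools get an unlabeled
(salvage) influx of 2 /h so their steady-state labeling plateaus below the
medium enrichment and differs between scenarios; other dilution is carried
by v_glc. Medium tracer enrichment defaults to 1.0 (pure tracer at 2 mM);
the physiological-medium preset (0.6 mM glutamine) scales the
glutamine-consuming fluxes by 0.6 (uptake-limited turnover) but leaves
enrichment at 1.0.

**Scenario presets.** "TSM-like" (premalignant-like): v_GLS 12, v_PPAT 1.0,
v_TA 4, v_pyr 0.6, v_glc 4. "AIG3-like" (malignant-like): v_GLS 4, v_PPAT 5,
v_TA 4, v_pyr 1.8, v_glc 8 (higher glycolytic/pyruvate anaplerosis). The
defining invariant is the direction of the contrast — the malignant-like
state has a higher v_PPAT/v_GLS ratio — not the absolute values, which are
round numbers chosen once to put early alpha-KG labeling and late IMP
labeling in plausibly measurable ranges.

**Pathway scores.** glutaminolysis_score = 13C atom fraction of alpha-KG at
0.25 h; denovo_score = 15N atom fraction of IMP at 6 h; nitrogen_shift_index
= log2(denovo/glutaminolysis). Both scores are strictly increasing in their
fluxes (v_GLS and v_PPAT respectively), which is what makes the index a
meaningful one-number summary of the shift.

**Flux fitting.** `fit_fluxes` runs bounded (non-negative) least squares over
the stacked MID-grid residuals at the observed time points, free parameters
defaulting to (v_GLS, v_PPAT) with everything else fixed at the skeleton's
values. Noise-free self-consistency recovers generating fluxes to <0.1%;
identifiability relies on observing both an early TCA metabolite and a late
nucleotide.

## Spike-in MRM quantification (`impaqt_quant`)

Endogenous peptide amount = (sum of light transition intensities / sum of
heavy) x spiked amount — summation *before* the ratio, which makes the
estimate invariant to common intensity rescaling; peptides with a zero heavy
sum are excluded and counted, never turned into infinities. Protein
abundance is the mean +/- sample s.d. over peptide x replicate estimates
(a single estimate is s.d. 0 by convention and flagged low-evidence).
Copies per cell = abundance [fmol/ug] x 1e-15 x protein-per-cell [ug] x
Avogadro; the protein amount per cell is a configuration value (default
2.5e-4 ug, a typical mammalian figure) — the protein assay itself is not
modeled. Panel z-scores standardize each protein across samples with sample
s.d. (ddof = 1, configurable since either convention is defensible);
constant rows are emitted as zeros with a flag. The PPAT/GLS1 abundance
ratio per sample is the panel's one-number summary of nitrogen-fate balance.

## Survival meta-analysis (`survival_meta`)

Per cohort and gene: dichotomize at the median (strictly above -> high; ties
to the low group — the convention is documented and configurable because the
upstream databases do not state theirs), then maximize the Cox partial
likelihood for the single binary covariate by Newton iteration with Efron
tie handling (more accurate than Breslow when event times tie). The
model-based SE is the inverse observed information. Monotone likelihood
(separation) is detected when the estimate diverges (|log HR| > 15) and the
cohort is excluded from pooling, counted in a skip report — this is why
per-gene patient totals can differ. Kaplan-Meier curves and the 1-df
log-rank test are delegated to lifelines.

Pooling: fixed-effect inverse-variance, and DerSimonian-Laird random effects
with tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)),
I^2 = max(0, (Q - df)/Q) x 100, both with Wald CIs and p-values on the
log-HR scale (pooling happens on log HR, not HR). Per-organ tables are
produced under both models; integration across organs uses random effects.
Cohorts enter only if their maximum follow-up exceeds a configurable filter
(default 84 months, i.e. >7 years). No multiplicity correction is applied to
the volcano p-values. The Cox estimator is cross-checked in tests against an
exhaustive grid search of an independently coded partial likelihood and
against lifelines; the pooling against statsmodels' `combine_effects`.

## Synthetic data (`synthetic_data`)

Every generator returns ground truth next to observations, enabling
closed-loop recovery tests.

- **Peak lists**: kinetic-model MIDs -> natural-abundance convolution ->
  exact m/z per isotopologue -> merging of species closer than the
  instrument FWHM (flagged) -> multiplicative log-normal noise (mean-one
  parameterization) -> one centroid list per metabolite channel and time.
- **Transition tables**: ground-truth copy numbers inverted through the
  quantification model into light/heavy ratios, log-normal noise per
  transition at a given CV.
- **Cohorts**: per-gene log-normal expression; subjects above the cohort
  median have their exponential hazard (baseline ln2/36 per month, i.e.
  36-month median survival) multiplied by a cohort-specific HR drawn as
  log HR ~ Normal(log true HR, tau^2); independent exponential censoring
  tuned to a target fraction (default 0.3) plus an administrative cap at
  180 months. Survival ground truth anchors to the pooled neuroendocrine
  contrasts (PPAT 5.21, GLS1 0.38). When several genes multiply one hazard,
  the marginal per-gene Cox HR is attenuated relative to the conditional
  generating HR (non-collapsibility); recovery simulations therefore use one
  gene per run so that the generating HR is the marginal estimand.

What the generators deliberately do **not** emulate: chromatographic peak
shapes and drift, batch effects, interference between co-eluting analytes,
missing-not-at-random expression, non-proportional hazards, and correlated
censoring. Passing the recovery tests shows the estimators invert their own
forward models under realistic noise — it does not certify behavior under
model misspecification real data can exhibit.

## Numerical choices and degenerate inputs

- Correction inversion: NNLS; residual and condition number reported;
  cond > 1e10 raises.
- Separability boundary: ">= required" with a 1e-12 relative guard against
  float representation.
- Newton steps in the Cox solver are clipped to +/-2 per iteration;
  divergence past |beta| = 15 flags separation.
- Zero-variance paired differences: t = 0, p = 1 when the samples are
  identical, +/-inf with p = 0 for a constant non-zero shift, both flagged.
- Constant expression or a split with an empty group raises rather than
  producing a degenerate HR; all-zero peak assignment warns and returns an
  all-zero MID.
- Tumor volume auto-swaps axes (width is the smaller by convention) with a
  warning.

## Problem sizes

The recovery experiments run at desk scale chosen to make Monte-Carlo error
small against the quantities checked: 200 correction simulations at 1%
noise, 100 flux-fit replicates at 5% noise, 100 random toy datasets for the
Cox/grid-search comparison, 200 replicate meta-analyses (k = 10 cohorts,
n = 500) for CI coverage, one n = 20,000 cohort for generator calibration,
and a 100-protein MRM panel at 10% CV.

## Known limitations

- Carbon is all-or-none at the backbone unit: partial TCA scrambling
  (M+1..M+4 carbon isotopomers of alpha-KG/fumarate) is not modeled, so the
  carbon readout is the backbone-labeled fraction only.
- No compartmentation (cytosolic vs mitochondrial pools share one
  enrichment) and constant pool sizes during labeling.
- The two-pathway decomposition of late-time alpha-KG/fumarate labeling is
  explicit in the model but the real partition is not identifiable from the
  spectra alone.
- Univariate Cox on the dichotomized indicator only; no clinical covariates,
  no competing risks.
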