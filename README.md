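# glnfate

Quantitative analysis of glutamine carbon and nitrogen fate in cancer cells.

Proliferating cells consume glutamine in two competing ways: glutaminase
(GLS1) cleaves the amide (γ) nitrogen and feeds the carbon skeleton into the
TCA cycle (glutaminolysis/anaplerosis), while amidophosphoribosyltransferase
(PPAT) transfers that same amide nitrogen onto PRPP, the committed step of de
novo purine biosynthesis. Malignant progression shifts the balance from the
first fate to the second, and the shift is measurable three independent ways:
dual-isotope tracing, absolute protein quantification, and patient survival.
`glnfate` implements the quantitative machinery for all three, plus synthetic
data generators with known ground truth, for metabolism and cancer-genomics
researchers who want the analyses as tested, reusable code.

## What's inside

- **`isotope_core`** — dual [13C5/15N2]glutamine isotopologue analysis:
  exact-mass enumeration over a 2-D (n13C, n15N) grid, mass-defect
  separability (13C adds 1.0033548 Da, 15N adds 0.9970349 Da — resolvable at
  Orbitrap resolving powers), ppm-tolerance peak assignment,
  natural-abundance/purity correction by per-element binomial convolution
  inverted with non-negative least squares, and the "percent labeled" atom
  fraction Σₖ k·fₖ / n_atoms.
- **`tracer_flux`** — a two-pathway kinetic labeling model: first-order
  well-mixed pools, position-class enrichments dx/dt = Σ vᵢ(sᵢ − x)/P solved
  exactly by matrix exponential, purine/pyrimidine nitrogen wired by an
  editable atom-transition map (IMP: 2 glutamine amides + 1 aspartate +
  1 glycine). Early 13C α-ketoglutarate labeling reads GLS1 activity; late
  15N IMP labeling reads PPAT. Includes pathway shift scores and bounded
  least-squares recovery of (v_GLS, v_PPAT).
- **`impaqt_quant`** — spike-in MRM absolute quantification: endogenous =
  (Σ light / Σ heavy) × spiked fmol, protein mean ± s.d. over peptides and
  replicates, copies per cell, panel z-scores and the PPAT/GLS1 ratio.
- **`survival_meta`** — per-cohort median-split hazard ratios (Newton on the
  Efron partial likelihood, separation-flagged), Kaplan-Meier + log-rank,
  fixed-effect and DerSimonian-Laird random-effects pooling with Q, τ², I²,
  and per-organ / integrated per-gene tables.
- **`synthetic_data`** — generators for all three input kinds with ground
  truth attached, and scenario presets ("TSM-like" premalignant vs
  "AIG3-like" malignant, plus a 0.6 mM physiological-medium variant).
- **`pipeline_io` / CLI** — end-to-end runs with provenance records;
  `glnfate mid | simulate | scores | mrm | meta | synth`.

## Worked example

Generate synthetic dual-tracer spectra for both scenarios, assign and correct
the MIDs, and compute the pathway scores:

```sh
glnfate synth peaks --preset AIG3-like --seed 42 --out synth
glnfate mid --peaks synth/peaks.tsv \
            --metabolites src/glnfate/data/metabolites.csv --out mid_out
cat mid_out/scores.csv
```

```
sample,glutaminolysis_score,denovo_score,nitrogen_shift_index
AIG3-like,0.03259794183,0.5422865094,4.056202497
```

The same commands with `--preset TSM-like` print:

```
sample,glutaminolysis_score,denovo_score,nitrogen_shift_index
TSM-like,0.1221899931,0.246206843,1.010744722
```

Reading: in the malignant-like state only 3.3% of α-ketoglutarate carbon is
tracer-derived at 0.25 h (glutaminolysis down ~4-fold versus 12.2%), while
54% of IMP nitrogen is labeled at 6 h (de novo purine synthesis up ~2-fold
versus 25%) — the nitrogen shift index (log2 of the ratio of the two scores)
rises from 1.0 to 4.1.

For the survival side, simulate ten cohorts with known per-gene hazard ratios
and pool them:

```sh
glnfate synth cohorts --preset AIG3-like --seed 42 --out cohorts
glnfate meta --manifest cohorts/manifest.csv --out meta_out
```

`meta_out/integrated.csv` (random-effects pooling across cohorts):

```
gene       hr   ci_low  ci_high            p        i2  n_patients
PPAT 3.658346 3.214327 4.163701 6.221297e-86  0.000000        2000
GART 2.027189 1.767168 2.325468 6.144294e-24 22.555609        2000
GMPS 1.518634 1.318745 1.748820 6.537392e-09 28.237595        2000
UMPS 1.257329 1.099335 1.438029 8.310282e-04 22.224075        2000
GLS1 0.513085 0.454710 0.578954 2.517008e-27  0.000000        2000
```

High expression of the purine-pathway enzymes is deleterious (HR > 1, PPAT on
top) and high glutaminase expression protective (HR < 1), recovering the
generating contrast. Marginal HRs sit closer to 1 than the conditional
generating values because several prognostic genes share one hazard in this
simulation (non-collapsibility of the hazard ratio); single-gene simulations
recover the generating HR itself (see `docs/methods.md`).

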