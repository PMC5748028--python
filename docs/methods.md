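# Methods

## The evaluation problem

A targeted metabolomics kit quantifies a fixed 188-metabolite panel in eight
compound classes: 21 amino acids (AA) and 21 biogenic amines (BA) by LC-MS/MS
after derivatization, and 40 acylcarnitines (AC), 38 diacyl- and 38
acyl-alkyl-phosphatidylcholines (PCaa, PCae), 14 lysophosphatidylcholines
(lysoPC), 15 sphingomyelins (SM), and total hexoses (H1) by flow-injection
MS/MS against 13 shared lipid/acylcarnitine internal standards plus one for
the hexoses.  Applying it to tissue homogenates raises three questions per
extraction condition — a (solvent, tissue:solvent ratio) pair: how much of
the panel becomes quantifiable, how reproducibly, and how badly does the
co-extracted matrix distort ionization?  The package computes those three
axes from a plate of per-well concentrations (µM) and ISTD peak areas and
reduces them to one auditable recommendation per tissue.

## Definitions and estimators

**Quantifiability.**  A metabolite is quantifiable in a condition iff its
concentration is above the LOD in every replicate.  The boundary is
inclusive — a value exactly at the LOD counts as detectable (`below_lod =
conc < LOD`); the convention is configurable (`at_lod_detectable=False`
flips it) but used consistently everywhere, including the synthetic
censoring.  Missing values are never imputed (a zero would corrupt CVs and
means); a missing replicate disqualifies the metabolite, as does absence
from a condition's wells.  Class yield divides by the *full* panel class
size so conditions are comparable; the single-member hexose class therefore
reports 0 or 100.

**Dilution correction.**  Extract µM ≡ pmol/µL, multiplied by X µL solvent
per mg tissue gives pmol/mg.  Only the added solvent is corrected for;
tissue water is not subtracted.  Because the generator *does* model tissue
water (below), corrected synthetic concentrations underestimate true content
by the factor X/(X+w) — a deliberate, documented bias shared with standard
practice; exact-recovery tests set w = 0.

**Fold changes.**  Per tissue, each condition is compared with the methanol
extract at the tissue's lower ratio.  Per class the default aggregate is the
median over metabolites (quantifiable in both conditions) of the log2 ratio
of condition means; the median resists the heavy right tails of lipid
concentrations.  A mean aggregator and a summed-class variant
(log2 of summed means over the common metabolites) are selectable, since the
class-level aggregation rule is a genuine design choice.  Cells where no
metabolite qualifies are NA; the reference column is identically zero.

**CVs.**  `100 · sd(ddof=1) / mean` over replicate concentrations of
quantifiable metabolites, n ≥ 2.  Summaries report median, 20% and 80%
quantiles (linear interpolation of order statistics, the "type 7" rule —
fixed so the oracle test is exact) and fractions with CV strictly below each
threshold (defaults 10% and 15%; 15% is the accepted bioanalytical
criterion).

**Ionization efficiency.**  Per (condition, ISTD):
`100 · median(tissue-extract areas) / mean(zero-sample areas)` for the
matching solvent.  The median is robust to single-well failures; the three
zero samples are averaged.  Zero samples define 100% by construction.
Metabolites inherit their ISTD's value.  The relative matrix effect divides
the tissue median by the median over reference plasma wells; values > 1 mean
less suppression than in the matrix the assay was validated for.

**Isotopologue crosstalk.**  The distribution of a molecule's total nominal
mass shift is the convolution of per-atom isotope distributions (polynomial
multiplication over integer shift exponents), truncated with the tail mass
reported.  Unit-resolution (nominal) shifts are used, not exact masses: the
interference of interest is channel overlap at integer Dalton spacing.  The
packaged abundance table covers H, C, N, O, S, P, Cl (IUPAC values,
renormalized per element to sum to 1).  The full elemental contribution is
computed — for taurine's M+2 (≈ 4.7%) the dominant term is ³⁴S, not ¹³C₂ —
because the mechanism is channel overlap regardless of element.  ISTD
labeling is assumed isotopically pure.

**Interference flags.**  (a) Any metabolite above its ULOQ in any replicate
of a condition.  (b) Crosstalk suspects: predicted crosstalk fraction
(M+shift abundance × condition mean concentration / a 55 µM plasma-scale
reference) above a threshold (default 0.1), or the metabolite's ISTD showing
efficiency above an enhancement threshold (default 300% — far outside what
matrix effects produce).  Every flag carries its numeric evidence.

**Recommendation.**  The combination of the three axes into one choice is
not canonical; the package uses
`w_y · mean class yield/100 + w_r · frac(CV < 15%) + w_i · min(median
efficiency, 100)/100` with defaults (0.4, 0.4, 0.2).  Efficiency is capped:
enhancement above the zero-sample anchor is an artifact, not a benefit.
Flagged metabolites are excluded from scoring by default.  Exact ties break
deterministically: reproducibility, then yield, then solvent preference
EtOH/PB > MeOH > PB (the mixed solvent extracts the broadest panel with high
reproducibility), then the lower ratio (less dilution → higher sensitivity).
Sub-scores are always reported so any other rule can be audited.

## The synthetic generator

The generator emulates the 11-tissue × 3-solvent × 2-ratio design (ratios
1:3/1:6 for most tissues; 1:6/1:9 for bone; 1:12/1:18 for the low-input
pituitary and adrenal glands), 6 replicates per condition, 3 zero samples
per solvent, 5 reference plasma wells, 3 spiked QC wells, and a 7-level
calibrator series — one plate, no between-plate variance (plate-effect
monitoring via reference plasma is represented; simulating it is out of
scope).

For metabolite m (class c, true content T pmol/mg), tissue t (water w
µL/mg), solvent s, ratio X:

    extract conc  C = T · E[c,s] / (X + w)        (µM)
    observed conc = C · ε,   ε lognormal, mean 1, CV = cv[c,s]
    ISTD area     = base · S[t,s,mode] · ε′  +  k · conc · p_shift

`ε` uses σ² = ln(1+cv²), µ = −σ²/2 so its mean is exactly 1 and its true CV
exactly the configured value; cv = 0 is the degenerate noise-free limit
(ε ≡ 1), used by the exact-recovery tests.  The denominator X + w models the
tissue's own water diluting the extract beyond the nominal ratio; the
default w is a single placeholder 0.75 µL/mg (0.2 for fat, 0.3 for bone),
as per-tissue water volumes are not separately established.  An optional
efficiency bonus `E·(1+β·X/(X+w))` exists to emulate better lipid extraction
at higher organic dilution; β defaults to 0 (documented knob, not asserted
behavior).

Default parameters are the study conditions, chosen once:

* **Extraction efficiencies** E[c,s]: lipid classes ≈ 0.9–0.95 in MeOH and
  EtOH/PB but 0.04–0.08 in phosphate buffer; AA/BA highest in buffer
  (0.92–0.95); acylcarnitines 0.85–0.9 organic, 0.5 buffer; hexoses high
  everywhere.
* **Replicate CVs**: ≈ 0.09–0.11 for FIA classes in organic solvents,
  0.22–0.25 in buffer; AA ≈ 0.08–0.10 everywhere; BA best in buffer (0.12)
  and poor in organics (0.24–0.30).
* **Suppression** S: FIA factors drawn uniformly in [0.6, 0.8] per
  (tissue, solvent), with fat/PB fixed at 0.3 and pituitary/PB and bone/PB
  at 1.0; LC factors uniform in [0.7, 1.5].  Zero samples and plasma have
  S = 1 by definition.
* **Contents**: class-level medians (AA 2000, BA 60, AC 12, PCaa 200,
  PCae 120, lysoPC 80, SM 60, H1 8000 pmol/mg) with lognormal spread
  (σ = 0.8 across metabolites, 0.3 across tissues), sized against the
  panel's placeholder LODs so that acylcarnitines are partially censored
  and lipids are heavily censored in buffer.  Taurine is fixed at
  40 000 pmol/mg in brain, bone, liver, lung, muscle, kidney, and ovary —
  far above its 1000 µM ULOQ in the extract — and 3000 elsewhere.
* **Crosstalk**: every metabolite with a formula and a shifted ISTD leaks
  `k · conc · p_shift` counts onto its ISTD channel (k = 3000 counts/µM).
  With the default panel only taurine (+2 Da ISTD) produces a visible
  effect — a > 300% ISTD enhancement in the taurine-rich tissues at both
  ratios, while plasma-level analytes contribute under 10% — so the artifact
  emerges from the isotope arithmetic rather than being special-cased.

The same seed yields a bit-identical dataset (a single RNG consumed in fixed
order).  What the generator does **not** emulate: calibration-curve fitting
and raw spectra, derivatization chemistry, between-plate and batch effects,
correlated metabolite panels, drift within a run, and region-specific tissue
heterogeneity.  Passing tests therefore demonstrate the *pipeline's*
correctness under the assumed noise model, not the behavior of any real
instrument or tissue.

## The shipped panel fixture

`data/default_panel.csv` is a synthetic fixture, not vendor data: real
analyte names where publicly standard (the amino acids, taurine, sarcosine,
acylcarnitine chain names, lipid species nomenclature), placeholder
LOD/LLOQ/ULOQ values (class-level bases with deterministic lognormal jitter,
documented in `scripts/make_default_panel.py`), elemental formulas for the
LC analytes, and an ISTD map with 13 shared FIA ISTDs, one hexose ISTD, and
per-analyte labeled LC ISTDs (+3 Da labels; +2 Da for taurine, the spacing
that creates the crosstalk channel).

## Numerical choices and degenerate inputs

Quantiles: numpy's default linear interpolation (type 7).  CV: ddof = 1.
Fractions below threshold: strict inequality.  Efficiency and matrix-effect
ratios with a missing denominator (ISTD absent from plasma wells) yield NA
with a logged warning rather than an error; a solvent with no zero samples
is an error naming the solvent, since the efficiency anchor is undefined.
Conditions with one replicate are skipped from CVs with a warning.  Ties in
recommendation sorting use a stable mergesort over explicitly ordered keys,
so results are row-order invariant.  Below-LOD input cells may be numeric or
censored codes (`<LOD`, `ND`, ...): both are accepted, kept missing, and
flagged.

## Problem sizes

The default study is one plate: 420 wells (396 tissue extracts + 9 zeros +
5 plasma + 3 QC + 7 calibrators) × 188 metabolites ≈ 79 000 measurements;
the full evaluation runs in seconds.  The suppression-recovery experiment
uses 1000 replicates of one tissue (≈ 1.1 M measurements).  The acceptance
script completes in well under a minute.

## Known limitations

* Placeholder panel limits and class-level synthetic parameters are
  calibrated for realistic *structure* (censoring patterns, CV bands,
  suppression ranges), not for any specific tissue's absolute values.
* The recommendation rule is this package's operationalization of a verbal
  criterion; different weightings can change winners in close calls, which
  is why sub-scores and runner-up margins are always reported.
* Matrix effects are quantified, never corrected for: no concentration
  adjustment is applied to suppressed analytes.
* The LC ISTD map assigns one labeled standard per analyte with an assumed
  label shift; real kits' label compositions are proprietary, and only the
  2-Da taurine spacing is load-bearing.
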