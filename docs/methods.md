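# Methods

`corefuc` implements the quantitative analysis stack used to characterize
acceptor-substrate preferences of FUT8, the α1,6-fucosyltransferase that
installs core fucose on N-glycans. Five stages cover the measurement types
such a study produces: GDP-release enzyme kinetics, isothermal titration
calorimetry (ITC), STD-NMR epitope mapping, NOESY-derived inter-proton
distances, and site-specific glycopeptide quantification by LC–MS precursor
features. Every stage has a paired synthetic-data generator with known
ground truth, so each fitting procedure is validated by parameter recovery.

## Enzyme kinetics (`corefuc.kinetics`)

A GDP-Glo-style assay reads out the GDP released per transfer event as
luminescence. The analysis chain is:

1. **Calibration** — ordinary least squares on a GDP standard curve
   (luminescence vs pmol GDP); the inverse map converts assay readings to
   product amounts.
2. **Hydrolysis correction** — the enzyme slowly hydrolyzes GDP-Fuc without
   an acceptor; the mean no-acceptor blank is subtracted before conversion.
   Negative corrected amounts (noise at low signal) are clipped to zero with
   a warning.
3. **Velocity conversion** — product (pmol) / (incubation time × enzyme
   mass) in nmol·min⁻¹·mg⁻¹. The enzyme mass comes from its concentration
   (default 100 nM), reaction volume (default 10 μL) and molar mass.
4. **Hyperbolic fit** — pooled (not averaged) replicate velocities are fit
   to v = Vmax·S/(Km+S) by nonlinear least squares, initialized at
   Vmax₀ = max v and Km₀ = S at half of Vmax₀ (interpolated). Standard
   errors come from the fit covariance.

kcat is derived as Vmax × M(enzyme) × 10⁻⁶ (per-mg → per-mole); catalytic
efficiency is kcat/Km. The enzyme molar mass is an explicit input
(default 58 000 g/mol, appropriate for FUT8 constructs of this size) because
the per-mg convention is meaningless without it.

**Saturability rule.** Some acceptors (low-/high-mannose glycans) never
saturate the enzyme in the tested range — velocity grows linearly with
concentration and the hyperbola is unidentifiable. The fit declares a
substrate non-saturable when the fitted Km exceeds 5× the maximal tested
concentration or the covariance is unbounded, and then reports no
parameters. This operationalizes a qualitative judgement; the factor 5 is
configurable.

## ITC one-site binding (`corefuc.itc`)

Integrated per-injection heats are fit to the closed-form single-site
(Wiseman) isotherm. The cell heat content after injection i is

    Q_i = n·Mt_i·V0·ΔH·Θ_i,   Θ from the quadratic bound-fraction root,

with cell and syringe concentrations corrected for displaced volume using
the standard fixed-cell expressions (Mt = M0(1−d/2V0)/(1+d/2V0),
Xt = X0(d/V0)/(1+d/2V0)), and per-injection heats by differencing with the
(1 − v/2V0)-type correction. Heats are normalized per mole of injectant
(kcal/mol). Four parameters are fit — n, log₁₀Kd, ΔH and a constant
dilution offset — with multi-start over Kd decades; fitting the dilution
offset replaces a separate blank titration. Kd's standard error is
propagated from log₁₀Kd by the delta method.

Degenerate cases: a flat heat trace, or a fitted |ΔH| below 3× its standard
error, is reported as "no measurable binding" rather than as parameters.
For **low-c titrations** (c = n·[cell]/Kd ≲ 1, the weak binders), n and ΔH
are strongly anti-correlated and only their product is determined; the fit
accepts a fixed n (`fix_n`), the standard constraint in this regime, and the
analysis drivers use it together with a higher-molar-ratio injection
schedule. Parameters from such fits are estimates with wide intervals — at
2 % heat noise the Kd scatter is of the same order as the tens-of-percent
uncertainties typical for published weak-binding constants.

Thermodynamic dissection: ΔG = RT·ln(Kd in molar) with
R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹, T defaulting to 298.15 K; −TΔS = ΔG − ΔH
by construction. The driving-force label is a simple dominance rule: the
favorable (negative) term with the larger magnitude names the profile
(enthalpy-driven / entropy-driven), anything else is mixed. The thresholds
are definitional, not fitted.

## STD-NMR epitope mapping (`corefuc.std`)

Each ligand proton's STD amplitude vs saturation time follows
STD(t) = STDmax·(1 − e^(−ksat·t)). The epitope map uses the **build-up
rate** STDmax·ksat (the initial slope) rather than any single-time STD
value, which removes the bias from unequal T1 relaxation across protons.
Rates are normalized to the strongest proton = 100 %; larger values mean
closer approach to the protein surface. Overlapping resonances are combined
pointwise before fitting — summation by default, averaging as an option.
Series with no growth are flagged null and excluded from the map (an all-null
condition is an error). Comparing ± GDP maps reports per-proton raw-rate
ratios and normalized deltas plus a flag that fires when every shared proton
increases. Scale equivariance (amplitudes ×c ⇒ STDmax ×c, ksat unchanged)
guarantees the map is invariant to spectrometer scaling.

## NOESY / ISPA distances (`corefuc.noesy`)

In the initial-rate regime the NOESY cross-peak build-up is linear in mixing
time with slope ∝ r⁻⁶. The "linear initial part" is selected automatically
as the largest prefix of mixing times whose OLS fit has R² ≥ 0.99 (≥ 3
points; threshold configurable), and the isolated spin pair approximation
converts slopes to distances against a reference pair of known separation:
r = r_ref·(σ_ref/σ)^(1/6). Reference distances are *inputs* (e.g. an
intra-ring pair whose distance is known from simulation or ideal geometry);
the module never computes them. The glycosidic ψ conformer call compares
each measured distance with user-supplied syn/anti expectations: per-pair
nearest-expectation votes, unanimity decides, any pair farther than a
tolerance (default 0.5 Å) from both expectations — or a split vote — yields
"ambiguous".

## Glycopeptide compositions and site reports (`corefuc.glycoms`)

Precursor features (m/z, charge, intensity) are converted to neutral masses
(m/z·z − z·1.0072765) and decomposed over monosaccharide building blocks on
top of candidate peptide backbones: Hex 162.05282, HexNAc 203.07937,
dHex 146.05791, NeuAc 291.09542, phosphate (HPO₃) 79.96633 Da. The search
is an exhaustive bounded depth-first enumeration with branch-and-bound
pruning on the remaining mass, complete and sound within the count bounds
(defaults Hex ≤ 9, HexNAc ≤ 7, dHex ≤ 2, NeuAc ≤ 4, phosphate ≤ 2 — broad
N-glycan biology, configurable). ppm error is computed against the
theoretical mass; candidates are ranked by |ppm| with lexicographic
composition tie-breaks, so results are fully deterministic. The default
tolerance is 5 ppm. Only compositions are assigned — isobaric structures
cannot be distinguished at the precursor level, so structure names are
annotation pass-through.

Glycosite peptides are recognized by the +0.98402 Da Asn→Asp deamidation
left by PNGase F: a peptide whose deamidated yield rises more than a fold
threshold (default 2) after treatment is flagged as a glycosite carrier.

Per-site quantification ranks a site's assigned features by intensity,
takes the top N (default 5) as the denominator, sums intensities per
composition, and reports glycoform fractions plus the core-fucosylated
fraction (share of compositions with ≥ 1 dHex). Fractions over the reported
glycoforms sum to 1 by construction.

## Synthetic data (`corefuc.synthetic`)

Generators emulate each input class with known ground truth and a seeded
`numpy` Generator, so identical configurations give byte-identical outputs:

- **Kinetics** — hyperbolic (or deliberately linear) velocities plus a
  constant hydrolysis background, encoded through a linear standard curve
  into luminescence; blanks carry the background alone. Default acceptor
  series 5–1000 μM, duplicates.
- **ITC** — the same Wiseman model as the fitter (the noiseless round trip
  is exact by construction), additive Gaussian heat noise with
  sd = CV × max|heat|, optional dilution offset, default 19 × 2 μL
  injections into a 200 μL cell at 70 μM with 800 μM syringe ligand.
- **STD** — mono-exponential build-ups at saturation times
  0.5–5 s.
- **NOESY** — slopes scaled by (r_ref/r)⁶ from supplied distances; curves
  exactly linear to a window (default 300 ms) then exponentially saturating
  (C1-continuous, damping constant 50 ms), over mixing times 100–1500 ms.
  The sharp post-window curvature makes the auto-window rule well-posed.
- **Glyco-MS** — features at charges {2, 3} (intensity split 70/30), m/z from
  peptide + composition masses with Gaussian ppm error, optional log-normal
  intensity scatter, fractions validated to sum to 1.

Noise is multiplicative Gaussian (CV-parameterized, default 3 %) for
kinetics/STD/NOE intensities — matching the roughly proportional scatter of
optical and integral readouts and keeping values positive at low CV — and
additive in heat units for ITC (2 % of the peak heat in the recovery
studies). The replicate noise magnitude of the emulated instruments is not
documented; the defaults are configurable working values, not claims.

**What the generators do not emulate:** raw thermogram waveforms, spectral
processing (phasing, peak picking, integration of 2D spectra), spin
diffusion, chromatographic peak shapes, isotopologue patterns, co-eluting
interferences, or missing/contaminant features. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
statistical models, not robustness to every artifact of real instrument
data.

## Numerical choices and degenerate inputs

- All nonlinear fits use `scipy.optimize.curve_fit` (trust-region reflective
  with bounds); the Michaelis–Menten fit is cross-checked in the tests
  against a brute-force (Km, Vmax) lattice search.
- The ITC fit multi-starts over Kd ∈ {0.1, 1, 10, 100, 1000} μM and keeps
  the lowest-SSE solution; the mass decomposition enumerates with a node
  budget (default 10⁶) and fails loudly when bounds are too loose.
- Tie-breaks and orderings are deterministic everywhere (lexicographic
  composition vectors; stable groupbys).
- Degenerate inputs are first-class: all-zero heats, flat STD series,
  all-zero NOE integrals, empty candidate peptide lists and bare-peptide
  masses all return defined results or explicit flags rather than crashing.

## Problem sizes

The simulation studies use 8 acceptor concentrations × 2 replicates for
kinetics (200 seeds in the recovery study), 19–30 injections per titration
(50 seeds at 2 % noise), 7 saturation times × 5 protons for STD, 10 mixing
times × 3 pairs for NOESY (50 seeds at 2 % noise), and 3 glycosites × 2
glycoforms × 2 charge states for the feature tables. These sizes mirror the
emulated experiments themselves.

## Known limitations

- Single-site ITC only; no displacement, sequential or multi-site models.
- No Kd estimation from STD titrations, and no full relaxation-matrix
  (CORCEMA-style) STD modeling.
- ISPA ignores spin diffusion; distances inherit the reference pair's
  accuracy.
- Glycopeptide assignment has no MS/MS scoring or FDR control; identical
  compositions from isobaric structures are indistinguishable by design.
- The deamidation-based glycosite detector assumes spontaneous deamidation
  is comparable before/after treatment; heavy in-source deamidation would
  need the fold threshold raised.
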