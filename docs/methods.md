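# Methods

## The model

The package implements, entirely in silico, a molecular "genetic decoder":
a DNA strand-displacement circuit that reads a diploid genotype and reports
its phenotype class as a fluorescence pattern. The computation is a linear
classifier executed by chemistry:

1. **Genetic code.** A panel of biallelic loci defines two alleles per
   locus. A diploid sample is encoded as a binary vector x with one bit per
   allele: 1 if at least one chromosome carries the allele, 0 otherwise. A
   heterozygous locus sets both of its bits, a homozygous locus exactly one.

2. **Weighted sums.** Each allele i carries a signed weight w_i (in 1×
   concentration units). The circuit computes two non-negative sums,
   X = Σ max(w_i, 0) x_i and Y = Σ max(−w_i, 0) x_i, and their difference
   net = X − Y by molecular subtraction. Phenotype classes are ordered
   intervals on the net axis, separated by comparator boundaries θ (for the
   CYP2C19 panel: poor < −2 < intermediate < 0 < extensive < 4 <
   ultrarapid).

3. **Readout.** Comparator channels report the sign of the net score (VIC:
   net < 0, Cy5: net > 0) and its magnitude against the boundaries (FAM:
   net < −2, ROX: net > 4). A channel is ON when its normalised
   fluorescence exceeds 0.4 RFU; the ON/OFF 4-tuple is decoded to a class
   by a small rule table.

## Weight learning

`learn_coefficients` finds w by linear programming: one two-sided
inequality per genotype (its score must sit inside its class interval with
at least the margin's clearance), weight bound |w_i| ≤ 8, objective
minimise Σ|w_i| (total gate material). The LP solution is snapped to the
coarsest rational grid (denominators 1, 2, 4, 8) that preserves
feasibility, so weights are realisable as pipetted gate concentrations; if
snapping fails, a bounded integer program (`scipy.optimize.milp`) is the
exact fallback. Every returned array is re-verified by exhaustive score
enumeration; infeasibility is reported with a minimal conflicting genotype
pair when two identical codes carry different labels.

The default margin of 0.5 (1× units) is the largest value the 4-class
CYP2C19 geometry admits with boundaries (−2, 0, 4): the two intermediate
genotype scores must differ by the *17 allele's weight inside an interval
of width 2, which forces the margin to at most 0.5.

## Circuit compilation

Weights become gates (1× = 10 nM for pharmacogene circuits, 50 nM for
polygenic-score circuits):

* multiplication (seesaw) gate per nonzero-weight allele at |w_i| × base,
  with fuel at 2× the gate. Catalysis regenerates the input, so the
  *gate*, not the input, sets the released output — this is what makes
  the multiplication coefficient definitive despite variable ligation
  yields.
* summation gates (1.5× the attainable branch sum) converting weighted
  outputs into the common species X and Y.
* a cooperative-hybridization subtraction gate: X binds reversibly, a
  second arm captures Y irreversibly, annihilating X and Y one-for-one.
  Sized at 4× the attainable min(X, Y): a large excess keeps the
  singly-bound intermediate pool high, which is what makes annihilation
  much faster than the competing transformation leak.
* per comparator channel, one truncated-toehold transformation gate
  converting the leftover into that channel's H species. The gates on one
  side are identical, so they split the leftover into exact equal shares;
  each channel thresholds its own copy at level/n. This per-channel copy
  is the package's resolution of a structural conflict: with a single
  shared H, a presence channel ("H > 0") and a level channel ("H > 2")
  cannot coexist, because the level threshold (necessarily fast) absorbs
  sub-threshold H before a slow reporter can fire, while a reporter fast
  enough to catch transient H also fires on leak.
* extended-toehold threshold gates absorb each channel's H up to its
  comparator level. Presence channels carry a small deadband threshold
  (0.35× base / n) that swallows circuit leak — "net < 0" is read as "net
  beyond the noise floor".
* slow catalytic reporters (restoration gates) release one fluorophore per
  event and restore H, so reporting integrates H exposure without
  perturbing the arithmetic. RFU is normalised per channel between the
  no-input baseline (0) and full reporter turnover (1).

The dual-gene dosing circuit runs two weighted-sum branches in parallel
(per-gene presence and severity channels on the negative side) and pools
the positive leftovers into a collective comparator; the normal dose
requires both branches positive *and* the collective channel ON. The
polygenic-score circuit uses the literal ternary encoding (below) with one
effect-allele and one other-allele gate per variant.

## Kinetics

Gates expand into at-most-bimolecular mass-action reactions integrated
with a stiff BDF solver (analytic Jacobian, rtol 1e-8, atol 1e-6 nM,
output every 120 s, 2.5 h endpoint for pharmacogene circuits and 4 h for
polygenic-score circuits). Strand-composition bookkeeping is attached to
every species; each reaction is checked for per-strand balance at build
time and total material is asserted conserved to < 1e-6 relative along
every trajectory.

Rate constants are model parameters — no kinetic rates are reported for
the original chemistry — chosen once, by timescale analysis, to realise
the designed ordering (threshold ≫ transformation; subtraction ≫
transformation; threshold ≫ reporter):

| parameter | default | unit |
| --- | --- | --- |
| standard toehold (7 nt) | 1.0e6 | M⁻¹s⁻¹ |
| truncated toehold (5 nt) | 3.75e3 | M⁻¹s⁻¹ |
| extended toehold (9 nt) | 6.0e6 | M⁻¹s⁻¹ |
| cooperative second-arm capture | 1.0e7 | M⁻¹s⁻¹ |
| catalytic reporter | 3.5e5 | M⁻¹s⁻¹ |
| subtraction intermediate dissociation | 0.25 | s⁻¹ |
| global leak | 0 | s⁻¹ |

Three numerical trade-offs fixed these values. (i) The subtraction
intermediate must dissociate fast enough that a lone leftover X is not
sequestered away from the transformation stage, yet bind strongly enough
that annihilation outruns transformation — 0.25 s⁻¹ with a 4× gate excess
and a fast second-arm capture satisfies both, leaving < 2% of full scale
in the wrong H channel across the whole (X₀, Y₀) grid. (ii) The
transformation stage is bimolecular in two depleting species; a 4× gate
excess at a proportionally slower rate keeps the bulk flux (and hence the
annihilation leak) unchanged while removing the late-time stall that
otherwise starves the above-threshold channels. (iii) The reporter rate
3.5e5 is the intersection of the OFF-state bound (RFU < 0.1 at 0.8× a
threshold fed through a production stage) and the ON margins of the
round-trip decoding at the ligation-efficiency extremes.

## LDR front end

The ligase-dependent reaction is modelled as an endpoint yield: a present
allele produces linked primer at P·e (efficiency e, default 0.45, the
middle of the measured 0.35–0.64 range; P = 10 nM per pair), an absent
allele at P·c. A per-cycle linear-accumulation variant (template-limited,
capped by primer supply) is provided for sensitivity analysis, and
per-allele efficiencies can be jittered over [0.35, 0.64] from a seeded
RNG keyed by sample id (so cohort order never affects a call).

The cross-ligation default is c = 1e-4, deliberately far below the
measured *upper bound* of 2.1%: a seesaw gate integrates any persistent
input, so a spurious linked primer at 0.1% of 10 nM would displace most
of its gate within 2.5 h and corrupt both branch sums. The default is
therefore an operating point for the functional cross-activation, not the
gel-quantified ligation bound; the presence-channel deadbands absorb the
residual leak. Cross-ligated product is treated as fully functional
(worst case). Rare-allele enrichment is a pure fold-change stub on the
variant allele fraction (clipped at 1), with no amplification chemistry.

## Polygenic scores

PRS_s = Σ_v d_{s,v}·lnOR_v over a scoring model parsed from catalog-layout
text ('#' metadata, tab-separated body; OR columns are log-converted). The
molecular *literal* encoding maps the ternary dosage onto binary inputs:
effect-allele gate at 2·lnOR·100 nM (to X), other-allele gate at
lnOR·100 nM (to Y), so homozygotes contribute 2·lnOR, heterozygotes lnOR
and non-carriers −lnOR. The circuit's net therefore equals
PRS − Σ_{d=0} lnOR — an exact, documented offset that is surfaced in every
report rather than hidden. The `exact_dosage` alternative uses
stoichiometric (fuel-less) gates with dosage-scaled inputs and reproduces
the PRS without offset. Cohorts are simulated under Hardy–Weinberg
equilibrium (dosage ~ Binomial(2, p) per variant, seeded); risk categories
are rank-based deciles — bottom decile low, top decile high, everything
strictly between intermediate, so the categories partition the cohort.

## What the synthetic data does and does not show

The genotype–phenotype tables are reconstructions of standard clinical
correlations (CPIC-style activity scoring) over small star-allele panels:
CYP2C19 (10 diplotypes over *1/*2/*3/*17; *1/*17 is classed ultrarapid
per the classic 4-class convention, *2/*17 intermediate and configurable),
DPYD (30 genotypes over 7 SNPs), TPMT and NUDT15. The 22-variant scoring
model is a *seeded synthetic stand-in* with effect sizes in plausible GWAS
ranges, not a real catalog accession, so its cohort mean and spread are
properties of the synthetic draw, not of any published score. Passing
tests demonstrate that the decoding architecture is sound under the
modelled chemistry; they do not validate ligase fidelity, secondary
structure, pipetting error, or any other wet-lab failure mode, and no
human-sample concordance is claimed. Problem sizes (5×5 concentration
grids, 10–30 genotype cohorts, 2504-sample synthetic populations, 3
simulated PRS circuit samples) were chosen to exercise every pathway at
full fidelity with second-scale integration times.

## Known limitations

* Multi-threshold comparators beyond one negative and one positive
  boundary are not compiled.
* The unlinked-primer pathway is modelled as strictly zero-rate; the
  global leak parameter exists for leak studies but defaults to 0.
* Sequence design is composition-level only: no nearest-neighbor
  thermodynamics, no secondary-structure screening; the melting
  temperature estimate is an advisory Wallace-type heuristic.
* Stochastic (SSA) simulation and temperature dependence are out of scope.
* Haplotype phasing, copy-number star alleles and multi-allelic sites are
  not represented.
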