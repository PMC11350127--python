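# Methods

This note records the models behind each stage, the defaults and why they
were chosen, and the places where the design was genuinely open.

## Panel algebra

Genotypes are length-`n` vectors of whole-chromosome origins with the
indicator coding L*er* → 0, Col → 1, so fitted coefficients are directly
the effect of substituting a Col chromosome into an otherwise fixed
genotype.  A (−½, +½) effect coding would orthogonalise the factorial but
re-parameterise every coefficient; the 0/1 coding was kept because it is
the parameterisation in which the decomposition's effects are usually
reported.  Panels enumerate lexicographically (chromosome 1 most
significant, L*er* < Col) — a reproducibility choice only.  Design-matrix
interaction columns are exact elementwise products of their parent
main-effect columns, so marginality is a structural property of the
matrix, not a bookkeeping convention.  `n` is a parameter (default 5,
bounded at 20): panels for species with 7–12 chromosomes are representable
but rapidly large.

## Breeding simulator

Achiasmatic gametes draw each chromosome independently with
P(Col) = ½ — the defining property of reverse breeding — so a specific CSL
appears with probability 2⁻ⁿ and panel completion is a coupon-collector
process.  The simulator reports observed completeness; the
inclusion–exclusion closed form Σⱼ(−1)ʲC(K,j)(1−j/K)ᴺ serves as the
independent oracle in the tests.  A practical finding worth noting: at
n = 5 the common ~3·2ⁿ sizing (96 DH lines) completes the panel only
~18.5% of the time; the last genotypes are normally obtained by targeted
crosses.

Recombinant meiosis uses the Haldane model — crossover counts Poisson in
map length, positions uniform, no interference — because it gives
closed-form recombination fractions to test against; interference (e.g.
Kosambi) is a documented non-default gap.  NIL panels are DH gametes of an
sCSL × recurrent-parent F1: only the substituted chromosome segregates,
and injected crossover positions are recorded per line so boundary
detection can be validated against the truth.

RILs are simulated by *explicit repeated selfing* (default 10
generations): each generation performs two exact Haldane meioses per line,
vectorised as Markov phase chains over marker loci (exact for a single
meiosis because the Poisson crossover process has independent increments).
A cheaper single-step shortcut — adjacent-marker flips with the selfing
expansion R = 2c/(1+2c) — reproduces pairwise recombination exactly but
decorrelates distant markers too fast (Π(1−2Rⱼ) instead of 1−2R(d)), which
measurably distorts genome-wide multiple-testing calibration; the explicit
simulation costs essentially the same and was therefore preferred.
Residual heterozygosity after 10 generations (~0.1%/locus) is resolved by
reporting one haplotype.

The default marker map is Arabidopsis-like: five chromosomes of
120/85/95/90/110 cM, markers every 5 cM, physical scale 250 kb/cM
(~2.5 Mbp per 5 cM, matching typical SNP-set resolution).

## Phenotype simulator

The generator emulates the study design the statistics assume: 32 CSLs ×
12 replicates grown with 100 RILs × 3 replicates on a 12×60 grid split
into three complete blocks of 12×20 (4 CSL replicates and 1 RIL replicate
per block; 684 of 720 positions filled).  Trait values are the factorial
effect model plus N(0, σ_b²) block effects, a smooth environmental
surface, and N(0, σ_e²) plant noise.  The surface is a sum of low-frequency
2-D cosines (≤1 cycle across the field) rescaled to a requested standard
deviation, plus optional independent row/column offsets, centred to zero
mean — smooth structure of the kind fertility or microclimate gradients
produce, and of the kind the adjustment stage claims to remove.

Default effect models: flowering time (days) with a dominant chromosome-5
main effect (−6 d) and two-way epistasis among chromosomes 1/3/5,
σ_e = 2 d; main stem length (mm) with a strong chromosome-2 effect
(+60 mm), four two-way terms, a 40 mm three-way term among chromosomes
1/2/5, σ_e = 15 mm.  These are calibrated qualitatively — effect-to-noise
ratios that make a 12-replicate experiment decisively informative without
being trivial — not to any measured dataset.

What the generator does **not** emulate: heavy-tailed or heteroscedastic
noise, germination-date correction, outlier plants, genetic correlation
between traits, segregation distortion, or residual transgene effects.
Passing tests therefore demonstrate correctness of the machinery under the
stated statistical model, not robustness to every field pathology.

## Spatial adjustment

The mixed model is

y = mean + population + block + f(row, col)  [fixed]
  + row + column + genotype-within-population + e  [random]

with `f` a centred tensor-polynomial surface (total degree 3 by default)
and a separate genotype variance per population (heterogeneous genetic
variances, e.g. CSL vs RIL).  Block and surface columns are centred so
the fitted environmental part has zero mean over the plants by
construction.  REML is computed by profiling through the Woodbury
identity (cost O(q³) in the ~200 random levels), optimised over
log-variances by L-BFGS-B with restarts.  Numerical choices that matter:

- the residual variance is floored at var(y)·e⁻¹⁰; letting it collapse
  makes the Woodbury solves catastrophically ill-conditioned and the
  objective value meaningless;
- after optimisation, any variance component whose removal does not
  worsen the objective is snapped to zero (parsimony polish) — with
  noise-free data the profile is flat there and the minimal solution is
  preferred;
- if the residual lands on its floor the data were (numerically)
  noise-free, and the BLUP system is re-solved at a much smaller residual
  so corrected values honour the exact fit.

Outputs are routed as the downstream stages expect: plant-level corrected
values (raw minus fitted environment, genotype signal retained) feed the
epistasis decomposition — individual values are preferred over line means
there to keep residual degrees of freedom — while BLUP-shrunken line
means feed the linkage scans.  This stand-in is *a* principled spatial
correction with testable behaviour (surface recovery r ≥ 0.9 at default
settings; variance-component median bias < 15% over 200 reduced-layout
simulations of 16 genotypes × 6 replicates, a size chosen to keep the
property test cheap); it is not a reimplementation of any specific
P-spline package, and no numeric equivalence to one is claimed.

## Epistasis decomposition

OLS on plant-level corrected values; all models are compared by partial
F-tests (for single-column terms, equivalently the squared t).  The
cascade: (1) from the saturated-to-order-3 model, drop the least
significant three-way term while its p-value exceeds α₃ = 5·10⁻⁵
(stringent to correct for the ten candidate terms), refitting after each
drop; (2) the same over two-way terms not nested under a surviving
three-way term, at α₂ = 5·10⁻⁵; (3) prune unprotected main effects (same
α — the stage-3 threshold is not separately standardised anywhere, so the
stage-2 value is reused), then test the final model against the
intercept-only model.  An information-criterion variant of the drop rule
was considered and rejected as the default because an α-threshold rule is
what the reported thresholds parameterise; the F-test rule is what the
calibration tests certify.  Ties in the least-significant term break
toward keeping the larger |t|, then by name — the elimination path is
fully deterministic.  Two-way terms protected by marginality are retained
without testing (a test-then-restore variant would select identical sets
whenever the protected terms' parents survive, but protection is the
cleaner contract).

Effect-plot class means are model predictions at the mean design row of
the panel genotypes in each corner class of the interaction, with
delta-method 95% CIs; on the complete balanced panel this equals the
model-implied class mean.

Calibration under the default generator (σ known, 12 replicates): the
null rate of selecting any three-way term is ≪ 0.5%; an injected
three-way effect of 4σ is recovered as exactly its term in >95% of runs;
the chromosome-by-background test at α = 10⁻³ keeps false interaction
selection ≤1% and detects c_k = 5σ with >95% power.  Stage-wise backward
elimination agrees with brute-force all-subsets selection (same per-term α
rule, maximal admissible subset, RSS tie-break) on n = 3 panels.

## Linkage mapping

Composite interval mapping in its regression (Haley–Knott) form on
genotype-level values: expected Col dosages on a ≤5 cM grid (conditional
expectations given flanking markers under the selfing-RIL Markov chain;
ends extrapolate from the nearest marker), per-position F-tests of the
dosage term with cofactor dosages included except within 50 cM of the
tested position, peaks above threshold subject to 30 cM minimum
separation, iterated to a stable cofactor set.  Because the exclusion
window lets shadow peaks linked to a true QTL reach the threshold, the
final QTL set is backward-eliminated once in a joint multiple-QTL model
(all called QTLs as simultaneous predictors, no window); this is the
standard final pruning step and removes window artefacts without touching
genuine secondary QTLs.  Effects are signed +Col / +L*er* by the
regression coefficient.  Support intervals take the contiguous region
within 2 units of the −log10(p) peak, mapped to bp by piecewise-linear
interpolation on the marker map.

Genome-wide thresholds use the Li–Ji effective number of tests: per
chromosome, M_eff = Σᵢ[I(λᵢ≥1) + (λᵢ−⌊λᵢ⌋)] over marker-correlation
eigenvalues, summed across chromosomes (a whole-genome-matrix option is
available), then Šidák α_p = 1−(1−α)^(1/M_eff).

**Known limitation.** At 5 cM RIL marker density the Li–Ji M_eff (~50 for
105 markers; 52 from the exact population correlation matrix) understates
the effective number of tests implied by the null maximum (~90): the
eigenvalue rule grants no reduction to marker pairs until their
correlation reaches 1, yet still undercounts AR-like chains.  The
realised genome-wide error of the α = 0.05 threshold is therefore ~6–8%
rather than 5% in 500-scan null calibrations (for comparison, Bonferroni
on the raw marker count gives ~4%).  The method is implemented exactly as
specified and the calibration test records this behaviour; users wanting
strict 5% control at this density should lower α or use the raw marker
count.

NIL fine-mapping regresses the phenotype on the local introgression
dosage marker-by-marker within each recurrent background (monomorphic
markers are flagged, not tested), thresholds per chromosome by the same
Li–Ji rule, and reports heatmap-ready effect/significance tables with
drop-2 support intervals; reciprocal panels expose background-dependent
effect signs directly.

## Pipeline and reproducibility

All randomness flows through one seeded `numpy` generator per entry
point; identical seeds give byte-identical panels, layouts and reports.
Every pipeline artefact carries the configuration hash; a JSONL trace
records each elimination step and model comparison so the selection path
can be audited.  Problem sizes in the test suite (e.g. 500 null / 200
power simulations, 100-RIL scans, reduced layouts for the REML bias
check) are the package's calibration choices, balancing Monte-Carlo
resolution against suite runtime.
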