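# Methods

## Scope and structure

`dsbrepair` predicts clonogenic survival and chromosome-aberration yields
from the fate of radiation-induced DNA double-strand breaks (DSBs). The
pipeline has four stages: induction (dose → expected break count), repair
(pathway assignment, kinetics, fidelity), spatial misrepair (competition
between correct rejoining and binary misrejoining of free ends), and
outcome (aberration classes → death routes → survival, LQ summaries, MID,
D10, RBE). Charged particles modify exactly one ingredient — the spatial
clustering of breaks, expressed as an intra-track interaction rate — via a
single energy parameter `e_dsb`.

All arithmetic is expectation-level: break complexities, pathway choices
and fidelities enter as fractions, not per-break random draws, and damage
yields are treated as Poisson means when converted to survival. The only
discreteness retained is the number of ion traversals at high LET, where
per-cell fluctuations genuinely reshape the dose response.

## Parameters

Shared constants (`ModelParameters`), none cell-line specific:

| parameter | default | units | role |
|---|---|---|---|
| `dsb_yield` | 5.738 | DSB Gy⁻¹ Gbp⁻¹ | break induction per DNA content |
| `lambda_fast` / `lambda_slow` / `lambda_mmej` | 3.6 / 0.15 / 0.0084 | h⁻¹ | NHEJ / HR / MMEJ repair rates |
| `p_complex` | 0.42 | — | fraction of breaks that are complex |
| `p_fail` | 0.67 | — | defective-pathway failure → MMEJ |
| `sigma_rel` | 0.0428 | R_nuc | misrejoining range / nuclear radius |
| `mu_nhej` / `mu_hr` / `mu_mmej` | 0.985 / 1.0 / 0.445 | — | pathway fidelities |
| `mitotic_sensitivity` | 0.014 | break⁻¹ | mitotic-catastrophe rate (G2/M) |
| `apoptotic_sensitivity` | 0.0085 | break⁻¹ | G1 arrest/apoptosis rate |
| `e_dsb` | 60.7 | keV | energy per DSB; sets nuclear geometry |
| `deletion_threshold` | 3×10⁶ | bp | lethal-deletion size cut |
| `p_asym` | 0.5 | — | asymmetric-rejoining probability |
| `track_poisson_threshold` | 0.5 | DSB/track | switch to discrete track averaging |
| `async_g1_weight` | 2/3 | — | G1 share of asynchronous populations |

Two source conventions disagree on details; the package binds them as
follows. The mitotic and apoptotic sensitivities are bound by *semantic
role* to 0.014 and 0.0085 break⁻¹ respectively (the symbols ψ and φ are
attached inconsistently to these roles in different places in the
literature parameterisation). The MMEJ fidelity is 0.445 by default with
the tabulated alternative 0.465 available as
`ModelParameters.with_table_mmej()`.

Cell phenotypes (`CellPhenotype`) carry: total unreplicated DNA content in
Gbp (`genome_gbp`, 6.1 for diploid human — chosen so the default yield
reproduces 35 DSB/Gy; doubled internally for G2/M), chromosome count,
binary NHEJ/HR competence, binary G1-arrest competence, and cell-cycle
phase. Bundled fixtures provide a generic human line and Chinese-hamster
style lines (4.7 Gbp, 21 chromosomes, arrest-deficient, with
NHEJ- and HR-deficient variants); hamster genome values are representative
and should be overridden per line where known. Graded (partial) repair
capacity is out of scope.

## Nuclear geometry from `e_dsb`

Requiring that 1 Gy (= 6.242 keV/µm³ in water) produces 35 DSBs in a human
nucleus gives V_nuc = 5.61 `e_dsb` µm³ and r_nuc = 1.1 `e_dsb`^⅓ µm; the
two printed constants are consistent to <1% and both are exposed. The
misrejoining range is σ = `sigma_rel` · r_nuc (≈185 nm at the default
`e_dsb`).

## Spatial misrepair

Free ends at separation d interact at ζ(d) = exp(−d²/2σ²), normalised to
ζ(0) = 1 so that the self-pair (correct rejoin) defines the unit rate and
P_correct = μ(1−e^−η)/η holds with no extra constant. For N uniform breaks
in the spherical nucleus the competing rate is η = (N−1)·θ(R,σ), with
θ the mean of 2ζ over uniform point pairs, evaluated by adaptive quadrature
over the analytic pair-distance density f(s) = 3s²/R³ − 9s³/4R⁴ + 3s⁵/16R⁶.
θ is scale-invariant and validated against ≥10⁶-pair Monte-Carlo sampling
in the test suite; the restricted variant θ(R,σ,r_max) truncates the same
integral at r_max.

Chromosomes are equal spherical territories of radius r_c = R·n_c^(−1/3).
The intra-chromosome probability is implemented as

    P_intra = θ(r_c, σ) / (n_c · θ(R, σ))

i.e. the within-territory pair rate weighted by the 1/n_c share of breaks
in one territory, relative to the whole-nucleus rate. The 1/n_c weight is
required for P_intra to be a probability: without it the ratio evaluates to
≈ n_c at the model's σ/R, and the large-σ limit gives 1 instead of the
random-partner value 1/n_c. Both limits behave correctly in this form
(n_c = 1 → 1; σ ≫ R → 1/n_c).

Deletion sizes map to separation through D = 2L·r_D³/R³ with L the
phase-appropriate total DNA length in bp and R the *nuclear* radius (kept
as stated in the source formulation even though deletions are
intra-chromosomal). P_del<D = θ(r_c,σ,r_D)/θ(r_c,σ), clamped to 1 when
r_D exceeds the territory diameter.

The inter-arm probability treats each chromosome as one arm pair around a
central centromere, l_c = L/n_c. A break at genomic distance b from the
centromere spans it when its partner lies further than b away:
P_interArm(b) = P_del>b. The package averages over break position,

    P_interArm = (2/l_c) ∫₀^{l_c/2} P_del>b db,

which keeps the quantity a probability conditional on an intra-chromosome
event (the source's printed prefactor l_c/L carries units of base pairs and
cannot be one). The integral uses Simpson quadrature on a cubic-power grid
clustered near b = 0 (257 nodes; doubling changes the value by <0.1%), with
P_del<b read from a cached cumulative-trapezoid table of the restricted
pair rate (4001 nodes).

## Repair pathways

Simple breaks use NHEJ in all phases; complex breaks use NHEJ in G1 and HR
after replication. A break whose assigned pathway is defective fails over
to MMEJ with probability `p_fail`; the remaining fraction is rejoined by
NHEJ machinery with NHEJ kinetics and fidelity — also when NHEJ itself is
the defective pathway, a deliberate reading of an underspecified corner
(the defect is expressed through the failed fraction, not through a fidelity
penalty on the residue). Repair kinetics N(t) are the tri-exponential sum
of pathway fractions; they are exposed as a standalone endpoint
(`repair-curve`, `remaining_dsbs`) and feed survival only through the
optional replating-delay decay of the apoptosis-relevant break count —
for single-fraction acute exposures they do not otherwise affect late
outcomes.

## Survival

G1: S = exp(−N_dic − N_del>D), with the apoptotic factor exp(−φ·N_G1)
applied only in G1-arrest-competent lines (N_G1 is the initial break count,
decayed through N(t) when a replating delay is given). G2/M:
S = exp(−N_dic − N_interArm)·exp(−ψ·N_m) with N_m the initial count;
double-deletion lethality in G2 is neglected. Apoptosis is tied to G1
irradiation only. Asynchronous populations are mixed 2:1 G1:G2.

LQ parameters come from non-negative least squares on ln S over a 0–10 Gy
grid in 0.5 Gy steps (equal weights, β ≥ 0 enforced — high-LET curves are
genuinely linear and fit with β = 0 exactly). MID uses the erfc closed form
written via `erfcx` for overflow safety, cross-checked against adaptive
quadrature to 10⁻⁶ relative; D10 is the positive root of the LQ equation.
RBE is the ratio of reference to test dose at the D10 or MID endpoint.

## Charged-particle extension

Radial energy profiles (energy per µm of track per annular bin;
logarithmic binning from 0.1 nm, 100 bins per decade, ≈2.33% width growth)
are read from delimited text or produced by the synthetic generator. DSB
densities are E/E_DSB per bin — the conversion is volume-independent.

The DSB separation distribution around an "average" break is built by
(i) coarsening the radial bins to ≤10 nm resolution (resolution is set by
σ ≈ 185 nm, not by the 2.33% scoring bins), (ii) angular discretisation of
each annulus with arc length ≤40 nm — the angular step that resolves pair
distances to the arc scale, since |∂d/∂φ| ≤ min(r_i, r_j) — accumulating a
transverse-distance histogram over annulus pairs weighted by DSB content,
and (iii) convolution with uniform longitudinal offsets out to ±5 µm (ζ at
5 µm is ≈e^−365) on a 5 nm distance grid. Halving all three steps changes
η_track by <0.1%, and the whole construction is validated against an
explicit 3D track simulation (sampled break positions along long tracks) to
within 5% at LET 1–100 keV/µm. η_track = Σ 2ζ(r)·n(r) is per-track,
independent of dose, and adds to the uniform inter-track rate inside
P_correct; aberration classification keeps the uniform-geometry
probabilities (only the total misrepair rate is modified by clustering).

DSBs per traversal are (LET/E_DSB)·chord with the central-axis chord
2·r_nuc by default; the mean chord 4R/3 is available
(`dsb_per_track(..., chord="mean")`) since the dose-to-track-count
conversion for non-central chords is a genuinely open convention. Above
0.5 DSB/track, survival is averaged over a Poisson number of traversals
whose mean delivers the expected total damage, truncating the weight sum at
1−10⁻⁶. After replication both the per-traversal DSB count and η_track are
doubled — a traversal intercepts twice the DNA — which keeps the track
count at a given dose independent of phase. Inter-track break positions
are assumed uncorrelated (uniform), which underestimates survival variance
at very high LET but not the mean.

### Synthetic track generator

The built-in generator is a fixture stand-in for Monte-Carlo transport
output, not a physics model: a constant-dose core (10 nm radius) plus a
1/r² penumbra, matched continuously and normalised exactly to the target
LET, with the penumbra radius taken from a delta-ray-range-like power law
(0.0616·E^1.7 µm, clamped to 0.05–10 µm) and crude LET↔energy power laws
for protons and carbon. It reproduces the qualitative features that drive
the model — a core carrying <25% of the energy for fast particles, tracks
narrowing as particles slow (hence the slightly super-linear η_track–LET
relation) — but not any particular transport code's curves. Quantitative
work should supply measured or simulated profiles through
`read_radial_profile`.

## E_DSB calibration and synthetic datasets

`fit_edsb` minimises Σ(MID_model − MID_obs)² over `e_dsb` for ion records
with registered phenotypes (scipy `least_squares`, bounds 10–300 keV,
standard error from the Jacobian). Because the geometric probabilities are
scale-invariant and the separation distribution is linear in 1/e_dsb, each
objective evaluation reuses cached per-LET track computations, keeping a
50-record fit at a few seconds.

The synthetic dataset generator draws cell lines from the bundled
phenotypes and LETs from a discrete grid of representative beam values
(1–30 keV/µm), mirroring the discrete beam energies of real survival
databases and keeping track computations cacheable. Model α/β are
dose-rescaled by a lognormal factor f with coefficient of variation 0.16 —
the replicate-to-replicate MID variability observed among nominally
identical published experiments — as α/f, β/f², which multiplies MID by
exactly f. Parameter recovery on such data (n = 50, 10% noise, 20 seeds)
is calibrated: estimates scatter around the generating value consistently
with the reported standard errors.

What passing these tests shows — and does not. The generator produces data
exactly under the model's assumptions with clean lognormal noise; recovery
there demonstrates the estimator and pipeline are self-consistent and
unbiased, not that real datasets (with dosimetry offsets, phenotype
misclassification, correlated lab effects and heterogeneous dose ranges)
would yield the same precision.

## Problem sizes and numerical choices

Dose grids use 21 points (0–10 Gy); LET scans use 9 points spanning
2–250 keV/µm with protons below and carbon above 30 keV/µm; Monte-Carlo
oracles use 10⁶ point pairs (θ), 4000 placements (η) and ~3×10⁵ sampled
breaks per LET (η_track), with standard errors taken from independent
replicates because close-pair statistics are heavy-tailed at low LET.
Quadrature tolerances: 10⁻¹⁰ relative for θ; degenerate inputs (zero dose,
zero LET, η → 0, β = 0) all take analytic limits. Survival curves are
clipped to strictly positive values before log-fitting; the LQ fit ignores
the trivially-zero dose-0 point.

## Known limitations

Binary repair phenotypes; no dose-rate or low-energy-photon RBE effects;
no fractionation, hypoxia or 3D/tissue context; single simple/complex
damage dichotomy with LET-independent repair kinetics; misrepair-induced
slowing of repair neglected; mutation endpoints not implemented; spherical
nuclei and equal spherical chromosome territories; inter-track correlations
ignored (mean-level predictions only at extreme LET).
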