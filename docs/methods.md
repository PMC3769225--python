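# Methods

This note documents the models implemented in `allonet`, the choices made
where the design was genuinely open, and what the synthetic generators do
and do not emulate.

## Elastic-network model and allosteric free energy

A protein is reduced to one bead per residue at the C-alpha position. Every
bead pair within an inclusive cutoff Rc is joined by a Hookean spring of
identical stiffness k; the defaults are k = 1 kcal mol⁻¹ Å⁻² and
Rc = 8 Å. Each bound ligand contributes one pseudo-node at the
mass-weighted mean of its atoms, wired by the same cutoff/stiffness rule as
the protein beads (including possible ligand–ligand springs — the minimal
uniform assumption). The apo and singly bound states are obtained by
deleting ligand nodes from the doubly bound network, never by re-solving
the structure: binding acts only through the vibrational spectrum.

The 3N×3N stiffness (Hessian) matrix has off-diagonal 3×3 blocks
−k·(êêᵀ) per spring and diagonal blocks that close each block row to zero,
giving exact translational invariance. All masses are unit: mass prefactors
are state-independent constants that cancel in the balanced free-energy
combination below, and only ratios of fluctuation amplitudes are reported.

For each ligation state the harmonic free energy contributes
S = Σ ln λ_m over the nonzero modes. The allosteric free energy is

    ΔΔG = (RT/2) · (S_holo2 + S_apo − 2 S_holo1),

and the cooperativity ratio of stepwise dissociation constants is
K2/K1 = exp(ΔΔG/RT) with R = 1.987 cal mol⁻¹ K⁻¹ and T = 300 K by default.
ΔΔG > 0 (K2/K1 > 1) is negative cooperativity. With full mode sums the
nonzero-mode counts are 3N, 3N−3 and 3N−6; the +1/−2/+1 weights cancel
them, so unit and mass constants (and any global stiffness rescale) drop
out exactly. The full sum is taken as canonical; truncated sums feed the
convergence profile, whose detector reports the smallest n after which
successive K2/K1 values stay within 1e−4 over 50 consecutive modes. Toy
networks of ~50–120 beads do not reach such a plateau — their top-of-spectrum
modes keep shifting the balance by ~0.03 — so at toy scale the profile is
reported with the unconverged flag and the full-sum value stands; the
plateau behaviour is exercised on engineered spectra whose binding
perturbation is confined to the lowest modes.

Rigid-body modes are identified by count (six for a 3D geometry, five for
collinear ones) after verifying a spectral gap at relative tolerance 1e−9;
a different count raises with a connectivity diagnosis rather than being
silently absorbed. Dense symmetric eigensolves are used throughout — at
desk scale (3N ≲ 1500) exactness beats iterative methods.

Crystal dimers are only approximately C2-symmetric, so the two choices of
which ligand to keep in the singly bound state differ slightly; the
package averages the two S_holo1 log-sums before forming ΔΔG. Ensembles of
structures are combined as the unweighted arithmetic mean of per-structure
K2/K1 with SEM = sd/√n.

## Spring-scanning mutagenesis

A point mutation is emulated by multiplying every spring incident to one
residue — in both chains of the homodimer by default, matching experimental
mutants that carry the change in both monomers — by a dimensionless factor
k_R/k; edits compose multiplicatively and a per-chain or per-pair override
exists. Scanning residues against the factor grid {0.25, 0.5, 1, 2, 4}
yields the cooperativity control map; simultaneous multi-residue edits
support cases where a mutation creates a new contact elsewhere (modelled
as a second edit, e.g. a gained contact stiffened fourfold). Per-contact
scans rescale one spring at a time and report the change in K2/K1 split by
same-monomer versus cross-monomer partners.

Flexibility reports use B = (8π²/3)·msf with msf from the pseudo-inverse
of the Hessian (equivalently the mode sum Σ|v|²/λ); because masses are
unit, only the percentage change versus wild type is scientifically
meaningful. Site-level changes aggregate mean per-residue msf over a named
residue set, then take the square root, comparing RMS amplitudes.

## Super-coarse-grained block model

Each monomer is two blocks (ligand-binding and DNA-binding domain), each
with one internal breathing amplitude b_i; three inter-block relative
displacements u12 (across the interface), u13 and u24 (within each
monomer) complete seven degrees of freedom. The stiffness matrix carries
the printed diagonal constants k1…k4, k12, k13, k24 plus bilinear
breathing–displacement cross-couplings −c·j_e between each displacement
and its two blocks' breathing modes, with j_e fixed at the apo stiffness
of that contact and c a dimensionless geometric coefficient
(default 0.15). Ligand binding multiplies diagonals only: k1 (then k2) by
β, k12 by α per event, k13 (then k24) by γ. Free energies are
(RT/2)·ln det K and ΔΔG uses the same +1/−2/+1 combination; the dimension
is 7 in every state, so global rescales cancel.

Two structural facts forced this geometry and are worth recording. If the
cross terms are written as completed squares — each displacement relaxing
freely against its own spring — the determinant factorizes over the tree
of block contacts and ΔΔG vanishes identically for any binding factors.
And if the cross-couplings scale with the binding factors, a 2×2 reduction
shows det(2)·det(0)/det(1)² = 1 − t(α²/β − 1)² + O(t²) ≤ 1: such a model
can never be anti-cooperative. Fixed geometric coupling with
diagonal-only binding factors is the minimal structure that leaves both
wild-type parameter sets (CAP and GlxR presets) on the anti-cooperative
side, and it preserves the exact degeneracies ΔΔG = 0 at α = β = γ = 1 and
at c = 0. c = 0.15 is the largest round value keeping both presets
positive definite in all three ligation states. Known limitation: the
qualitative ridge/basin layout of the (k1, k12) landscape depends on this
coupling choice and should be read as a property of this model, not a
unique consequence of the printed constants; cells that lose positive
definiteness are reported as NaN.

## Sequential-site ITC model

For s sequential binding steps with stepwise dissociation constants K_i,
the fraction with i ligands bound is F_i ∝ Π_{j≤i}[L]/K_j; the free ligand
concentration solves the mass balance L_tot = [L] + P_tot·Σ i·F_i by
bracketed root finding on [0, L_tot] to a relative tolerance of 1e−12. The
cell heat content is Q = V0·P_tot·Σ F_i·(Σ_{l≤i}ΔH_l), and each
injection's heat is ΔQ corrected for the displaced volume,
q_j = Q_j − Q_{j−1} + (dV/V0)(Q_j + Q_{j−1})/2, with cell species diluted
by (1 − dV/V0) per injection. Fitting minimizes squared residuals over
{ln K_i, ΔH_i} by Levenberg–Marquardt from a deterministic multistart grid
(stopping early when a start is numerically exact); the first injection is
excluded by default, reflecting the syringe-diffusion artefact of the
instrument class. CAP-type data use s = 3 (two major plus one minor site);
GlxR-type use s = 2.

The reported cooperativity ratio defaults to the statistical convention:
the stepwise ratio of the two major sites divided by 4, the value two
identical independent sites on a symmetric dimer would show, so that 1
means non-cooperative and the number lives on the same intrinsic scale as
exp(ΔΔG/RT) from the network model. The raw stepwise ratio is retained for
audit, and every report names its convention.

## Conservation versus allostery

Per-position minimum mutation counts are estimated by nearest-neighbour
parsimony: for each sequence, all sequences at its minimum Hamming
distance (ties included, gaps count as differences) contribute their
differing positions; the counts n_i sum to the total N by construction.
Each position's mutation probability is linked to its allosteric score
x = |ΔK2/K1| at k_R/k = 0.25 through
μ(x) = logistic(β0 + β1·x + β2·x²) — the simplest three-parameter link
giving the two degrees of freedom the allostery test needs; scores are
used raw (any tiny plotting offset is display-only). Overdispersion among
positions is a beta-binomial with shapes a = μ/φ, b = (1−μ)/φ, which has
per-trial variance μ(1−μ)φ/(1+φ); below φ = 1e−10 the binomial limit is
evaluated directly. Likelihood-ratio tests compare the full model against
β1 = β2 = 0 (2 df) and against the binomial limit (1 df; note the latter
null is on the boundary φ = 0, making the χ²₁ reference conservative).
Profile-likelihood confidence intervals re-maximize the nuisance
parameters on an expanding bracket and solve the drop-by-χ²₁(level)/2
condition by bisection; endpoints beyond the search span are reported as
open. Fits use Nelder–Mead with a BFGS polish from a small deterministic
multistart, φ on a log scale.

## Synthetic generators

All generators are pure functions of (config, seed).

*Toy dimer*: two compact bead clusters per monomer (12 beads each by
default, 48 total — large enough for non-trivial spectra, small enough for
brute-force oracles), monomer B the exact C2 rotation of monomer A when
the symmetric flag is set, one three-atom unequal-mass ligand per monomer
so the mass-weighted placement is exercised. Disconnected draws are
resampled with the seed incremented and a warning. It emulates the
two-domain homodimer topology and exact symmetry; it does not emulate
secondary structure, realistic contact order, or crystallographic noise,
so quantitative K2/K1 values at toy scale say nothing about real proteins
— only the structural invariants (zero-mode count, symmetry, rescale
invariance, decoupling limits) transfer.

*Titrations*: the forward model above plus i.i.d. Gaussian heat noise
(default 0.4 µcal on ~40 µcal early injections, ~1%), with geometry
defaults of 40×1 µL injections of 5 mM ligand into 202 µL of 200 µM
protein. Baseline drift, peak-integration error and active-volume
uncertainty are not modelled.

*Sequence families*: per-position counts are drawn from the linked
beta-binomial (`synth_counts`, untruncated, for statistical studies) and
realized as a mutation path: an ancestor plus one sequence per event, each
differing from its predecessor at exactly one position, same-position
events interleaved by a greedy scheduler so that no two adjacent path
steps hit the same position. On such a path every adjacent pair is each
other's unique-or-tied nearest neighbour and parsimony recovers exactly
two counts per event (once from each side), giving a known ground truth.
Because a position can host at most 19 distinct substitutions, the family
realization redraws per-position counts above that cap (a tail-truncated
beta-binomial); count-level studies use the untruncated draws. Defaults —
L = 210, N = 500 events, β0 = −5.3 (mean rate near 1/L), β1 = −2.4,
β2 = 0, φ = 0.005 (overdispersion factor ≈ 3.5 at N = 500) — mirror the
scale of a ~165-member family of a 210-residue protein. No phylogeny
beyond the path construction is emulated, so passing tests demonstrate the
estimator's behaviour under its own generative assumptions, not robustness
to real evolutionary correlation.

## Problem sizes and numerical choices

Dense eigensolves dominate the cost: a 48-bead toy triple takes ~50 ms, a
~420-residue dimer with ligand nodes ~1 s per ligation state. The test
suite and the acceptance script therefore run statistical studies at
deliberately modest sizes: 120–200 replicates for type-I-error
calibration of the 2-df allostery test, 20 replicates at 2000 events for
strong-effect sign recovery, and single noise-free titrations for exact
parameter recovery (machine-precision residuals make replication
uninformative there). Ties in the cutoff (d = Rc exactly) are included;
duplicate coordinates and disconnected networks are hard errors; all
optimizer starts are deterministic.
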