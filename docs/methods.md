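# Methods

## Scope and data model

The package analyses *multi-run* coordinate ensembles: several independent
MD replicas of one system (receptor ± ligand ± ion), sharing a topology.
All statistics are computed on the trailing fraction of each run (default
window 0.5, i.e. the last half of every replica, mirroring the common
practice of discarding the first half as equilibration), selected **per
run** — never across concatenated replicas — and then pooled. Frame counts
kept per run follow a floor rule, `floor(window × frames)`, taken from the
run's tail.

Topologies are PDB files; ligand residues are those stored as HETATM (or
named explicitly). Insertion codes are rejected: author numbering must be
unambiguous, and all residue ranges in region definitions are inclusive on
both ends. Coordinate runs use a plain-text dialect (magic line, atom and
frame counts, then one `x y z` row per atom per frame, Å) so that fixtures
are small, diffable and platform-independent.

Built-in region fixtures for the adenosine A2A receptor provide the
extracellular loop region (I64–L78, L137–V178, C254–Y271), the
intracellular loop region (A30–Y43, I104–A121, L208–H230), the orthosteric
binding-site residues, the G-protein-interface residues (22 residues after
range expansion) and the broader extracellular surface used as pathway
sources.

## Torsional entropy

Conformational entropy is estimated in internal (torsion) coordinates;
bond and angle contributions are neglected as comparatively small.
Dihedrals use the standard signed atan2 formulation (verified against an
independent geometry library); angles live in [−180°, 180°), with +180°
mapped to −180°. Colinear (undefined) frames are dropped from that
torsion's series with a log record, as are φ/ψ of chain-terminal residues.

Each torsion's marginal entropy is the Gibbs entropy of its binned
distribution on M = 30 equal bins (12° bins — a common choice for dihedral
statistics; the bin count is configurable):

    S_raw = − Σ_k p_k ln p_k           (nats = units of k_B)
    S     = S_raw + (M_occ − 1) / (2N)  (Miller–Madow correction)

where M_occ counts occupied bins and N the pooled sample count. The
correction form is config-switchable (`correction="none"` disables it)
because several finite-sampling corrections circulate in the literature;
Miller–Madow is the default as the simplest first-order bias correction.
Region entropies are sums of corrected per-torsion entropies over all
torsions of all region residues (both backbone and side-chain torsions by
default), with per-loop subtotals reported alongside the totals.

## Mutual information

Pairwise MI uses the identical estimator on the M×M joint histogram:

    I(a;b) = S(a) + S(b) − S(a,b)

with the correction applied to each term. Under independence the three
Miller–Madow terms nearly cancel the positive plug-in bias of MI, so
independent pairs calibrate to ≈ 0; residual negative estimates are
clamped to zero with the raw value retained. Residue-level MI aggregates
over all (torsion-of-i, torsion-of-j) combinations by maximum (sum and
mean are options); the attaining torsion pair is recorded. Histograms pool
samples, so MI is invariant to run ordering.

The synthetic ground truth is a bivariate angular model with von Mises
marginals and cosine-of-difference coupling,

    p(θi, θj) ∝ exp[κm cos θi + κm cos θj + κc cos(θi − θj)],

sampled *exactly* by rejection from the product of the marginals
(acceptance `exp(κc(cos(θi−θj) − 1))`). Its MI is computed by midpoint
quadrature on a 720×720 grid (doubling the grid moves the value by
< 1e−12 for the concentrations used); the oracle can also return the MI of
the distribution *discretized* to the estimator's bin count, the
population quantity the histogram estimator converges to. At κc = 2 the
binned (30-bin) MI sits ~0.9% below the continuous value, well inside the
5% calibration band used in the tests.

## Allosteric pathways and pipelines

Residues form a graph whose edges require both correlated motion and
physical contact: edge (i, j) exists iff the minimum heavy-atom distance
is ≤ 5 Å in ≥ 75% of analysis frames *and* MI(i, j) > 0. A pure-MI
complete graph would make pathways physically meaningless, so the
proximity gate is part of the edge definition (both parameters are
configurable). Edge cost is

    c(i, j) = − ln( MI_ij / MI_max )

with MI_max the graph-wide maximum, turning maximum-product-of-MI path
search into an additive nonnegative shortest-path problem. One optimal
path is computed per (source, sink) pair with Dijkstra; among equal-cost
optima the lexicographically smallest residue sequence is returned, making
results deterministic. Pathways from the extracellular surface to the
G-protein interface are retained only if they traverse at least one
binding-site residue; pairs with no qualifying path are recorded as
absent, not errors. Disconnected endpoints yield an explicit no-path
result.

Pipelines are connected components of the pathway-overlap graph (two
pathways overlap when they share ≥ 1 edge; the threshold is a parameter).
A pipeline's strength is its member count, so strengths across pipelines
always sum to the number of retained pathways; a residue's hub count is
the number of member pathways containing it. Pipelines are ordered by
descending strength with ties broken by smallest member residue id.

## Ligand–receptor contacts

Two contact kinds per frame:

* hydrogen bond — heteroatom (N/O) pair within 3.5 Å **and**
  donor–H–acceptor angle ≥ 120° (the angle is taken at the hydrogen;
  either partner may donate; a heavy atom's hydrogens are those of its own
  residue within 1.2 Å). If an in-range pair has no hydrogen on either
  side, detection fails unless ideal-placement inference is enabled, in
  which case the distance gate alone decides (equivalent to assuming the
  H on the donor–acceptor axis) and the output is flagged.
* van der Waals — any ligand-carbon to residue-carbon pair within 4.0 Å;
  residues without carbons can never make this contact.

Occupancy = in-contact frames / total analysis frames, pooled over runs
(equivalently the frame-weighted mean of per-run occupancies). A contact
is *sustained* iff occupancy strictly exceeds 0.40 — exactly 40% is not
sustained. Both kinds are reported separately per residue plus a combined
any-contact occupancy. Mean minimum distances between the contact-defining
atom sets are reported over in-contact frames and over all frames; state
comparisons difference the all-frames means.

The interaction energy is a cutoff-free sum over group pairs of
`k·q_i·q_j/r + 4ε[(σ/r)¹² − (σ/r)⁶]` with k = 332.0636 kcal·Å/(mol·e²)
and Lorentz–Berthelot combining (geometric optional), averaged per frame
(mean ± SD). Parameters are user-supplied; the package ships no force
field and does not attempt to reproduce any MD engine's energies.

## Flexibility and pocket geometry

RMSF is computed about the ensemble-average structure: frames are
least-squares superposed (Kabsch) onto the running average over a fit
selection (default: the analysed selection; all Cα is the pipeline
default), iterating fit and re-average to self-consistency, then
`RMSF_i = sqrt(⟨|x_i − ⟨x_i⟩|²⟩)`. Superposition removes six rigid-body
degrees of freedom, so with small fit selections the recovered RMSF of
pure noise dips below σ√3 by ≈ (1 − 2/N_atoms)^½; validation fixtures use
≥ 150 fit atoms, keeping the bias under 1%. B-factor = (8π²/3)·RMSF².

The spatial distribution function superposes frames on a rigid alignment
selection (≥ 3 atoms) and bins tracked-atom positions on a 3D grid
(default 1 Å); positions off the grid are tallied separately.

Pocket volume follows the POVME recipe: a 12×12×12 Å box of 1 Å voxels
centred on the ligand centroid; a voxel dies when its centre lies within
the van der Waals radius (Bondi set: C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20 Å; table configurable) of any receptor atom, the ligand itself
excluded from the clash set. Voxel centres sit at integer multiples of
the spacing from the box centre (an even count extends one half-voxel
farther on the negative side); this alignment keeps the empty box at
exactly 1728 ų and the single-atom 3 Å clash sphere within 9% of the
analytic 113.1 ų, versus +20% for a half-offset grid at the same
spacing. Surviving voxels 6-connectivity-disconnected from the 4 Å core
sphere at the box centre are pruned as outside pockets (pruning can be
disabled). Per-frame volumes are pooled over runs into mean ± SD.

Activation-state projections compute per-frame Cα–Cα distances for two
residue pairs (e.g. R102–E228 for TM3–TM6 and R102–Y288 for TM3–TM7) and
histogram them on a 2D grid (0.25 Å bins); crystal-structure reference
distances can be attached as markers.

## BAR free energies

Each λ window supplies forward and reverse work samples (reduced units by
default; kcal/mol inputs are converted through the stated temperature,
default 310 K). The window free energy solves Bennett's self-consistent
equation

    Σ_i f(M + W_f,i − ΔG) = Σ_j f(−M + W_r,j + ΔG),
    f(x) = 1/(1+eˣ),  M = ln(n_f/n_r)

by bracketed Brent root finding (the imbalance is monotone in ΔG; the
bracket is widened until it straddles the root). The standard error uses
Bennett's asymptotic variance; when the two work distributions barely
overlap the value is still returned but the SE is flagged unreliable.
Totals sum window ΔGs with errors combined in quadrature. Deterministic
work (zero variance, Crooks-consistent) is returned exactly.

Gaussian fixtures exploit the Crooks constraint: if W_f ~ N(μ, σ²) then
the unique consistent reverse distribution is W_r ~ N(σ² − μ, σ²) and
ΔG = μ − σ²/2, giving a closed-form truth per window. The package only
consumes work samples; it never runs alchemical MD, so literature ΔG
values produced by cluster-scale simulations are out of reach by design.

## Synthetic generator: what it emulates, what it does not

The toy receptor is a set of straight residue stacks ("helices", 20 Å
apart, 3.8 Å rise) of five-atom alanine-like residues plus a ligand with
named atoms (an amine-like N and hydroxyl-like O, each given an explicit
hydrogen, plus carbons). Atoms jitter with an isotropic per-axis Gaussian
σ (scalar or per-residue), so the expected 3D RMSF is σ√3 — the per-axis
convention is recorded in the fixture metadata. Scheduled ligand contacts
are realized by moving the assigned ligand atom onto/away from its target
residue (2.9 Å for hydrogen bonds with the H at 180°, 3.5 Å for C–C
contacts, 8 Å when out of contact) in a seeded random permutation of
frames, separately within the analysis window and its complement, so the
within-window occupancy is exact to within 1/frames by construction.
Identical seeds reproduce bit-identical fixtures.

These fixtures deliberately contain no force field, solvent, membrane,
periodic boundaries, or autocorrelated dynamics — frames are i.i.d. given
the schedule. Passing tests therefore demonstrate estimator correctness
(calibration, bias, invariances, determinism) on data with known
structure, not the sampling quality or physical realism of any real MD
ensemble.

## Problem sizes and numerical choices

Validation runs use 5 runs × 20 000 frames (10⁵ samples) for MI/entropy
calibration, 10⁴ pooled frames for RMSF recovery, 10⁵ work samples per
window for single-window BAR and 20 × 10⁴ for the λ-ladder, 200 random
graphs (≤ 12 nodes) for the path oracle, and 200-frame runs for contact
schedules — sizes at which the analytic tolerances (5% MI, 3% RMSF, 2 SE
for BAR) hold comfortably and the whole suite runs in well under a
minute per module. Histogram bin indices clip the right edge to guard
against floating-point roundoff at +180°; MI clamps negative estimates at
zero; Dijkstra ties break lexicographically; volume grids use strict
`> r²` retention so an atom exactly on a voxel centre deletes it.

## Known limitations

* First-order entropies only: no second-order/MIST/MIE expansions, no
  quasi-harmonic estimates.
* The exact undersampling-correction formula used by prior entropy work is
  not uniquely determined in the literature this design follows;
  Miller–Madow is one defensible choice and is therefore switchable.
* One optimal path per (source, sink) pair — no k-shortest-path variant.
* H-bond detection assumes explicit hydrogens or accepts ideal-placement
  inference; no water-mediated hydrogen-bond networks.
* No periodic-boundary unwrapping or membrane handling; inputs are assumed
  whole and unwrapped.
* Binary trajectory formats are not parsed; convert to the plain-text
  dialect (or extend `traj_io`) first.
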