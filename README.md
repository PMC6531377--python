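# gpcrdyn

Trajectory-ensemble analysis of G protein-coupled receptor (GPCR)
conformational states.

When a GPCR such as the adenosine A2A receptor is simulated in several
conformational states — inactive (R), active-intermediate (R′), G-protein
bound fully active (R*·G), and the metastable state after G-protein removal
(R*·G⁻) — the interesting biology lives in *differences between ensembles*:
how much conformational entropy the extracellular and intracellular loops
carry, how strongly torsional motions of distant residues are correlated,
which ligand contacts persist, how the binding pocket volume and the ligand
density cloud change, and what the ligand binding free energy is in each
state. `gpcrdyn` implements that analysis layer for multi-run MD ensembles
(the convention throughout is five independent replicas with the trailing
half of each run as the analysis window), and ships a synthetic-data module
so that every estimator can be validated against analytic or brute-force
ground truth without any external trajectory.

## What it computes

* **Torsional entropy** — for each backbone/side-chain torsion, the Gibbs
  entropy of the binned angle distribution
  `S = -Σ_k p_k ln p_k + (M_occ - 1)/(2N)` (Miller–Madow undersampling
  correction), in units of k_B; region totals over extracellular /
  intracellular loop sets, with per-loop subtotals.
* **Mutual information & allosteric pipelines** — pairwise torsional MI
  `I(i;j) = S_i + S_j - S_ij` on a 30×30 joint histogram; a residue graph
  restricted to spatially proximal pairs (min heavy-atom distance ≤ 5 Å in
  ≥ 75% of frames) with edge cost `-ln(MI/MI_max)`; maximum-MI pathways
  from the extracellular surface to the G-protein interface passing through
  the orthosteric site (Dijkstra, provably equal to exhaustive enumeration
  on the test graphs); pipelines as connected components of the
  pathway-overlap graph, with strength = member count and per-residue hub
  counts.
* **Ligand contacts** — hydrogen bonds (N/O pair ≤ 3.5 Å and
  donor–H–acceptor angle ≥ 120°) and van der Waals contacts (any C–C pair
  ≤ 4.0 Å), per-frame over the pooled analysis window; a contact present in
  strictly more than 40% of snapshots is *sustained*; mean contact
  distances and a Coulomb + Lennard-Jones interaction energy.
* **Flexibility & pocket geometry** — per-atom RMSF about the
  ensemble-average structure after least-squares superposition, B-factor
  `B = (8π²/3)·RMSF²`; spatial distribution function of tracked ligand
  atoms; POVME-style binding-site volume (12 Å box, 1 Å grid, van der Waals
  clash deletion, 4 Å core-region pruning); activation-state projections on
  Cα–Cα distance pairs (TM3–TM6, TM3–TM7).
* **Binding free energy** — Bennett Acceptance Ratio (BAR) over per-λ
  forward/reverse work samples, with asymptotic standard errors and
  quadrature-combined window totals.

## Worked example

```python
import gpcrdyn as g

# a torsion pair with known coupling (von Mises marginals, cosine coupling)
spec = g.TorsionModelSpec(n_residues=2, coupling_edges=[(0, 1, 2.0)],
                          marginal_concentration=0.0,
                          n_runs=5, frames_per_run=20_000, seed=1)
tor_i, tor_j = g.gen_coupled_torsions(spec)
mi, _ = g.mutual_information_pair(tor_i, tor_j, m_bins=30)
print(f"estimated MI  = {mi:.4f} nats")
print(f"quadrature MI = {g.oracle_mi(0.0, 2.0):.4f} nats")

ent = g.entropy_first_order(tor_i, m_bins=30)
print(f"torsion entropy = {ent.corrected:.4f} k_B")

# BAR on Crooks-consistent Gaussian work (truth: mu - sigma^2/2 = 0.5 kT)
(wf, wr), = g.gen_bar_samples(g.WorkSampleSpec(
    mu=[1.0], sigma=[1.0], samples_per_window=100_000, seed=1))
res = g.bar_window(g.WindowWork(0, wf, wr))
print(f"BAR dG = {res.dg:.4f} +/- {res.se:.4f} kT")
```

prints

```
estimated MI  = 0.5652 nats
quadrature MI = 0.5716 nats
torsion entropy = 3.4012 k_B
BAR dG = 0.4974 +/- 0.0023 kT
```

The MI estimator lands within ~1% of the dense-quadrature oracle for the
coupled pair; the flat (κ_m = 0) marginal gives the uniform-histogram
entropy ln 30 ≈ 3.4012 k_B; BAR recovers the closed-form window free
energy within two standard errors.

The CLI mirrors the library:

```sh
gpcrdyn simulate-fixtures --out fixtures/ --seed 1
gpcrdyn run-all config.yaml --out results/
gpcrdyn compare config.yaml --out results/
gpcrdyn bar work_samples.tsv
```

`config.yaml` names the states (topology + run files, or a synthetic toy
spec), region definitions (or the built-in `A2AR` fixture), stage toggles
and parameters; all defaults equal the analysis conventions above.

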