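# allokin

Analysis toolkit for mapping **allosteric communication in protein kinases**
(and other multi-domain enzymes) from solution-NMR chemical shifts,
isothermal titration calorimetry, and simulation-derived conformational
ensembles. The motivating system is the catalytic subunit of protein
kinase A (PKA-C), whose hallmark is binding cooperativity between the
nucleotide site in the N-lobe and the substrate cleft at the lobe
interface: mutations near the αC-β4 loop can leave catalysis intact while
abolishing this long-range coupling. The package provides the complete
quantitative chain used to detect such uncoupling, exercisable end-to-end
on synthetic data with planted ground truth.

## What it computes

**Chemical-shift perturbation (CSP) mapping** (`allokin.peakio`).
Per-state amide peak tables are aligned across a ligation series
(apo → nucleotide-bound → ternary) and combined perturbations computed as

    Δδ = sqrt(ΔδH² + (0.154 · ΔδN)²)

with the conventional 0.154 nitrogen scaling. A linewidth-based
significance filter keeps residues whose shift change strictly exceeds
½Δν(A) + ½Δν(B).

**CONCISE** (`allokin.concise`). Residues whose shifts respond *linearly*
to ligand binding are scored by per-residue PCA; the pooled, standardized
PC1 scores give one probability density per state whose mean tracks the
position of the conformational equilibrium (open → intermediate → closed)
and whose width reports how coordinated the response is — an allosterically
uncoupled protein shows visibly broader densities.

**CHESCA** (`allokin.chesca`). Pairwise Pearson correlations R_ij of
signed shift responses across ≥ 3 states identify allosteric networks;
complete-linkage clustering on 1 − |R_ij| at a display cutoff of 0.98,
per-residue correlation scores

    CorrScore = #(|R_ij| > R_cutoff) / #pairs

and community-level scores R_A,B = #(|R_ij| > R_cutoff)/(n_A·n_B) at
cutoff 0.8 (community membership is user-supplied as a plain-text map).

**ITC binding cooperativity** (`allokin.itc`). Single-site (1:1) fits of
integrated injection heats under the exact finite-injection binding
quadratic (the continuum Wiseman-isotherm derivative is available for
cross-checks), thermodynamic decomposition ΔG = RT ln K_d,
TΔS = ΔH − ΔG, and the cooperativity coefficient

    σ = K_d(apo) / K_d(nucleotide-saturated)

with σ ≫ 1 meaning nucleotide binding primes the enzyme for substrate.

**Markov-state modelling** (`allokin.msmkit`). tICA projection of feature
trajectories, K-means microstates, reversible transition-matrix estimation
with stationary populations π, the population ↔ free-energy relation
ΔG = −RT ln(p/(1−p)) (a 0.5% excited state at 300 K sits at
≈ 3.2 kcal/mol, the usual NMR detection limit), and kinetic Monte Carlo
trajectory synthesis.

**Ensemble shift comparison & restraints** (`allokin.cs_tools`). Per-site
chemical-shift differences Δω between ground- and excited-state conformer
ensembles with bootstrap errors, regression of predicted vs experimental
|Δω|, and the replica-averaged chemical-shift restraint penalty
E_cs = α Σ (δ_exp − ⟨δ_calc⟩_replicas)².

**Synthetic data** (`allokin.synthetic_data`). Seeded generators with
planted truth for all of the above: correlated residue networks riding on
activation coordinates, paired isotherms with planted σ, metastable
Gaussian-emission Markov dynamics, and two-state conformer shift ensembles.

## Worked example

```python
import allokin as ak

# four-state ligation series with two planted 15-residue networks
states, truth = ak.gen_shift_tables(ak.NetworkSpec(seed=1))

# covariance analysis at the 0.98 display cutoff
m = ak.response_matrix(states, set(states.retained))
net = ak.cluster_residues(ak.correlation_matrix(m), response=m)

# paired ITC experiments with planted cooperativity sigma = 3
apo, nuc, _ = ak.gen_itc_experiment(Kd_uM=17.0, dH_kcal_mol=-11.0,
                                    sigma_planted=3.0, noise_fraction=0.02,
                                    seed=1)
sigma, err = ak.cooperativity_sigma(ak.fit_single_site(apo),
                                    ak.fit_single_site(nuc))
print(f"sigma = {sigma:.2f} +/- {err:.2f}")
print(f"dG(p=0.5%) = {ak.population_free_energy(0.005, 300.0):.2f} kcal/mol")
```

This prints

```
sigma = 2.95 +/- 0.15
dG(p=0.5%) = 3.16 kcal/mol
```

the fitted cooperativity coefficient (planted value 3: nucleotide binding
enhances pseudosubstrate affinity threefold) and the free energy
corresponding to a 0.5%-populated excited state at 300 K. The recovered
clusters in `net.clusters` match the planted networks at residues 10–24
and 120–134 exactly. (In the default series the second network follows its
own, orthogonal equilibrium — that is what makes the two clusters
statistically separable.)

For the equilibrium densities, plant both networks on the *same* monotone
activation coordinate and run CONCISE:

```python
import numpy as np
from allokin.synthetic_data import ClusterSpec

rng = np.random.default_rng(1001)
clusters = [
    ClusterSpec(residues=list(range(10, 25)), direction_H_ppm=0.1,
                direction_N_ppm=0.65, magnitudes=rng.uniform(0.6, 1.4, 15)),
    ClusterSpec(residues=list(range(120, 135)), direction_H_ppm=0.08,
                direction_N_ppm=0.5, magnitudes=rng.uniform(0.6, 1.4, 15)),
]
states, _ = ak.gen_shift_tables(ak.NetworkSpec(seed=1, clusters=clusters))
print(ak.concise_analysis(states).densities.round(3))
```

```
           mean_score  sd_score
apo            -1.530     0.016
ADP            -0.188     0.034
ATPgN           0.590     0.031
ATPgN_PKI       1.128     0.026
```

A command-line pipeline mirrors the library (`allokin csp / concise /
chesca / communities / itc-fit / msm / kmc / dw-compare / simulate`); see
`allokin --help`.

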