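# allonet

Allostery without conformational change, from coarse-grained protein
dynamics. `allonet` is a Python library for quantifying how ligand binding
re-tunes the global low-frequency vibrational modes of a homodimeric
protein — the mechanism by which CRP/FNR-family transcription factors such
as *E. coli* CAP and *C. glutamicum* GlxR achieve negative cooperativity
between their two cAMP sites while their mean structure stays put.

It is written for structural biologists and biophysicists who want to:

* build **elastic network models** (one bead per Cα, uniform springs within
  8 Å, one mass-weighted pseudo-node per bound ligand) from PDB files and
  compute the allosteric free energy
  `ΔΔG = (RT/2)(S_holo2 + S_apo − 2 S_holo1)` with `S = Σ ln λ_m` over
  nonzero normal modes, and the cooperativity ratio
  `K2/K1 = exp(ΔΔG/RT)` (> 1: negative cooperativity);
* run **in-silico spring-constant mutagenesis** (`k_R/k` scans) to map
  which residues control cooperativity, with per-contact decompositions and
  per-residue flexibility (B-factor) change maps;
* evaluate a **7-degree-of-freedom block model** of a cooperative
  homodimer (two domains per monomer, breathing modes plus inter-block
  displacements, free energy from `(RT/2) ln det K`) and its (k1, k12)
  cooperativity landscape, with CAP and GlxR wild-type presets;
* fit **sequential two- and three-site binding models** to isothermal
  titration calorimetry heats (free ligand by bracketed root finding,
  stepwise K_i and ΔH_i by multistart least squares) and report K2/K1 in a
  statistically corrected convention comparable to the network prediction;
* test whether **allosterically important residues are conserved**:
  nearest-neighbour parsimony mutation counts from an aligned family,
  a beta-binomial model whose mutation rate is a logistic function of the
  residue's allosteric score, likelihood-ratio tests and profile
  confidence intervals;
* generate **synthetic data** with known ground truth for every stage
  (C2-symmetric toy dimers, noisy titrations, beta-binomial sequence
  families), so the whole pipeline is testable offline.

## Worked example

`examples/01_elastic_network_cooperativity.py` builds a 48-bead synthetic
homodimer and computes its cooperativity:

```
structure: toy-dimer-1, 48 residues, 2 ligand sites
S_apo   =   186.6628   (sum of log-eigenvalues, apo)
S_holo1 =   196.5352   (one ligand bound, site-averaged)
S_holo2 =   205.6785   (both ligands bound)
ddG     =    -217.31   cal/mol
K2/K1   =     0.6945
```

The three log-eigenvalue sums are the harmonic free-energy contributions
of the three ligation states; their balanced combination gives ΔΔG. Here
ΔΔG < 0 and K2/K1 < 1: for this toy geometry the first binding event
*stiffens* the second site's modes and binding is positively cooperative.
On the real CAP crystal ensemble the same computation gives
ΔΔG ≈ +179 cal/mol, K2/K1 ≈ 1.35 — weak negative cooperativity carried
entirely by the mode spectrum. The other examples cover the mutagenesis
scan, the block-model landscape (the CAP preset prints
`ddG = 2.6269 cal/mol, K2/K1 = 1.004416`, anti-cooperative), the ITC fit
(noise-free three-site heats refit to machine precision,
`K2/K1 statistical = 1.680`), and the conservation analysis (a family
generated with a decisively negative allostery coefficient yields
`allostery LRT: G = 50.05, p = 1.4e-11`).

A thin CLI mirrors the library:

```bash
allonet ddg --pdb 1I5Z.pdb --ligand CMP --temperature 300
allonet scan --pdb-list a.pdb,b.pdb --residues all --scales 0.25,0.5,1,2,4
allonet blockmodel --preset CAP --landscape
allonet itc-fit --sites 3 --convention statistical titration.csv
allonet conservation --fasta family.fa --scores scan.csv
allonet simulate network|itc|family --seed 1 --out fixtures/
```

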