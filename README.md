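# mrdock

Mixed-resolution Monte Carlo flexible protein–ligand docking.

`mrdock` is a research engine for docking small molecules into receptors whose
flexibility matters. The receptor is split into two regions: residues near the
binding site are treated atomistically with an AMBER-form force field, while
the rest of the protein is coarse-grained with a structure-based (Gō) model on
the α-carbons. All atom positions are tracked throughout, so the two regions
couple through ordinary atomic nonbonded terms. Sampling is Metropolis Monte
Carlo with an optional nonequilibrium candidate Monte Carlo (NCMC) layer that
alchemically decouples and recouples the ligand inside each compound move.
The intended users are molecular-modelling researchers who want a transparent,
fully scriptable docking platform rather than a black-box docking program.

## The potential

The total energy splits by region,

    U(r) = U_CG(r) + U_AA(r) + U_CG/AA(r)

with the coarse-grained part `U_CG = U_bb + U_Gō`: atomistic backbone
bond/angle/dihedral terms plus a 12-10 pair potential on the α-carbons,

    U_Gō = Σ_ij  ε [5 (r⁰_ij/r_ij)¹² − 6 (r⁰_ij/r_ij)¹⁰]   (native contacts)
           Σ_ij  5 ε (r_HC/r_ij)¹²                          (nonnative pairs)

Native contacts are coarse residue pairs within 8 Å (Cα–Cα) in the reference
structure; defaults ε = 3.0 kcal/mol, r_HC = 1.7 Å. The atomistic and
cross-region terms use 12-6 Lennard-Jones with AMBER combining rules and a
solvent-exposure-dependent distance-dependent dielectric (SEDDD) for
electrostatics:

    U_elec(i,j) = K_coul q_i q_j / (ε_ij r_ij),
    ε_ij = r_ij [ε₀ + (1 − s_kl)(ε₁ − ε₀)],    s_kl = c (v_k + v_l)

where v_k is the occluded fraction of group k's hydration shell (EEF1-style
Gaussian exclusion) and defaults are ε₀ = 2, ε₁ = 8, c = 0.625 — a fully
exposed pair at 10 Å sees an effective dielectric of 80.

For alchemical moves the same energy is regrouped as

    U = U_protein + U_ligand + λ_VDW·U_VDW + λ_elec·U_elec

and an NCMC move walks (λ_elec, λ_VDW) down to (0, 0) and back over four
phases (0.05 steps every 5 interior MC moves), accumulating the nonequilibrium
work `w = Σ Δλ·U_component(r)` and accepting the whole compound move with
probability min[1, exp(−βw)].

## Worked example

Dock the bundled toy ligand into the toy helix receptor (five docking runs,
fixed protein, short refinement):

```bash
mrdock dock --protocol mc --moves 2000 --poses 200 --runs 5 --seed 1 \
            --mode fixed_protein --out campaign
```

prints (energies in kcal/mol):

```
   run_id variant  interaction_energy  total_energy
default/0 default           -4.149184   1318.210097
default/1 default           -1.975493   1320.467577
default/2 default           -4.446147   1317.873064
default/3 default           -5.164898   1317.205782
default/4 default           -2.229998   1320.153940
```

Each row is one independent seeded run: 200 random poses are scattered in a
4 Å ball around the site centre, refinement starts from the lowest-energy
pose, and the final pose's protein–ligand interaction energy (the ranking
score) and total energy are reported. Final poses are written as PDB files
and the table as `campaign/campaign.tsv`. The same campaign is available from
Python via `mrdock.docking.run_campaign`, and `mrdock.analysis` provides
symmetry-corrected ligand RMSD, complete-linkage pose clustering with a
10th-percentile cutoff, and the three pose-ranking rules.

`mrdock fixtures --out fixtures` writes a fully parameterized toy complex
(PDB + YAML parameter file) for experimentation without any downloads.

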