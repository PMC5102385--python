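# gagfold

Tools for asking whether two protein domains share a fold when the
similarity is too weak for ordinary structure searches — the situation that
arises when comparing the central domains of the spumaretroviral (foamy
virus) Gag protein with the N- and C-terminal domains (NtD/CtD) of
orthoretroviral capsid (CA) proteins — together with the supporting
biophysical analyses of such domains: sedimentation-equilibrium
self-association fitting and ¹⁵N-relaxation rotational-correlation-time
estimation.

## What it computes

**Fold kinship by decoy-calibrated alignment.**  Two Cα traces are aligned
by double dynamic programming on local structural environments (the vector
of distances from each residue to all others).  The native alignment score
is standardized against a background of alignments between *decoys* —
random compact models with exactly the natives' secondary-structure segment
lists — giving a Z-score

&nbsp;&nbsp;&nbsp;&nbsp;Z = (S_native − μ_decoy) / σ_decoy.

Z-scores for one domain pairing (NN, NC, CN, CC) across a panel of viruses
are combined into a one-tailed probability T_prob (Stouffer's Σz/√k against
the normal tail, or a one-sample t-test; both reported), and the
forward-vs-reverse pairing question is settled by the differential

&nbsp;&nbsp;&nbsp;&nbsp;ΔT_prob = log₁₀(T_NN·T_CC) − log₁₀(T_NC·T_CN),

with −Δ > 0 favouring the linear (N↔N, C↔C) domain correspondence.
Rigid-body superposition uses the Kabsch algorithm, ranked by the SSM
Q-score Q = N_align²/((1+(rmsd/R₀)²)·N₁·N₂).

**Monomer–dimer sedimentation equilibrium.**  Equilibrium profiles follow
c(r) = c₀·exp(σ(r²−r₀²)) with reduced buoyant mass σ = M(1−v̄ρ)ω²/(2RT);
a dimer adds 2·K_A·c_m² with twice the mass signal.  A global fit over
speeds and loadings shares M_w (single species) or K_A (association;
K_D = 1/K_A) with per-profile reference concentration and baseline free.

**Rotational correlation time.**  ¹⁵N T1/T2 of a rigid isotropic rotor
(dipolar + CSA, J(ω) = (2/5)τc/(1+(ωτc)²)) is inverted per residue via the
T1/T2 ratio, restricted to rigid residues (hetNOE > 0.75), and averaged
with a trimmed mean.  Sphere-model solvent-accessible and buried interface
areas round out the toolkit.

## Worked example

```sh
python analysis/01_simulate_inputs.py
python analysis/02_fold_kinship.py
python analysis/03_sedimentation_fit.py
python analysis/04_relaxation_tc.py
```

prints (abridged):

```
published panel: 4/5 top Z-scores are forward pairings; differential
  -delta = 11.80 (12 by the exponent convention)
synthetic panel (3 quartets, 200 decoys/pairing): mean forward Z 1.58,
  mean reverse Z -2.80, -log10(dT_prob) = 5
monomer-dimer fit of simulated table: K_D = 0.900 uM (truth 0.9)
single-species fit: Mw = 20.54 kDa (truth 20.54)
didomain: tau_c 14.1 ns -> T1 1.259 s, T2 46.7 ms, inverts to 14.10 ns
homodimer: tau_c 18.2 ns -> T1 1.609 s, T2 36.4 ms, inverts to 18.20 ns
simulated table: tau_c = 14.05 ns from 40/50 rigid residues (truth 14.1)
```

Reading this: of the twenty published per-virus Z-scores, four of the top
five belong to forward pairings, and the published pairing probabilities
combine to a 12-log difference favouring the forward correspondence.  On
fully synthetic domain quartets (a 4-helix and a 5-helix toy domain with
designed kinship) the pipeline separates kin pairs from cross pairs by
several σ and yields a positive differential.  The sedimentation fit
recovers the 0.9 μM dissociation constant from 0.5%-noise data, and the
relaxation inversion reproduces the generating correlation times.

The same operations are scriptable through the `gagfold` CLI
(`compare-domains`, `aucfit`, `relax`, `simulate`).

## Layout

- `src/gagfold/` — the library: `structures`, `superpose`, `sap_align`,
  `decoys`, `significance`, `hydrodynamics`, `relaxation`,
  `sasa_interface`, `synthetic_data`, `cli_pipeline`.
- `analysis/` — numbered narrative drivers writing under `results/`.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
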