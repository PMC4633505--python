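# bindfold

Ensemble analysis of binding-coupled nucleic-acid folding.

`bindfold` is a Python package for analysing conformational ensembles of a
protein bound to a DNA/RNA duplex — the situation of a polymerase fragment
gripping a template/transcript hybrid. Given multi-model PDB trajectories
(room-temperature folded ensembles and high-temperature unfolding runs) it
answers four questions structural biologists ask of such systems:

1. **What holds the complex together?** Residue-level interaction
   classification — hydrophobic (side-chain mass centers < 6.5 Å),
   electrostatic (positive-residue charge center to phosphate center
   < 11 Å), hydrogen bonds (polar heavy atoms with a template donor
   < 3.5 Å) and native contacts (side-chain centers < 7.5 Å) — with
   ensemble populations and the > 30 % stability cut.
2. **In what order does it come apart (and hence fold)?** Time series of
   Q_f (surviving fraction of tertiary native contacts), Q_b (binding
   contacts) and the radius of gyration R_g, each fitted to first-order
   kinetics y(t) = A·exp(−t/τ) + B, plus −ln p free-energy surfaces over
   (Q_f, Q_b) or (Q_f, R_g) and apo-minus-bound distance-difference maps.
3. **Which bases matter at the transition state?** The transition
   probability P(t) is fitted to the Boltzmann sigmoid
   P = 1/(1 + exp((t − τ_TS)/τ_trans)), the transition-state ensemble is
   the P ∈ [0.4, 0.6] window, and per-base Φ-values
   Φ_i = (N_TS,i − N_U,i)/(N_F,i − N_U,i) rank bases by transition-state
   nativeness.
4. **Induced fit or conformational selection?** Each bound frame is
   matched to its most similar apo frame; Δ = CS − IF compares apo-pool
   diversity (CS) against bound-to-matched-apo deformation (IF), globally
   (Δ1, 40 Å) and at the binding site (Δ2, 12 Å), with per-shell
   two-sample Kolmogorov–Smirnov tests. Δ < 0 means induced fit dominates.

A first-class synthetic-data module generates duplex+helix complexes,
contact-decay unfolding trajectories, committor series and IF/CS ensemble
pairs with known ground truth, so the whole pipeline is testable without
any external structures.

## Worked example

Simulate an unfolding trajectory with planted kinetics and re-fit it:

```sh
bindfold simulate --scenario unfold --seed 7 --frames 120 --out fx
bindfold kinetics --traj fx/unfold.pdb --native fx/native.json \
                  --observables qf,qb,rg --out kin
```

which logs (one 120-frame replica; the planted lifetimes are
τ_Qb = 1.21 ns, τ_Qf = 1.71 ns):

```
bindfold: Qf over 1 trajectories: tau 1.638 (single fit) ns, A 0.949 ..., B 0.009 ...
bindfold: Qb over 1 trajectories: tau 1.010 (single fit) ns, A 1.069 ..., B -0.013 ...
bindfold: Rg over 1 trajectories: tau 5.239 (single fit) ns, A -35.023 ..., B 51.109 ...
```

Unbinding (τ ≈ 1.0 ns) is faster than tertiary unfolding (τ ≈ 1.6 ns),
which is faster than the overall extension of the molecule — read in
reverse, the hybrid contracts, folds, then binds. Averaging six replicas
tightens the estimates toward the planted values (see
`scripts/acceptance.py`). The same fixtures drive the mechanism
discriminator:

```sh
bindfold simulate --scenario IF --seed 7 --frames 16 --out mech
bindfold mechanism --bound mech/bound.pdb --apo mech/apo.pdb \
                   --receptor mech/partner.pdb --out mrep
```

```
bindfold: Binding-mechanism report
  bound frames 16, apo frames 16
  Delta1 (whole molecule, CS - IF)  -0.5000 Å -> induced fit dominant
  Delta2 (binding site, CS - IF)    -1.8750 Å -> induced fit dominant
  KS median p 1, fraction p<0.05 0.18
```

The deformation was planted only within 12 Å of the partner, so both Δ
values are negative and the deviation-versus-distance profile decreases —
the induced-fit signature.

Library use mirrors the CLI: `gen_complex` → `native_contact_set` →
`q_series`/`fit_exponential`, `fit_boltzmann` → `extract_tse` →
`per_base_contact_counts` → `phi_values`, and `mechanism_report`. Every
fit returns a result object with a `summary()`.

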