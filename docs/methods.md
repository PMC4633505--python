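# Methods

This note records the models behind each analysis stage, the defaults and
why they hold, what the synthetic generators do and do not emulate, and
the numerical choices a maintainer would want written down.

## Interaction model

All interaction criteria are residue-level distance tests on mass centers,
with strict inequalities (a pair *closer than* the cutoff qualifies;
boundary equality does not):

| interaction | geometric test | cutoff |
|---|---|---|
| hydrophobic | side-chain mass centers | < 6.5 Å |
| electrostatic | positive-charge-group center to phosphate-group center | < 11 Å |
| hydrogen bond | polar heavy atoms (N/O/S), ≥ 1 template donor | < 3.5 Å |
| native contact | side-chain mass centers, non-adjacent pairs | < 7.5 Å |

Conventions the criteria leave open, fixed here:

* **Side chains.** Amino acids: heavy atoms beyond Cβ inclusive; glycine
  contributes its Cα so every residue has a nonempty site. Nucleotides:
  base heavy atoms (everything outside the sugar–phosphate backbone) —
  the contact criteria are applied to nucleotides, which have no side
  chain in the protein sense, so the base is the natural analogue.
* **Charge groups.** Arg {NE, CZ, NH1, NH2}, Lys {NZ},
  His {ND1, CE1, NE2}; when these atoms are absent (centroid-level
  models) the side-chain center stands in. The phosphate group is
  {P, OP1, OP2}; a 5′-terminal nucleotide without a phosphate simply has
  no electrostatic site (warning, not an error).
* **Donors.** Hydrogens are never required in the input; donor capability
  is read from per-residue template tables of polar heavy atoms that
  carry hydrogens (backbone N except proline, Ser/Thr/Tyr hydroxyls,
  Lys/Arg/His/Asn/Gln/Trp nitrogens, ribose O2′, base amino/imino
  nitrogens).
* **Non-adjacency** means |i − j| ≥ 2 in contiguous within-chain
  numbering; inter-chain pairs are never sequence-excluded.
* A native contact is *stable* when it holds in ≥ 50 % of folded-state
  frames (configurable); an interaction is *populated* when its ensemble
  population exceeds 30 % (strict).
* Hydrophobic classification is purely geometric — it is not restricted
  to apolar residues, matching the criterion's definition; an
  apolar-only filter exists but is off by default.

## Qf/Qb partition

The native set is partitioned for kinetics by molecular *group*, not raw
chain: with `binding_groups = (receptor_chains, ligand_chains)`, "inter"
contacts cross the protein/nucleic boundary (Q_b, unbinding) and "intra"
contacts lie within the ligand group (Q_f, tertiary folding of the
duplex, whose two strands are distinct chains). Receptor-internal
contacts belong to neither observable. Without groups the partition
falls back to chain identity.

## Kinetics

Q and R_g series are fitted to y(t) = A·exp(−t/τ) + B by bounded
nonlinear least squares (τ ∈ (0, 10·t_max], A and B free) with five
jittered restarts from data-driven initial guesses (B = min y,
A = y(0) − B, τ = first crossing of B + A/e). Time is re-zeroed
internally, so uniform time shifts change only amplitude bookkeeping,
never τ. τ is reported directly as the process half-time — the
convention of the analyses this package implements — and a separate
ln 2·τ column is emitted, explicitly labelled as not the reported
half-time. Across replicas, parameters are summarised as mean ± sample
SD; for low-variance point estimates the replica-averaged series can be
fitted instead (this is what the acceptance harness does — see
"statistical honesty" below).

## Transition state and Φ-values

Per-snapshot transition probabilities P(t) are an *input* (from committor
shooting or any estimator; the package does not launch test simulations).
P(t) is fitted to P = 1/(1 + exp((t − τ_TS)/τ_trans)), so P(τ_TS) = 1/2
identically and the P ∈ [0.4, 0.6] band has width 2·ln(1.5)·τ_trans ≈
0.811·τ_trans. The TSE is the set of snapshots whose time falls in that
band; its average structure is the coordinate mean after Kabsch
superposition onto the frame nearest τ_TS. Per-base native-contact
counts are ensemble means (real-valued, not single-structure integers);
Φ is invariant under any common rescaling of the three count vectors, so
this choice cannot bias Φ. Bases with N_F = N_U have undefined Φ and are
flagged rather than ranked.

## Mechanism discriminator

For each bound frame the most similar apo frame is found by exhaustive
Kabsch-RMSD scan over the pooled apo frames (ties to the lower index).
After one *global* superposition of the match, per-site deviations
|r_bound − r_apo| are binned in 2 Å shells of distance from the binding
site — the partner's mass center in the bound average structure, kept
static so shells are comparable across frames. The IF sample is the
bound-to-match RMSD (global for Δ1; RMS over sites within 12 Å for Δ2,
same superposition); the CS sample pools each matched apo frame's RMSDs
to all other apo frames. Δ = frequency-weighted mean(CS) − mean(IF) with
0.5 Å histogram bins; as the bin width → 0 this equals the difference of
sample means, and tests assert agreement within half a bin. Per-shell
significance uses the two-sample KS test of the within-cutoff site
deviations against the whole molecule's (exact distribution below n = 25,
asymptotic above); because the shell sample is a subset of the global
one, these p-values are conservative — the type-I calibration reported
by the acceptance harness therefore uses two independent samples.

## Synthetic generators

The generators exist to plant recoverable ground truth, not physics: no
sterics, no energetics, and they are not a substitute for molecular
dynamics. Resolution is one backbone pseudo-atom per residue (Cα, or
P/C5′ for nucleotides) plus one side-chain/base centroid, because every
pipeline criterion operates on mass centers of exactly these sets.

* **Complex.** An 11-nt RNA strand paired with a 12-nt DNA strand on a
  common helical curve, packed against a 38-residue pseudo-helical
  protein with basic residues facing the duplex — the chain sizes of the
  system the pipeline is designed around. Helix twist/rise constants are
  plumbing, chosen so that no planted pair distance falls within 0.08 Å
  of any classification cutoff; the construction census (plain loops over
  the ideal geometry) is then a sharp oracle for the classifiers.
  Frames add isotropic Gaussian jitter (default σ = 0.3 Å, the scale of
  folded-state backbone fluctuations; census-equality checks use
  σ = 0.05 Å so near-cutoff flicker cannot blur the oracle).
* **Unfolding.** Independent per-contact exponential breaking cannot be
  realised geometrically once contacts share a residue, so breaking is
  generated at the residue level: residue escape times are exponential
  with per-group rates solved so that a contact — broken when *either*
  partner escapes, i.e. at the minimum of two exponentials — has exactly
  the requested class lifetime (defaults τ_Qb = 1.21 ns < τ_Qf = 1.71 ns
  < τ_Rg = 4.24 ns over a 10 ns window). Escaped residues jump
  17 + U(0, 8) Å along per-residue random directions (immediately beyond
  the 7.5 Å criterion) and keep drifting outward with time constant
  τ_Rg. Consequences: contact-survival marginals are exactly
  exponential but positively correlated through shared residues, and the
  R_g relaxation is only approximately single-exponential with an
  effective time constant above τ_Rg — which preserves, and is only
  claimed to preserve, the Q_b < Q_f < R_g ordering. The unbreakable-core
  fraction defaults to zero (the fitted offsets B of the reference
  analyses are 0.01–0.04, i.e. essentially zero); a nonzero core
  perturbs the class lifetimes of mixed contacts and is flagged as such.
* **Committor.** The Boltzmann sigmoid (τ_TS = 5 ns, τ_trans = 0.4 ns)
  plus clipped Gaussian noise (σ = 0.05).
* **Φ ensembles.** In each transition-state frame residue s is
  independently in place with probability q_s, so contact (i, j) survives
  with probability q_i·q_j and the implied per-base ground truth
  Φ*_i = Σ_{c∋i} q_i q_j / n_i is computed exactly and returned; folded
  keeps everything, unfolded displaces everything.
* **Mechanism pairs.** IF: the apo ligand is the bound conformation
  deformed by 3 Å at sites within 12 Å of the partner center. CS: the
  apo pool cycles 5 global conformers 2.5 Å apart, one of which matches
  the bound conformation up to jitter.

What passing on these fixtures does *not* show: robustness to force-field
artefacts, solvent effects, correlated breathing motions, partial
unfolding intermediates, or atom-level packing — none of which the
generators emulate.

## Numerical choices

* Kabsch superposition enforces a proper rotation by sign-correcting the
  smallest singular value; N < 3 or collinear sets raise. The solver is
  cross-checked against an independent quaternion (Horn) oracle to 1e-9.
* RMSF superposes frames onto the iterated mean structure (2 iterations;
  a third changes nothing measurable). Removing the 6 rigid degrees of
  freedom absorbs ≈ 6/(3N) of the variance — about 1.6 % of the RMSF at
  the 61-site fixtures — which is why the isotropic-jitter check carries
  a 3 % band.
* Equal-mass selections use the plain coordinate mean (exact for
  single-atom sites), keeping strict-inequality boundary tests sharp;
  unequal masses use the mass-weighted sum.
* Free-energy surfaces: 50×50 bins by default over the observed range
  padded 2 %; energies are −ln(p/p_max) in kT with empty bins +∞ in
  memory and max-finite + 1 kT in exports; a degenerate (single-point)
  range gets a 1 % pad and remains a valid single-well landscape.
* Exponential and sigmoid fits require ≥ 8 points; constant series raise
  an unidentifiable-model error; a P series that never crosses 0.5 has
  no transition to locate and raises.
* Multi-model PDB reading requires identical atom lists in every model
  (the offending model is named otherwise); hydrogens are dropped on
  read since all criteria are heavy-atom. Analysis stride is a config
  knob, default 1.

## Statistical honesty of the recovery checks

With six replicas of a complex this size (~24 binding and ~32 tertiary
stable contacts), a fitted lifetime is estimated from only ~140–190
break-time draws, so its sampling SD is 9–16 % of τ — Monte-Carlo
measured, and irreducible by estimator choice (constrained fits and the
survival-integral estimator were tried). The ±10 % recovery check in the
acceptance harness therefore fits the replica-averaged series (the
lowest-variance faithful estimator) and holds at the committed seed, but
at these study conditions it cannot hold for every seed; the kinetic
*ordering* check, by contrast, is robust (≥ 95 % of seeded runs). The
mechanism sign checks and Φ recovery operate far from their thresholds
and are seed-robust.

## Known limitations

* The paper-scale headline numbers of the source analyses (half-times
  from 498 K all-atom MD, TSE snapshot counts of 50/61, crystal-derived
  interaction partners) depend on all-atom simulations this package
  deliberately does not run; the pipeline reproduces the *methods* and
  validates them on planted ground truth.
* The KS shell test inherits the subset-vs-whole construction of the
  original analysis and is conservative near small cutoffs.
* No periodic-boundary handling: inputs must be whole molecules with
  solvent stripped (chain filtering is provided for that).
* Binary trajectory formats (DCD/XTC) are out of scope; multi-model PDB
  is the interchange format.
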