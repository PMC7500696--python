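# helixcheck

Analysis toolkit for NMR-guided structural modelling of small helical
peptide complexes — the kind of problem where a short labelled peptide
(here modelled on a leiomodin fragment binding the tropomyosin N-terminus)
is characterised by chemical-shift-derived torsion predictions, HSQC
titrations, and residual dipolar couplings, and candidate 3D models built
by restrained simulation must be validated against those data.

It is aimed at structural-biology practitioners who have TALOS+-style
prediction tables, peak lists, RDC tables, and multi-model PDB
ensembles/trajectories, and want reproducible versions of the standard
quality metrics instead of one-off spreadsheets.

## What it computes

* **Dihedral restraints** — per-residue φ/ψ flat-bottom restraints from a
  torsion-prediction table, restricted to rigid residues
  (RCI-S² ≥ 0.7 by default) with force constants rk2 = rk3 = 32.0
  kcal·mol⁻¹·rad⁻¹ and configurable exclusions.
* **Ensemble/trajectory metrics** — Kabsch superposition; all-pair ensemble
  RMSD with mean ± SEM (SEM = SD/√n_pairs); rolling RMSD
  (frame *t* vs frame *t − lag* after superposition, a drift metric);
  backbone (φ,ψ) RMSD against predicted targets with circular differences;
  convergence statistics between independently annealed ensembles,
  including a contact-based dissociation filter.
* **CSP and titration mapping** — compound shift perturbation
  Δδ = [(Δδ_H)² + (Δδ_N/6.5)²]^½, attenuation I/I₀ per titration point,
  and quartile-based effect classes mapped onto the sequence.
* **RDC validation** — D = D_max·v̂ᵀSv̂ with the 5-parameter Saupe tensor S
  fit by linear least squares; Q = rms(D_calc − D_obs)/rms(D_obs); dipolar
  wave D(n) = A_v + A_II·cos(2πn/3.6 + φ) over helical stretches.
* **Helix geometry** — helix axes (PCA of smoothed Cα traces), interhelix
  crossing angles, α-helix assignment from dihedrals, and linker contour
  lengths L = 4 Å·(coil residues) + 1.5 Å·(helical residues).
* **Synthetic data** — ideal helices built from internal coordinates,
  helix bundles at controlled crossing angles, perturbed ensembles,
  drifting trajectories, RDCs from a known tensor, and two-state
  fast-exchange titrations, so the whole pipeline is testable end to end.

## Worked example

```python
import helixcheck as hx

BB = hx.AtomSelection.parse("*:*:N,CA,C")

# a two-helix complex crossing at 47 deg, and a 10-model "deposited" ensemble
complex_ = hx.build_bundle([23, 27], 47.0, separation=7.0)
ens = hx.perturb_ensemble(complex_, 0.8, 10, seed=4242)
summary = hx.ensemble_summary(ens, BB)
print(f"pairwise RMSD: {summary['mean']:.2f} +/- {summary['sem']:.2f} A "
      f"over {int(summary['n_pairs'])} pairs")

a = hx.helix_axis(complex_, (2, 22), chain="A")
b = hx.helix_axis(complex_, (2, 26), chain="B")
print(f"interhelix angle: {hx.interhelix_angle(a, b):.1f} deg")

# RDC validation on couplings generated at a 1.5 Hz experimental noise level
helix = hx.build_ideal_helix(21)
tensor = hx.SaupeTensor(8.0, -3.0, 4.0, 2.0, -5.0)
rdcs = hx.synth_rdc(helix, tensor, 1.5, seed=12, residue_set=range(2, 22))
rep = hx.fit_alignment_tensor(helix, 0, rdcs)
print(f"RDC fit: n={rep.n_used}, Q = {rep.q_factor:.3f}, "
      f"rmsd = {rep.rmsd_hz:.2f} Hz")

print(f"contour length 13 coil + 5 helix: {hx.contour_length(13, 5)} A")
```

prints

```
pairwise RMSD: 1.94 +/- 0.01 A over 45 pairs
interhelix angle: 47.0 deg
RDC fit: n=20, Q = 0.322, rmsd = 1.24 Hz
contour length 13 coil + 5 helix: 59.5 A
```

The ensemble spread (mean over the 45 unordered model pairs) and the
crossing angle describe the precision and topology of the model ensemble;
the Q-factor says how well the structure explains the measured couplings
(Q ≈ 0.3 is typical for 1.5 Hz noise on ~12 Hz couplings at this problem
size; experimental structures in the 10–25 % range are considered good);
and 59.5 Å is the maximum extension of an 18-residue linker with 13 coil
and 5 helical residues — the number that decides whether two binding sites
can be bridged.

The same operations are available from a thin CLI, e.g.

```sh
helixcheck restraints --talos talos.csv --s2-min 0.7 --exclude 25
helixcheck rmsd-ensemble --pdb ensemble.pdb --fit "A:17-39:N,CA,C"
helixcheck rdc-fit --pdb model.pdb --rdc rdc.csv --residues 18-38
helixcheck contour --coil 13 --helix 5
```

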