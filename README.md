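# lysodimer

Analysis toolkit for studying **dimer formation in partially unfolded
proteins** from molecular-dynamics data, built around the human-lysozyme
amyloidosis model system (wild type vs. the aggregation-prone D67H
variant). The aggregation cascade starts when a destabilised monomer
partially unfolds, exposes a hydrophobic patch, and pairs up with another
monomer; `lysodimer` provides the measurements used to follow each step of
that story:

1. **Conformational analysis** — backbone RMSD time series and per-residue
   Cα RMSD averages against a fixed reference (Kabsch least-squares
   superposition, proper rotations only); time series of the
   guard-interaction distances that protect the hydrophobic pocket
   (minimum side-chain contact distances, e.g. Asp67{OD1,OD2} ×
   Tyr54{OH}); pocket hydration as the water count inside probe spheres of
   3–6 Å around the Cys65 sulfur; and the β-domain loop-opening coordinate
   (T70–D49 Cα distance) with histogram/Gaussian summary and a
   folded/unfolded verdict by the > 20 Å rule.
2. **Dimer stability** — mass-weighted center-of-mass separation of the
   two chains, with a sustained-crossing dissociation criterion
   (baseline + 10 Å) and back-tracked onset estimation; π-stacking
   ring-centroid distances for the interface contacts.
3. **Binding-affinity ranking** — reconstruction of dissociation
   free-energy profiles from constant-velocity stiff-spring pulling
   (steered MD) logs via the Jarzynski equality

   $$e^{-\Delta G(z)/k_BT} = \left\langle e^{-W(z)/k_BT} \right\rangle,$$

   where the work $W(z) = \int F\,dz_{\mathrm{ref}}$ integrates the spring
   force over the moving restraint reference $z_{\mathrm{ref}}(t) = z_0 + vt$
   (defaults: $k_s = 50$ kcal/mol/Å², $v = 1$ Å/ns, 300 K). The exponential
   average uses a max-shifted log-sum-exp; complexes are ranked by
   bulk-plateau-minus-minimum affinity.

Because full solvated MD is out of reach for routine testing, the package
ships a first-class **synthetic module**: an overdamped-Langevin toy
pulling engine whose exact free energies are available in closed form /
by quadrature, a mock-trajectory generator with programmable loop
flexibility, loop opening, pocket hydration and dimer drift, and
deterministic synthetic stand-in structures encoding the published
residue-level facts of the two lysozyme crystals. Every analysis stage is
validated against these ground truths and against independent oracles
(quaternion-method superposition, brute-force distance/count loops).

## Worked example

```python
import numpy as np
import lysodimer as ld

# a mock trajectory at the unfolded-variant condition (loop opening 23.5 Å)
hl = ld.synthetic_hl_structure()
spec = ld.MockTrajectorySpec(reference=hl, n_frames=2000,
                             target_mean_opening=23.5, opening_sd=1.0,
                             water_target=6.4, seed=0)
traj, truth = ld.generate_mock_trajectory(spec)

series = ld.calpha_pair_series(traj, ("A", 70), ("A", 49))
summary = ld.opening_histogram(series)
print(f"T70-D49 opening: {summary.mean:.1f} +/- {summary.sd:.1f} A "
      f"-> {ld.classify_unfolded(summary.mean)}")

center = ld.select(traj, ("atom", "A", 65, "SG"))
hyd = ld.hydration_shell_scan(traj, center, radii=(3, 4, 5, 6))
for r, m, s in zip(hyd.radii, hyd.mean_count, hyd.sd_count):
    print(f"waters within {r:.0f} A of C65:SG: {m:.1f} +/- {s:.1f}")

# free-energy reconstruction on the toy pulling engine
pot = ld.ToyPotential.harmonic(1.0)
protocol = ld.PullingProtocol(k_s=50.0, v=0.25, z0=0.0, temperature=300.0)
params = ld.LangevinParams(gamma=0.2, dt=2.5e-4, temperature=300.0, seed=42)
logs = ld.simulate_pulling(pot, protocol, params, n_traces=200, span=10.0,
                           output_stride=16)
grid = np.linspace(0.0, 10.0, 101)
traces = [ld.work_trace(lg, protocol, grid) for lg in logs]
profile = ld.jarzynski_profile(traces, protocol.kT)
exact = ld.stiff_spring_free_energy(pot, protocol, grid)
print(f"dG(10 A) = {profile.dG[-1]:.2f} kcal/mol "
      f"(exact {exact[-1]:.2f}, max error {np.max(np.abs(profile.dG - exact)):.3f})")
```

prints

```
T70-D49 opening: 23.5 +/- 1.3 A -> unfolded
waters within 3 A of C65:SG: 0.8 +/- 0.9
waters within 4 A of C65:SG: 1.9 +/- 1.4
waters within 5 A of C65:SG: 3.7 +/- 1.9
waters within 6 A of C65:SG: 6.4 +/- 2.5
dG(10 A) = 49.06 kcal/mol (exact 49.02, max error 0.058)
```

The opening coordinate is recovered at its configured mean and classified
unfolded by the 20 Å rule; the hydration scan recovers the configured
pocket occupancy (6.4 waters within 6 Å, shrinking with the probe volume);
and 200 slow pulls reconstruct the restraint free energy of the harmonic
toy potential to better than 0.1 kcal/mol.

A `lysodimer` console command exposes the same stages as subcommands
(`analyze`, `hydration`, `smd`, `simulate`, `rank`) driven by a single
JSON configuration; see `lysodimer --help`.

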