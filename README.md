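# slitwater

Analysis toolkit for the hydrogen-bond state dynamics and diffusion mechanism
of water under planar nanoconfinement (graphene-style slit pores) and in bulk.

Water squeezed into a single molecular layer cannot complete the
four-coordinated 3D hydrogen-bond network of the bulk liquid: a large
population of O–H bonds stays *dangling* (DB), pointing at the confining
walls, and the residual network is topologically frustrated.  This changes
the mechanism of translational diffusion.  `slitwater` implements the full
analysis chain needed to quantify that mechanism from an MD trajectory:

* per-frame geometric **HB/DB classification** of every O–H bond, with
  coordination-state populations (fractions of 2-, 3-, 4-coordinated
  molecules);
* **continuous survival correlation functions** S(t) = ⟨h(0)H(t)⟩/⟨h⟩ of the
  HB and DB states and their lifetimes τ = ∫S(t)dt;
* **stable solvation-shell states**: each molecule's shell composition,
  filtered for ultrashort transients, and **solvation water exchange (SWE)**
  events in which a shell member Wa is replaced by Wb, with the time origin
  at the |O\*–Oa| = |O\*–Ob| equidistance crossing;
* **kick events**: HB→DB transitions that throw the bonded pair apart while
  the solvation shell persists, with event-synchronized traces (O\*–O
  distance, H-bond indicator, O–H orientation) and donor/acceptor
  recombination statistics;
* the **CTRW decomposition** of the diffusion coefficient,

      D_SWE  = δ²_O* / (2 d τ_SWE),
      D_kick = f · δ²_kick / (4 τ_kick),      (4 = 2d with d = 2 in-plane)

  where f is the mean number of H-bonded pairs per solvation basin taken
  from the coordination populations, alongside the Einstein-relation D from
  the MSD and the *frame* contribution (MSD restricted to intact shells), so
  that D ≈ D_SWE + D_kick (monolayer) or D ≈ D_frame + D_SWE (bulk) can be
  tested quantitatively;
* **structure profiles**: O–O radial distribution function, potential of
  mean force −kT ln g(r), and O–H/wall-normal orientation histograms split
  by bond state;
* **synthetic generators with planted ground truth** (telegraph state
  kinetics, jump+drift CTRW walks, geometric monolayer/bulk lattice toys
  with planted SWE and kick events) so every estimator and detector in the
  chain is falsifiable.

Units: Å and ps throughout; diffusion in Å²/ps with mirrors in
10⁻⁵ cm²/s (1 Å²/ps = 10 × 10⁻⁵ cm²/s).

## Worked example

```python
import numpy as np
import slitwater as sw
from slitwater import synthetic as syn

# a quasi-2D monolayer toy with the confined-water state statistics
traj, log = syn.gen_toy_monolayer(n_molecules=64, n_steps=3000, dt=0.01, seed=0)
bonds = sw.classify_bonds(traj)

db = float(sw.db_fraction_series(bonds).mean())
pops = sw.coordination_populations(sw.coordination_from_bonds(bonds))
factor = sw.mean_hb_partners(pops)
print(f"dangling-bond fraction: {db:.3f}")
print(f"mean H-bond coordination: {factor:.2f}")

for state in ("HB", "DB"):
    surv = sw.survival_function(bonds, state, max_lag=2.5)
    tau = sw.lifetime(surv, "integral_with_tail").tau
    print(f"tau_{state} = {tau:.3f} ps")

# CTRW bookkeeping on a kick+exchange jump walk with known ground truth
from slitwater.diffusion import msd_from_positions, fit_diffusion, assemble_report
from slitwater.kicks import kick_time_and_amplitude

pos, walk = syn.gen_two_channel_walk(n_walkers=300, n_steps=10000, dt=0.01, seed=0)
curve = msd_from_positions(pos, 0.01, max_lag_frames=3000, n_lags=50)
d_total = fit_diffusion(curve, (5.0, 25.0))
tau_k, d2_k = kick_time_and_amplitude(syn.kick_events_from_two_channel_log(walk))
sev = syn.swe_events_from_two_channel_log(walk)
tau_s = sw.swe_time(sev, 0.01)
d2_s = float(np.mean([e.delta_sq for e in sev]))
report = assemble_report("monolayer", 2, d_total, tau_swe=tau_s, delta_sq_swe=d2_s,
                         tau_kick=tau_k, delta_sq_kick=d2_k, kick_factor=2.5)
r = report.to_dict()
print(f"D_total = {r['D_total_1e-5_cm2_per_s']:.2f} x 1e-5 cm^2/s")
print(f"D_kick  = {r['D_kick_1e-5_cm2_per_s']:.2f} x 1e-5 cm^2/s")
print(f"D_SWE   = {r['D_SWE_1e-5_cm2_per_s']:.2f} x 1e-5 cm^2/s")
print(f"additivity residual = {report.residual:.3f}")
```

Output:

```
dangling-bond fraction: 0.359
mean H-bond coordination: 2.46
tau_HB = 0.449 ps
tau_DB = 0.247 ps
D_total = 5.60 x 1e-5 cm^2/s
D_kick  = 4.38 x 1e-5 cm^2/s
D_SWE   = 1.50 x 1e-5 cm^2/s
additivity residual = 0.051
```

About a third of the O–H bonds dangle toward the walls, the DB state relaxes
roughly twice as fast as the HB state, and in the jump walk the kick channel
carries about three quarters of the total mobility — the CTRW estimates
reconstruct the directly fitted D to within ~5%.

## Command line

The `slitwater` console script exposes each stage and a one-shot pipeline:

```sh
slitwater simulate --kind monolayer --n-molecules 64 --n-steps 2000 --out toy.extxyz
slitwater hbonds    --input toy.extxyz --outdir out/
slitwater lifetimes --input toy.extxyz --outdir out/
slitwater run-all   --input toy.extxyz --outdir out/   # all stages + summary.json
```

Every stage writes TSV tables with unit-bearing header comments; `run-all`
additionally writes a machine-readable `summary.json`.  A flat `key = value`
config file (see `slitwater.pipeline.RunConfig` for keys and defaults) can be
passed with `--config`.

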