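# ionbind

Analysis toolkit for transient ion–protein binding in molecular-dynamics
trajectories, built around the question of whether a protein can immobilise
the superoxide radical anion (O₂•⁻) long enough for radical-pair
magnetosensitivity to survive spin-rotational relaxation.

It is aimed at computational biophysicists who have (or simulate) MD
trajectories of small ions around a protein — here, superoxide or chloride
around a cryptochrome-like receptor — and want to quantify:

* **Binding kinetics** — binding events (contiguous intervals with the
  ion–protein heavy-atom minimum distance below 4 Å for at least two
  consecutive frames), their durations *t*_b, per-site and per-residue
  statistics, bound-fraction survival curves *f*(*t*) and bi-exponential
  fits *f*(*t*) ≈ *a* e^(−*t*/τ_fast) + (1−*a*) e^(−*t*/τ_slow), hit rates,
  and escape-termination rules.
* **Spatial structure** — Kabsch superposition, RMSD/RMSF, voxelised
  ion-occupancy maps (1 Å³ voxels, VMD-loadable OpenDX output) and
  iso-level hotspot (binding-site) extraction.
* **Rotational dynamics and spin physics** — the rotational correlation
  time τ₂ of the O–O bond vector from the autocorrelation of
  P₂(cos θ(t)) = ½(3 cos² θ − 1), and the spin-rotational relaxation
  arithmetic

  ```
  1/T = Δg² / (9 τ₂),     Δg² = Σᵢ (gᵢᵢ − g_e)²,     τ_s = 2π / (|γ_e| B)
  ```

  which decides whether a radical pair containing the ion can respond to a
  weak magnetic field (τ_s ≫ T ⇒ spin correlation is lost first).
* **Solvation** — ion-state-resolved (bound d ≤ 3 Å vs bulk d ≥ 10 Å)
  radial distribution functions g(r) of water, solvation-shell boundaries
  from the minima of g(r), per-shell water counts n and the number of
  waters shed upon binding.

Because real MD data for this problem are terabyte-scale, the package
ships a first-class `synthetic` module that generates trajectories with
known ground truth — ions hopping on/off labelled sites with exponential
residence times, rotational Brownian motion with τ₂ = 1/(6 D_r), and
pseudo-water point clouds with prescribed shell structure — so every
analysis stage is validated by parameter recovery.

## Worked example

Spin-relaxation feasibility for superoxide with the DFT-derived g-tensor
principal values (2.0020, 2.0077, 2.1100) in the 50 µT geomagnetic field:

```python
from ionbind.spin import GTensor, delta_g_squared, feasibility_assessment

dg2 = delta_g_squared(GTensor(2.0020, 2.0077, 2.1100))
print(f"Delta_g^2 = {dg2:.4f}")
for tau2 in (1.0, 100.0, 941.0):   # free ion / typical bound / best bound, ps
    f = feasibility_assessment(tau2, dg2, 50e-6)
    print(f"tau2={tau2:6.1f} ps  T={f.T_ns:7.2f} ns  "
          f"tau_s={f.tau_s_ns:.1f} ns  ratio={f.ratio:7.2f}  {f.verdict}")
```

prints

```
Delta_g^2 = 0.0116
tau2=   1.0 ps  T=   0.77 ns  tau_s=713.6 ns  ratio= 921.73  suppressed
tau2= 100.0 ps  T=  77.42 ns  tau_s=713.6 ns  ratio=   9.22  marginal
tau2= 941.0 ps  T= 728.57 ns  tau_s=713.6 ns  ratio=   0.98  feasible
```

i.e. a freely tumbling superoxide (τ₂ ≈ 1 ps) relaxes ~900× faster than it
precesses — no magnetosensitivity — while a site-bound ion slowed a
thousandfold reaches T ≈ τ_s, where a magnetic-field effect becomes
possible.

An end-to-end synthetic run (simulate → detect events → τ₂ → RDF →
occupancy map):

```python
from ionbind.pipeline import AnalysisConfig, run_pipeline

cfg = AnalysisConfig(seed=1, outdir="demo_out", params={
    "simulate": {"n_ions": 2, "duration": 100.0, "dt": 0.2},
    "rotation": {"tau2_ps": 100.0, "n_steps": 200000, "max_lag": 800},
})
run_pipeline(cfg)
```

writes 11 outputs under `demo_out/`.  `binding_summary.csv` tabulates the
70 detected events (54.3% longer than 1 ns for the default k_off = 1 ns⁻¹
site), and `spin_feasibility.json` reports the recovered rotational
correlation time and its consequences:

```
"tau2_fit_ps": 97.54, "tau2_integral_ps": 93.04,
"ground_truth_tau2_ps": 100.0, "T_ns": 75.5, "tau_s_ns": 713.6,
"ratio_tau_s_over_T": 9.45, "verdict": "marginal"
```

The same stages are available from the shell:

```
ionbind run -c config.yaml --seed 1
ionbind analyze-binding -c config.yaml --cutoff 4.0 --min-duration 0.4
ionbind analyze-rotation --seed 3 -o rot_out --field 5e-5
ionbind map-occupancy -c config.yaml --voxel 1.0 --iso 0.015
```

## File formats

* **Structures in:** PDB (ATOM/HETATM records; elements from column 77–78
  or a leading-letter heuristic).
* **Trajectories:** a diffable CSV with columns
  `frame, time_ps, atom_id, x, y, z`; rows with `atom_id == -1` carry the
  per-frame periodic box lengths in the x/y/z columns.  Coordinates are in
  Å, times in ps; binding times are reported in ns.
* **Out:** events/summaries/survival curves/RDF and shell tables as CSV,
  spin feasibility as JSON, occupancy grids as OpenDX scalar fields,
  hotspot centroids as PDB pseudo-atoms, plus a `manifest.json` recording
  the config hash, package version, seed and produced files.

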