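# pathmetad

Well-tempered metadynamics with path collective variables for mapping
two-state conformational transitions — the protocol used to chart the
open↔closed free-energy landscape of hinged multi-domain enzymes such as
adenylate kinase, packaged with analytic and bead-model test systems so the
whole pipeline runs and validates on a desktop.

## What it computes

Given two endpoint conformations (Cα-level PDB), the package

1. **builds a reference path** S(l), l = 1..P by morphing (linear
   interpolation after optimal superposition) and resamples it so
   successive frames are equally spaced in the mean-square-displacement
   metric, choosing λ = 1/mean(successive-frame MSD);
2. **evaluates the path CVs**
   s(R) = Σ l·e^(−λd²ₗ)/Σ e^(−λd²ₗ) (progress) and
   z(R) = −(1/λ) ln Σ e^(−λd²ₗ) (distance from the path), where d²ₗ is the
   MSD of R to frame l after Kabsch superposition on a chosen atom subset;
3. **samples** with a BAOAB Langevin integrator while depositing
   well-tempered hills on s — height w₀·e^(−V/k_BΔT), every `pace` ps —
   with half-harmonic walls restraining z (and optionally s);
4. **recovers free-energy surfaces** from the bias,
   F = −(T+ΔT)/ΔT·V, or from reweighting,
   w_i ∝ e^((V_i − c(t_i))/k_BT), projected onto any recorded CVs;
5. **analyzes** the FES: persistent basins, the minimax (lowest
   free-energy) path between them, barrier heights in kJ/mol and k_BT,
   population-weighted basin ΔF, plus per-domain RMSD/RMSF trajectory
   statistics.

Two synthetic systems exercise everything end to end: a 1-D tilted double
well whose barrier and minimum offset are exact by construction, and a
planar two-domain bead "protein" whose lid-like block crosses a designed
4 k_BT hinge barrier into an open state 1.5 k_BT below the closed one.

## Worked example

```python
import numpy as np
from pathmetad import (make_two_domain_model, build_morph_path,
                       resample_equal_msd, BiasState, WallRestraint,
                       run_wtmetad, fes_from_bias, find_minima,
                       barrier_height, basin_delta_f, Axis)

model = make_two_domain_model(seed=11)          # designed: 4 kBT / 1.5 kBT
system = model.make_system(seed=11)
sel = np.union1d(model.closed_endpoint.selections["CORE"],
                 model.closed_endpoint.selections["LID"])

ext_closed, ext_open = model.path_endpoints(0.25)
raw = build_morph_path(ext_closed, ext_open, 60, align_idx=sel)
path = resample_equal_msd(raw, 16, 0.02, align_idx=sel, measure_idx=sel)
print(f"lambda = {path.lam:.0f} nm^-2")

params = BiasState(T=300.0, deltaT=900.0, pace=2.0, w0=2.0,
                   sigma=np.array([0.4]), biased_cv_ids=["s"],
                   walls=[WallRestraint("z", 0.25, 4000.0),
                          WallRestraint("s", 2.0, 200.0, side="lower"),
                          WallRestraint("s", 15.0, 200.0, side="upper")])
trace, bias, traj = run_wtmetad(system, path, params, 1_000_000, seed=11)

fes = fes_from_bias(bias, [Axis(2.0, 15.0, 130, "s")],
                    time_average_fraction=0.2)
A, B = find_minima(fes, depth_threshold=2.5)[:2]
kj, kbt = barrier_height(fes, A, B, temperature=300.0)
print(f"barrier {A.label}->{B.label}: {kj:.1f} kJ/mol = {kbt:.2f} kBT")
print(f"basin dF = {basin_delta_f(fes, A, B, 300.0):.2f} kBT")
```

Output from this exact run:

```
lambda = 1355 nm^-2
barrier A->B: 10.3 kJ/mol = 4.11 kBT
basin dF = -1.38 kBT
```

Basin A is the open state (global minimum, wider), B the closed one; the
biased run recovers the designed 4 k_BT hinge barrier and the ~1.5 k_BT
stability of the open state from 4 ns of sampling.  λ comes out near the
inverse mean frame spacing by construction.

## Command line

A thin CLI wraps the library (`pathmetad --help`): `makepath` (endpoint
PDBs → equally-spaced path + λ report), `run` (YAML config → COLVAR/HILLS/
trajectory), `fes` (HILLS → FES), `reweight` (COLVAR+HILLS → projected
FES), `analyze` (FES → basins/path/barrier report), and `demo` (seeded
end-to-end two-domain run).  COLVAR and HILLS use the PLUMED-style ASCII
dialect; FES files are gnuplot-ready blocks.

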