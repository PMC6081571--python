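# aerotree

Reduced-order modelling of aerosol transport in healthy and
severe-asthmatic airway trees.

Severe asthma alters both lung *structure* — airway lumens flatten
(circularity `Cr = π·Dave/Pe` falls) and narrow (hydraulic diameter
`Dh = 4·Ac/Pe = Cr·Dave` falls) — and lung *function* — the air-volume
change between inflation levels shifts from the lower to the upper lobes.
`aerotree` is a desk-scale pipeline for studying how those alterations
reshape where inhaled particles go: it generates phenotype-controlled
synthetic airway trees, converts lobar ventilation into per-branch flows,
transports particle ensembles with a Lagrangian drag + gravity model, and
reports lobar distribution, branch deposition efficiency against the
Stokes number

    Stk = 2 Q ρ_p d² Cc α^3.7 / (9 π μ_f Dave³),

and the coupling of constriction (`1/Dh`) with wall shear stress, pressure
drop and deposition. It is a library for Python use; the `examples/`
scripts are the guided tour, and `docs/methods.md` documents the model and
its reductions (analytic elliptic-Poiseuille branch flow standing in for a
resolved CFD field is the central one).

Intended users: researchers in respiratory biomechanics and aerosol
dosimetry who want the structure–function–deposition mechanisms at desk
scale — for teaching, hypothesis screening, or as a transparent reference
against which resolved-CFD results can be interpreted.

## Worked example

```python
from aerotree import (flow_solution, generate_tree, generate_volume_change,
                      morphometry_table)
from aerotree.boundary_conditions import stokes_context
from aerotree.synthetic_data import PHENOTYPES

spec = PHENOTYPES["severe_cr_dh"]          # reduced Cr + lower-lobe constriction
tree = generate_tree(spec)
dv = generate_volume_change(spec)          # lobar air-volume change, upper-shifted
flow = flow_solution(tree, dv)             # 20 L/min sinusoidal-peak inflow

print(morphometry_table(tree, names=["Trachea", "RMB", "LB10"]))
print("U/(M+L)|v =", round(dv.uml_ratio, 3))
print("Stk(10um, LB10) =", round(stokes_context(tree, flow, "LB10", 10e-6).Stk, 3))
```

prints (seeded generator, reproducible):

```
         lobe  generation        Cr    Dave_mm      Dh_mm
branch
Trachea  none           0  0.835308  18.000000  15.035542
RMB      none           1  0.844702  11.979456  10.119065
LB10      LLL           5  0.857805   3.431312   2.943396
U/(M+L)|v = 0.818
Stk(10um, LB10) = 0.279
```

`Cr ≈ 0.84–0.86` is the severe phenotype's flattened lumen; the diffuse
lower-lobe constriction brings LB10 down to ~3.4 mm so its 10 μm Stokes
number reaches 0.28 — deep in the impaction regime — while the ventilation
ratio `U/(M+L)|v = 0.818` records the apical shift. Running a particle
ensemble (`run_ensemble`, see `examples/04_particle_deposition.py`) then
shows the downstream consequences: small particles distribute like the
ventilation (`U/(M+L)|dist ≈ U/(M+L)|v`), large particles shift toward the
lower lobes, and a focally constricted branch captures most of the 10 μm
particles that enter it (`examples/05_constriction_coupling.py`).

## Examples

| script | capability |
| --- | --- |
| `examples/01_morphometry.py` | Cr / Dave / Dh from printed subject calibres |
| `examples/02_build_synthetic_cohort.py` | generate and save the 4-phenotype cohort |
| `examples/03_flow_partitioning.py` | waveform → flows, Re, Stokes numbers |
| `examples/04_particle_deposition.py` | size-dependent lobar distribution |
| `examples/05_constriction_coupling.py` | constriction ↔ shear ↔ pressure ↔ dose |

Each runs in seconds to a few minutes and prints what its numbers mean.

## Layout

- `src/aerotree/airway_model.py` — tree data model, morphometry, I/O
- `src/aerotree/synthetic_data.py` — phenotype-controlled generator
- `src/aerotree/boundary_conditions.py` — waveform, flow split, Re/Cc/Stk
- `src/aerotree/flow_field.py` — elliptic-Poiseuille field, OU turbulence
  surrogate, Poiseuille wall loads
- `src/aerotree/particle_transport.py` — Lagrangian engine, fates, ensembles
- `src/aerotree/analysis_report.py` — ratios, tables, `run_pipeline`
- `docs/methods.md` — model description, defaults, limitations
- `docs/file_formats.md` — tree/ventilation/config file schemas
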