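# File formats

All on-disk numbers use millimetres / mm² (readability at airway scale);
the in-memory API is SI (m, m², s, kg).

## Airway tree — CSV (`*.csv`)

One row per branch, header exactly:

```
id,name,parent_id,lobe,generation,length_mm,x,y,z,dx,dy,dz,Ac_prox_mm2,Pe_prox_mm,Ac_dist_mm2,Pe_dist_mm
```

| column | meaning |
| --- | --- |
| `id` | unique branch token |
| `name` | anatomical label (may equal `id`; empty allowed) |
| `parent_id` | parent token; **empty marks the root** |
| `lobe` | `RUL`, `RML`, `RLL`, `LUL`, `LLL` or `none` (central airways); terminal branches must carry a lobe |
| `generation` | integer depth, trachea = 0 |
| `length_mm` | branch length |
| `x,y,z` | proximal end point (mm); `+x` left, `+y` anterior, `+z` inferior |
| `dx,dy,dz` | unit axis vector, pointing distally |
| `Ac_*_mm2`, `Pe_*_mm` | lumen area and perimeter at the proximal / distal station |

The CSV carries exactly two stations per branch and loses analytic ellipse
axes; values survive a round-trip to double precision. Parsing errors name
the offending row and field.

## Airway tree — JSON (`*.json`)

Lossless form: full float precision, any number of stations, optional
ellipse semi-axes. Top level:

```json
{"format": "aerotree-tree", "version": 1, "root_id": "Trachea",
 "branches": [{"id": "...", "name": "...", "parent_id": null,
               "lobe": "none", "generation": 0, "length_m": 0.054,
               "origin_m": [0,0,0], "direction": [0,0,1],
               "cross_sections": [{"area_m2": 2.5e-4, "perimeter_m": 0.057,
                                   "station": 0.0,
                                   "semi_major_m": 9.3e-3,
                                   "semi_minor_m": 8.7e-3}]}]}
```

`write_tree` → `read_tree` round-trips a tree field-for-field through JSON.

## Lobar air-volume change — CSV

```
lobe,delta_v_L
RUL,0.516...
```

Litres of air-volume change between the two inflation levels, one row per
lobe, all five lobes present, values ≥ 0, sum > 0.

## Flow solution — CSV

`branch_id,Q_m3s,Re,u_mean_ms` — per-branch flow rate, Reynolds number and
mid-branch mean axial speed.

## Run configuration — YAML

Accepted by `run_pipeline` (all keys optional; defaults are the study
conditions):

```yaml
phenotypes: [healthy_1, healthy_2, severe_cr, severe_cr_dh]
fluid: {rho_f: 1.12, nu_f: 1.64e-5}
waveform: {tidal_volume_L: 0.5, period_s: 4.8}
particles: {diameters_um: [2.5, 5.0, 10.0], rho_p: 1000.0,
            mean_free_path_nm: 68.0, alpha: 1.0}
release: {n_particles: 10000, n_releases: 9}
turbulence: {intensity: 0.29, eddy_length_mm: 8.0}
total_dv_L: 3.33
```

`run_pipeline` writes per-phenotype tree/flow/morphometry/deposition CSVs,
an `uml_ratios.csv` table, and `manifest.json` recording every seed and
parameter needed to reproduce the run byte-for-byte.
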