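"""Derived quantities, comparison tables and end-to-end pipeline.

Gathers the study's reported quantities from the simulation outputs:

* pulmonary-function ratios (FEV1/FVC as integer percent),
* the apical ventilation-shift ratio U/(M+L)|v and its particle analogue
  U/(M+L)|dist per particle size,
* morphometry tables (Cr, Dave, Dh per named branch),
* deposition efficiency of daughter branches against the Stokes number of
  their parent, and
* the constriction-coupling table relating 1/Dh to wall shear stress,
  pressure drop and deposition (Spearman rank correlations — the claim is
  an ordering, not a linear fit).

``run_pipeline`` orchestrates generation, flow, transport and reporting for
a set of phenotypes and writes CSV/JSON artifacts plus a manifest that makes
the run reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml
from scipy.stats import spearmanr

from .airway_model import (
    AirwayTree,
    UPPER_LOBES,
    LOWER_AND_MIDDLE_LOBES,
    compute_cr,
    compute_dave,
    compute_dh,
    section_at,
    write_tree,
)
from .boundary_conditions import (
    DEFAULT_FLUID,
    FluidProperties,
    FlowSolution,
    cunningham,
    flow_solution,
    peak_flow,
    stokes_number,
)
from .flow_field import TurbulenceSurrogate, pressure_drop, wall_shear_stress
from .particle_transport import (
    DepositionSummary,
    ReleaseSpec,
    TransportConfig,
    run_ensemble,
)
from .synthetic_data import (
    DEFAULT_TOTAL_DV_L,
    PHENOTYPES,
    BreathingWaveform,
    generate_tree,
    generate_volume_change,
)

__all__ = [
    "SubjectRecord",
    "LobarRatios",
    "TABLE_SUBJECTS",
    "fev1_fvc_ratio",
    "uml_ratio",
    "morphometry_table",
    "efficiency_vs_stk",
    "constriction_coupling_table",
    "run_pipeline",
]


@dataclass(frozen=True)
class SubjectRecord:
    """Spirometry and CT air volumes of one subject (litres)."""

    label: str
    fev1_baseline_L: float
    fvc_baseline_L: float
    fev1_maximal_L: float
    fvc_maximal_L: float
    tlc_L: float
    frc_L: float

    def __post_init__(self) -> None:
        for fev1, fvc in (
            (self.fev1_baseline_L, self.fvc_baseline_L),
            (self.fev1_maximal_L, self.fvc_maximal_L),
        ):
            if not (fvc >= fev1 > 0.0):
                raise ValueError(f"{self.label}: require FVC >= FEV1 > 0")
        if not (self.tlc_L > self.frc_L > 0.0):
            raise ValueError(f"{self.label}: require TLC > FRC > 0")

    @property
    def delta_v_L(self) -> float:
        return self.tlc_L - self.frc_L


#: The four study subjects' printed lung-function and CT air volumes.
TABLE_SUBJECTS: Dict[str, SubjectRecord] = {
    "HS 1": SubjectRecord("HS 1", 2.97, 3.82, 3.36, 4.04, 5.37, 2.04),
    "HS 2": SubjectRecord("HS 2", 3.15, 4.00, 3.17, 3.94, 4.31, 1.79),
    "SA 1": SubjectRecord("SA 1", 1.19, 1.83, 2.05, 2.97, 5.64, 2.85),
    "SA 2": SubjectRecord("SA 2", 1.02, 2.52, 1.17, 3.11, 4.33, 1.77),
}


def fev1_fvc_ratio(s: SubjectRecord, phase: str = "baseline") -> int:
    """FEV1/FVC as integer percent (round half-up, matching the tables)."""
    if phase == "baseline":
        fev1, fvc = s.fev1_baseline_L, s.fvc_baseline_L
    elif phase == "maximal":
        fev1, fvc = s.fev1_maximal_L, s.fvc_maximal_L
    else:
        raise ValueError("phase must be 'baseline' or 'maximal'")
    return int(math.floor(100.0 * fev1 / fvc + 0.5))


def uml_ratio(values_per_lobe: Mapping[str, float]) -> float:
    """(RUL+LUL)/(RML+RLL+LLL) of any per-lobe quantity."""
    upper = sum(values_per_lobe[lb] for lb in UPPER_LOBES)
    rest = sum(values_per_lobe[lb] for lb in LOWER_AND_MIDDLE_LOBES)
    if rest <= 0.0:
        raise ZeroDivisionError("middle+lower denominator is zero")
    return upper / rest


@dataclass(frozen=True)
class LobarRatios:
    """Ventilation-shift ratio and its particle-distribution analogues."""

    uml_v: float
    uml_dist: Mapping[float, float]  # diameter (m) -> U/(M+L)|dist


def morphometry_table(
    tree: AirwayTree, names: Optional[Sequence[str]] = None, station: float = 0.5
) -> pd.DataFrame:
    """Cr / Dave / Dh (mm) per named branch at the given station."""
    rows = []
    for bid in tree.topological_order():
        b = tree.branches[bid]
        if names is not None and b.name not in names:
            continue
        cs = section_at(b, station)
        rows.append(
            {
                "branch": b.name or b.id,
                "lobe": b.lobe,
                "generation": b.generation,
                "Cr": compute_cr(cs),
                "Dave_mm": compute_dave(cs) * 1e3,
                "Dh_mm": compute_dh(cs) * 1e3,
            }
        )
    return pd.DataFrame(rows).set_index("branch")


def efficiency_vs_stk(
    summary: DepositionSummary,
    flow: FlowSolution,
    tree: AirwayTree,
    pairs: Sequence[Tuple[str, str]],
    fluid: FluidProperties = DEFAULT_FLUID,
    rho_p: float = 1000.0,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Daughter deposition efficiency against parent-branch Stokes number.

    ``pairs`` lists (parent_name, daughter_name); one row per (pair, size),
    sorted by Stk.
    """
    rows = []
    for d in summary.tallies:
        for parent_name, child_name in pairs:
            pid = tree.find_by_name(parent_name)
            cid = tree.find_by_name(child_name)
            mid = section_at(tree.branches[pid], 0.5)
            stk = stokes_number(
                flow.Q_branch[pid], compute_dave(mid), d, rho_p, fluid.mu_f,
                cunningham(d) if d > 0 else 1.0, alpha,
            )
            row = summary.branch_table.loc[(d * 1e6, cid)]
            rows.append(
                {
                    "parent": parent_name,
                    "daughter": child_name,
                    "diameter_um": d * 1e6,
                    "Stk_parent": stk,
                    "efficiency": row["efficiency_mean"],
                    "efficiency_sd": row["efficiency_sd"],
                }
            )
    return pd.DataFrame(rows).sort_values("Stk_parent").reset_index(drop=True)


def constriction_coupling_table(
    tree: AirwayTree,
    flow: FlowSolution,
    summary: DepositionSummary,
    diameter: float,
    fluid: FluidProperties = DEFAULT_FLUID,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-branch Dave/Dh/tau_w/dP/deposition plus rank correlations.

    Returns the table and the Spearman correlations of 1/Dh with wall shear
    stress, pressure drop and per-branch deposition efficiency
    (deposited/entering — the per-branch quantity that isolates constriction
    from how many particles happen to reach a branch). Zero-variance columns
    yield NaN correlations (reported as undefined, not as zero).
    """
    rows = []
    for bid in tree.topological_order():
        b = tree.branches[bid]
        cs = section_at(b, 0.5)
        dave = compute_dave(cs)
        Q = flow.Q_branch[bid]
        row = summary.branch_table.loc[(diameter * 1e6, bid)]
        rows.append(
            {
                "branch": b.name or bid,
                "lobe": b.lobe,
                "Dave_mm": dave * 1e3,
                "Dh_mm": compute_dh(cs) * 1e3,
                "tau_w_Pa": wall_shear_stress(Q, dave, fluid.mu_f),
                "dP_Pa": pressure_drop(Q, dave, b.length, fluid.mu_f),
                "deposited_mean": row["deposited_mean"],
                "deposition_fraction": row["deposited_mean"]
                / summary.released_per_release,
                "deposition_efficiency": row["efficiency_mean"],
            }
        )
    table = pd.DataFrame(rows).set_index("branch")
    inv_dh = 1.0 / table["Dh_mm"]
    corrs: Dict[str, float] = {}
    for col in ("tau_w_Pa", "dP_Pa", "deposition_efficiency"):
        y = table[col]
        m = y.notna()
        if inv_dh[m].nunique() <= 1 or y[m].nunique() <= 1:
            corrs[col] = float("nan")
        else:
            corrs[col] = float(spearmanr(inv_dh[m], y[m]).statistic)
    return table, corrs


# -- pipeline --------------------------------------------------------------

_DEFAULT_CONFIG: dict = {
    "phenotypes": ["healthy_1", "healthy_2", "severe_cr", "severe_cr_dh"],
    "fluid": {"rho_f": 1.12, "nu_f": 1.64e-5},
    "waveform": {"tidal_volume_L": 0.5, "period_s": 4.8},
    "particles": {
        "diameters_um": [2.5, 5.0, 10.0],
        "rho_p": 1000.0,
        "mean_free_path_nm": 68.0,
        "alpha": 1.0,
    },
    "release": {"n_particles": 10000, "n_releases": 9},
    "turbulence": {"intensity": 0.29, "eddy_length_mm": 8.0},
    "total_dv_L": DEFAULT_TOTAL_DV_L,
    "efficiency_pairs": [
        ["RMB", "TriRUL"],
        ["RB9+10", "RB9"],
        ["RB9+10", "RB10"],
        ["LB10", "LB10a"],
        ["LB10", "LB10b"],
    ],
}


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(
    config: Optional[Mapping | str | Path] = None,
    out_dir: str | Path = "aerotree_out",
    seed: int = 0,
) -> dict:
    """Generate, solve, transport and report for all configured phenotypes.

    Returns the manifest dict (also written to ``manifest.json``). Outputs:
    per-phenotype tree files, flow CSV, lobe and branch summaries,
    morphometry table, U/(M+L) table, efficiency-vs-Stk table and the
    constriction-coupling table. Fully reproducible from the manifest.
    """
    if config is None:
        cfg = dict(_DEFAULT_CONFIG)
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = _merge(_DEFAULT_CONFIG, yaml.safe_load(fh) or {})
    else:
        cfg = _merge(_DEFAULT_CONFIG, config)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fluid = FluidProperties(**cfg["fluid"])
    waveform = BreathingWaveform(
        tidal_volume_L=cfg["waveform"]["tidal_volume_L"],
        period_s=cfg["waveform"]["period_s"],
    )
    diameters = tuple(d * 1e-6 for d in cfg["particles"]["diameters_um"])
    turb = None
    if cfg.get("turbulence"):
        turb = TurbulenceSurrogate(
            intensity=cfg["turbulence"]["intensity"],
            eddy_length=cfg["turbulence"]["eddy_length_mm"] * 1e-3,
            seed=seed,
        )
    tcfg = TransportConfig(
        rho_p=cfg["particles"]["rho_p"],
        mean_free_path=cfg["particles"]["mean_free_path_nm"] * 1e-9,
        alpha=cfg["particles"]["alpha"],
        turbulence=turb,
    )

    uml_rows = []
    all_warnings: Dict[str, List[str]] = {}
    for i, phen_name in enumerate(cfg["phenotypes"]):
        try:
            spec = PHENOTYPES[phen_name]
        except KeyError as exc:
            raise ValueError(
                f"stage 'generate': unknown phenotype {phen_name!r}"
            ) from exc
        spec = replace(spec, seed=spec.seed + 1000 * seed)
        tree = generate_tree(spec)
        dv = generate_volume_change(spec, cfg["total_dv_L"])
        flow = flow_solution(tree, dv, waveform=waveform, fluid=fluid)

        write_tree(tree, out / f"tree_{phen_name}.json")
        write_tree(tree, out / f"tree_{phen_name}.csv")
        pd.DataFrame(
            {"lobe": list(dv.delta_v_L), "delta_v_L": list(dv.delta_v_L.values())}
        ).to_csv(out / f"volume_change_{phen_name}.csv", index=False)
        pd.DataFrame(
            {
                "branch_id": list(flow.Q_branch),
                "Q_m3s": list(flow.Q_branch.values()),
                "Re": [flow.Re_branch[b] for b in flow.Q_branch],
                "u_mean_ms": [flow.u_mean_branch[b] for b in flow.Q_branch],
            }
        ).to_csv(out / f"flow_{phen_name}.csv", index=False)
        morphometry_table(tree).to_csv(out / f"morphometry_{phen_name}.csv")

        rs = ReleaseSpec(
            n_particles=cfg["release"]["n_particles"],
            n_releases=cfg["release"]["n_releases"],
            diameters=diameters,
            rng_seed=seed * 100 + i,
        )
        summary = run_ensemble(tree, flow, rs, tcfg, fluid)
        all_warnings[phen_name] = summary.warnings
        summary.branch_table.to_csv(out / f"deposition_branch_{phen_name}.csv")
        summary.lobe_table.to_csv(out / f"deposition_lobe_{phen_name}.csv")
        eff = efficiency_vs_stk(
            summary, flow, tree,
            [tuple(p) for p in cfg["efficiency_pairs"]],
            fluid, cfg["particles"]["rho_p"], cfg["particles"]["alpha"],
        )
        eff.to_csv(out / f"efficiency_vs_stk_{phen_name}.csv", index=False)
        table, corrs = constriction_coupling_table(
            tree, flow, summary, max(diameters), fluid
        )
        table.to_csv(out / f"constriction_coupling_{phen_name}.csv")
        with open(out / f"coupling_correlations_{phen_name}.json", "w") as fh:
            json.dump(corrs, fh, indent=1)

        for d in diameters:
            uml_rows.append(
                {
                    "phenotype": phen_name,
                    "diameter_um": d * 1e6,
                    "uml_v": dv.uml_ratio,
                    "uml_dist": summary.uml_dist(d),
                }
            )
    uml = pd.DataFrame(uml_rows)
    uml.to_csv(out / "uml_ratios.csv", index=False)

    manifest = {
        "seed": seed,
        "config": cfg,
        "Q_in_m3s": peak_flow(waveform),
        "phenotype_seeds": {
            name: PHENOTYPES[name].seed + 1000 * seed for name in cfg["phenotypes"]
        },
        "release_seeds": {
            name: seed * 100 + i for i, name in enumerate(cfg["phenotypes"])
        },
        "warnings": all_warnings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
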