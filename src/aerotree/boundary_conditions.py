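"""Ventilation-derived flow partitioning, Reynolds and Stokes numbers.

The flow split is ventilation-prescribed: the per-lobe air-volume change
between the two inflation levels fixes the fraction of inspiratory flow
leaving through each terminal branch, and internal branch flow rates follow
by mass conservation. There is no pressure-driven (resistance-network)
solution — the split, not the pressures, drives every regional result.

Particle inertia is summarised by the branch Stokes number

    Stk = 2 Q rho_p d^2 Cc alpha^3.7 / (9 pi mu_f Dave^3),

algebraically equal to tau_p * U / Dave with relaxation time
tau_p = rho_p d^2 Cc / (18 mu_f) and mean speed U = 4Q/(pi Dave^2) when the
particle-particle interaction factor alpha is 1 (dilute aerosol). Cc is the
Cunningham slip correction, relevant once particle size approaches the gas
mean free path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

from .airway_model import AirwayTree, compute_dave, section_at
from .synthetic_data import BreathingWaveform, LobarVolumeChange

__all__ = [
    "FluidProperties",
    "FlowSolution",
    "StokesContext",
    "ConfigurationError",
    "DEFAULT_FLUID",
    "DEFAULT_RHO_P",
    "DEFAULT_MEAN_FREE_PATH",
    "peak_flow",
    "terminal_flow_fractions",
    "propagate_flows",
    "flow_solution",
    "reynolds",
    "cunningham",
    "relaxation_time",
    "stokes_number",
    "stokes_context",
]


class ConfigurationError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


@dataclass(frozen=True)
class FluidProperties:
    """Air properties: density (kg/m³) and kinematic viscosity (m²/s)."""

    rho_f: float = 1.12
    nu_f: float = 1.64e-5

    def __post_init__(self) -> None:
        if not (self.rho_f > 0.0 and self.nu_f > 0.0):
            raise ValueError("fluid properties must be positive")

    @property
    def mu_f(self) -> float:
        """Dynamic viscosity (Pa·s), rho_f * nu_f by definition."""
        return self.rho_f * self.nu_f


DEFAULT_FLUID = FluidProperties()
#: Aerosol density (kg/m³) and air mean free path (m).
DEFAULT_RHO_P = 1000.0
DEFAULT_MEAN_FREE_PATH = 68e-9


def peak_flow(w: BreathingWaveform) -> float:
    """Peak inspiratory flow (m³/s) of a sinusoidal breath.

    Inspiration delivers the tidal volume over half a period with
    Q(t) = Q_peak sin(2 pi t / T), hence Q_peak = pi * TV / T.
    For TV 0.5 L, T 4.8 s this is 3.27e-4 m³/s (~20 L/min).
    """
    return math.pi * w.tidal_volume_L * 1e-3 / w.period_s


def terminal_flow_fractions(
    tree: AirwayTree, dv: LobarVolumeChange
) -> Dict[str, float]:
    """Fraction of inlet flow leaving through each terminal branch.

    Each lobe's air-volume change is split equally among that lobe's
    terminal branches (uniform intra-lobe ventilation), preserving the lobar
    ratios that the ventilation table prescribes. Fractions sum to 1.
    """
    lobe_terms = tree.lobe_terminals()
    total = dv.total_L
    fractions: Dict[str, float] = {}
    for lobe, terms in lobe_terms.items():
        dv_lobe = dv.delta_v_L[lobe]
        if dv_lobe > 0.0 and not terms:
            raise ConfigurationError(
                f"lobe {lobe} has volume change {dv_lobe} L but no terminal branches"
            )
        for t in terms:
            fractions[t] = dv_lobe / total / len(terms)
    return fractions


@dataclass(frozen=True)
class FlowSolution:
    """Per-branch steady flow state derived from the terminal fractions."""

    Q_branch: Mapping[str, float]       # m³/s
    f_terminal: Mapping[str, float]     # dimensionless, sums to 1
    Re_branch: Mapping[str, float]
    u_mean_branch: Mapping[str, float]  # m/s, mid-branch mean axial speed
    Q_in: float


def propagate_flows(
    tree: AirwayTree,
    fractions: Mapping[str, float],
    Q_in: float,
    fluid: FluidProperties = DEFAULT_FLUID,
) -> FlowSolution:
    """Distribute the inlet flow over the tree by bottom-up summation.

    Terminal branches carry ``fraction * Q_in``; every internal branch
    carries the sum of its children; the root carries ``Q_in`` exactly
    (enforced by construction of the fractions).
    """
    fsum = sum(fractions.values())
    if abs(fsum - 1.0) > 1e-9:
        raise ConfigurationError(f"terminal fractions sum to {fsum}, expected 1")
    Q: Dict[str, float] = {}
    for bid in reversed(tree.topological_order()):
        kids = tree.children(bid)
        if not kids:
            Q[bid] = fractions.get(bid, 0.0) * Q_in
        else:
            Q[bid] = sum(Q[k] for k in kids)
    u_mean: Dict[str, float] = {}
    Re: Dict[str, float] = {}
    for bid, b in tree.branches.items():
        mid = section_at(b, 0.5)
        u_mean[bid] = Q[bid] / mid.area
        Re[bid] = reynolds(Q[bid], compute_dave(mid), fluid.nu_f)
    return FlowSolution(
        Q_branch=Q, f_terminal=dict(fractions), Re_branch=Re,
        u_mean_branch=u_mean, Q_in=Q_in,
    )


def flow_solution(
    tree: AirwayTree,
    dv: LobarVolumeChange,
    waveform: Optional[BreathingWaveform] = None,
    Q_in: Optional[float] = None,
    fluid: FluidProperties = DEFAULT_FLUID,
) -> FlowSolution:
    """Convenience: fractions from the ventilation table, Q_in from the waveform."""
    if Q_in is None:
        if waveform is None:
            waveform = BreathingWaveform()
        Q_in = peak_flow(waveform)
    fractions = terminal_flow_fractions(tree, dv)
    return propagate_flows(tree, fractions, Q_in, fluid)


def reynolds(Q: float, dave: float, nu_f: float) -> float:
    """Branch Reynolds number, Re = u_mean Dave / nu = 4Q/(pi Dave nu)."""
    if dave <= 0.0 or nu_f <= 0.0:
        raise ValueError("dave and nu_f must be positive")
    return 4.0 * Q / (math.pi * dave * nu_f)


def cunningham(d_p: float, mean_free_path: float = DEFAULT_MEAN_FREE_PATH) -> float:
    """Cunningham slip correction, classical three-constant form.

    Cc = 1 + Kn (1.257 + 0.4 exp(-1.1/Kn)), Kn = 2 lambda / d_p.
    ~1.017 for a 10 um particle in air (lambda = 68 nm); grows steeply as
    d_p approaches the mean free path.
    """
    if not d_p > 0.0:
        raise ValueError("particle diameter must be positive")
    kn = 2.0 * mean_free_path / d_p
    return 1.0 + kn * (1.257 + 0.4 * math.exp(-1.1 / kn))


def relaxation_time(
    d_p: float,
    rho_p: float = DEFAULT_RHO_P,
    mu_f: float = DEFAULT_FLUID.mu_f,
    Cc: Optional[float] = None,
    mean_free_path: float = DEFAULT_MEAN_FREE_PATH,
) -> float:
    """Particle relaxation time tau_p = rho_p d^2 Cc / (18 mu_f); 0 for d_p = 0."""
    if d_p == 0.0:
        return 0.0
    if Cc is None:
        Cc = cunningham(d_p, mean_free_path)
    return rho_p * d_p**2 * Cc / (18.0 * mu_f)


def stokes_number(
    Q: float,
    dave: float,
    d_p: float,
    rho_p: float = DEFAULT_RHO_P,
    mu_f: float = DEFAULT_FLUID.mu_f,
    Cc: Optional[float] = None,
    alpha: float = 1.0,
    mean_free_path: float = DEFAULT_MEAN_FREE_PATH,
) -> float:
    """Branch Stokes number Stk = 2 Q rho_p d^2 Cc alpha^3.7 / (9 pi mu_f Dave^3).

    Scales as d_p² and as 1/Dave³ at fixed flow — the reason a constricted
    branch multiplies impaction. Zero for d_p = 0 (tracer limit).
    """
    if dave <= 0.0 or mu_f <= 0.0:
        raise ValueError("dave and mu_f must be positive")
    if d_p == 0.0:
        return 0.0
    if Cc is None:
        Cc = cunningham(d_p, mean_free_path)
    return 2.0 * Q * rho_p * d_p**2 * Cc * alpha**3.7 / (9.0 * math.pi * mu_f * dave**3)


@dataclass(frozen=True)
class StokesContext:
    """Stokes number of a given particle size in a given branch."""

    branch_id: str
    d_p: float
    Stk: float
    Cc: float
    alpha: float = 1.0


def stokes_context(
    tree: AirwayTree,
    flow: FlowSolution,
    branch_id: str,
    d_p: float,
    rho_p: float = DEFAULT_RHO_P,
    fluid: FluidProperties = DEFAULT_FLUID,
    alpha: float = 1.0,
    mean_free_path: float = DEFAULT_MEAN_FREE_PATH,
) -> StokesContext:
    mid = section_at(tree.branches[branch_id], 0.5)
    Cc = cunningham(d_p, mean_free_path) if d_p > 0.0 else 1.0
    stk = stokes_number(
        flow.Q_branch[branch_id], compute_dave(mid), d_p, rho_p,
        fluid.mu_f, Cc, alpha,
    )
    return StokesContext(branch_id=branch_id, d_p=d_p, Stk=stk, Cc=Cc, alpha=alpha)
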