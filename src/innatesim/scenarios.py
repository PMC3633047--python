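"""Standard parameterization, initial condition and the five-case ladder.

The shipped numbers parameterize the innate response of a generic 5 mm
strip of vascularized tissue to an intradermal LPS bolus.  Diffusion and
chemotaxis coefficients are tabulated in the literature in um^2/day and are
converted here to mm^2/day (x 1e-6).  Concentrations are in the model unit
(1e4 cells/mm^3, used as a label only).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model_core import ParameterSet, ScenarioFlags
from .numerics import Grid, TissueState

__all__ = [
    "CaseDefinition",
    "default_parameters",
    "initial_state",
    "build_case",
    "PROVENANCE",
    "UM2_TO_MM2",
]

#: 1 mm^2 = 1e6 um^2.
UM2_TO_MM2 = 1e-6

#: Where each default value comes from: "literature", "estimated" (adjusted
#: to qualitatively reproduce published LPS-response time courses) or
#: "adjusted" (literature value rescaled to these units / this domain).
#: Metadata only; nothing computational depends on it.
PROVENANCE = {
    "mu_LPS": "literature",
    "phi_RM_LPS": "adjusted",
    "theta_AC": "estimated",
    "lambda_N_LPS": "literature",
    "lambda_AM_LPS": "literature",
    "D_LPS": "estimated",
    "D_RM": "literature",
    "D_AM": "literature",
    "D_CH": "literature",
    "D_N": "literature",
    "D_ND": "adjusted",
    "D_G": "estimated",
    "D_AC": "literature",
    "chi_RM": "literature",
    "chi_AM": "literature",
    "chi_N": "literature",
    "P_RM_max": "estimated",
    "P_RM_min": "estimated",
    "Q_RM_max": "estimated",
    "Q_RM_min": "estimated",
    "P_N_max": "adjusted",
    "P_N_min": "estimated",
    "keq_ch": "estimated",
    "keq_g": "estimated",
    "M_max": "estimated",
    "N_max": "estimated",
    "mu_RM": "literature",
    "mu_AM": "literature",
    "mu_N": "literature",
    "mu_CH": "adjusted",
    "mu_G": "estimated",
    "mu_AC": "estimated",
    "beta_CH_N": "literature",
    "beta_CH_AM": "literature",
    "ch_inf": "adjusted",
    "lambda_LPS_N": "literature",
    "lambda_ND_AM": "literature",
    "alpha_G_N": "estimated",
    "g_inf": "estimated",
    "beta_RM_ND": "estimated",
    "alpha_AC_AM": "estimated",
    "ac_inf": "adjusted",
}


def default_parameters() -> ParameterSet:
    """The standard parameter set (rates per day, lengths in mm)."""
    return ParameterSet(
        mu_LPS=0.005,
        phi_RM_LPS=0.1,
        theta_AC=1.0,
        lambda_N_LPS=0.55,
        lambda_AM_LPS=0.8,
        D_LPS=2000 * UM2_TO_MM2,
        D_RM=4320 * UM2_TO_MM2,
        D_AM=3000 * UM2_TO_MM2,
        D_CH=9216 * UM2_TO_MM2,
        D_N=12096 * UM2_TO_MM2,
        D_ND=0.144 * UM2_TO_MM2,
        D_G=9216 * UM2_TO_MM2,
        D_AC=9216 * UM2_TO_MM2,
        chi_RM=3600 * UM2_TO_MM2,
        chi_AM=4320 * UM2_TO_MM2,
        chi_N=14400 * UM2_TO_MM2,
        P_RM_max=0.1,
        P_RM_min=0.01,
        Q_RM_max=0.5,
        Q_RM_min=0.0,
        P_N_max=11.4,
        P_N_min=0.0001,
        keq_ch=1.0,
        keq_g=1.0,
        M_max=6.0,
        N_max=8.0,
        mu_RM=0.033,
        mu_AM=0.07,
        mu_N=3.43,
        mu_CH=7.0,
        mu_G=5.0,
        mu_AC=4.0,
        beta_CH_N=1.0,
        beta_CH_AM=0.8,
        ch_inf=3.6,
        lambda_LPS_N=0.55,
        lambda_ND_AM=2.6,
        alpha_G_N=0.6,
        g_inf=3.1,
        beta_RM_ND=1.5,
        alpha_AC_AM=1.5,
        ac_inf=3.6,
    )


#: Amplitude of the injected LPS bolus (conc) and its extent (mm).
LPS0 = 100.0
BOLUS_END = 1.0
#: Uniform resting-macrophage background (conc).
RM0 = 1.0


def initial_state(grid: Grid) -> TissueState:
    """Initial condition: LPS bolus on [0, 1) mm, RM = 1 everywhere.

    The bolus interval is half-open: the node at exactly x = 1 mm carries
    the outside value 0.  All other species start at zero.
    """
    s = TissueState.zeros(grid)
    x = grid.x
    s.species("lps")[:] = np.where(x < BOLUS_END - 1e-9, LPS0, 0.0)
    s.species("rm")[:] = RM0
    return s


@dataclasses.dataclass(frozen=True)
class CaseDefinition:
    """One rung of the ablation ladder: flags plus optional overrides."""

    case: int
    description: str
    flags: ScenarioFlags
    overrides: dict = dataclasses.field(default_factory=dict)


_DESCRIPTIONS = {
    1: "only macrophages respond; monocyte influx at minimum permeability",
    2: "adds pro-inflammatory cytokine dynamics: production by active "
       "macrophages, permeability increase and chemotaxis",
    3: "adds neutrophils (phagocytosis, cytokine production) and the "
       "apoptotic-neutrophil pool",
    4: "adds protein granules and their monocyte-permeability channel",
    5: "adds anti-inflammatory cytokines blocking cytokine production "
       "and macrophage activation (full model)",
}


def build_case(case: int) -> CaseDefinition:
    """Return one of the five shipped scenario definitions (strictly nested)."""
    if case not in _DESCRIPTIONS:
        raise ValueError(f"case must be in 1..5, got {case!r}")
    return CaseDefinition(
        case=case,
        description=_DESCRIPTIONS[case],
        flags=ScenarioFlags.from_case(case),
    )
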