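"""Pointwise reaction kinetics of an LPS-driven acute-inflammation model.

The model follows eight interacting species in a strip of tissue after a
local injection of lipopolysaccharide (LPS), the endotoxin of Gram-negative
bacterial walls:

======  =======================================================
symbol  species
======  =======================================================
LPS     lipopolysaccharide (the immunogenic stimulus)
RM      resting (tissue-resident) macrophages
AM      hyperactivated macrophages
CH      pro-inflammatory cytokines (TNF-alpha / IL-8 class)
N       neutrophils
ND      apoptotic neutrophils
G       neutrophil protein granules
AC      anti-inflammatory cytokines (IL-10 / TGF-beta class)
======  =======================================================

The tissue is *homogenized*: every point exchanges leukocytes with an
overlying vascular compartment through an endothelium whose permeability is
a Hill function of the local pro-inflammatory cytokine (and, for monocytes,
protein granule) concentration.  Extravasation is therefore a distributed
source term ``permeability * (vascular pool - tissue concentration)`` rather
than a boundary flux.

This module holds the *local* (non-spatial) kinetics only: activation,
phagocytosis, cytokine production with saturation and anti-inflammatory
inhibition, and the Hill-type extravasation sources.  Diffusion and
chemotaxis live in :mod:`innatesim.numerics`.

Units
-----
Concentrations are expressed in the model's concentration unit
(1 unit = 1e4 cells/mm^3, carried as a label only -- all arithmetic uses the
raw tabulated numbers), lengths in mm, time in days.  All rate parameters
are per day; second-order rates are per (concentration * day).
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np

__all__ = [
    "SPECIES",
    "ParameterSet",
    "ScenarioFlags",
    "PointState",
    "ReactionRates",
    "hill_response",
    "rm_activation",
    "monocyte_source",
    "neutrophil_source",
    "reaction_terms",
]

#: Canonical species ordering used by every array-valued container.
SPECIES = ("lps", "rm", "am", "ch", "n", "nd", "g", "ac")


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """Every rate and coefficient of the eight balance equations.

    Attributes are named after the field's conventional symbols.  The
    constructor validates non-negativity, finiteness, the ordering of the
    permeability bounds and the positivity of the half-saturation and
    carrying-capacity constants.
    """

    # LPS kinetics
    mu_LPS: float  # 1/day, LPS decay
    phi_RM_LPS: float  # 1/(conc day), resting-macrophage activation by LPS
    theta_AC: float  # 1/conc, anti-inflammatory inhibition strength
    lambda_N_LPS: float  # 1/(conc day), LPS phagocytosis by neutrophils
    lambda_AM_LPS: float  # 1/(conc day), LPS phagocytosis by active macrophages
    # diffusion coefficients, mm^2/day
    D_LPS: float
    D_RM: float
    D_AM: float
    D_CH: float
    D_N: float
    D_ND: float
    D_G: float
    D_AC: float
    # chemotaxis coefficients, mm^2/day
    chi_RM: float
    chi_AM: float
    chi_N: float
    # endothelium permeability bounds, 1/day
    P_RM_max: float  # CH-driven monocyte permeability
    P_RM_min: float
    Q_RM_max: float  # granule-driven monocyte permeability
    Q_RM_min: float
    P_N_max: float  # CH-driven neutrophil permeability
    P_N_min: float
    # half-saturation constants, conc
    keq_ch: float
    keq_g: float
    # vascular availability, conc
    M_max: float  # monocytes in the blood
    N_max: float  # neutrophils in the blood
    # apoptosis / decay rates, 1/day
    mu_RM: float
    mu_AM: float
    mu_N: float
    mu_CH: float
    mu_G: float
    mu_AC: float
    # pro-inflammatory cytokine production
    beta_CH_N: float  # 1/(conc day), production by neutrophils
    beta_CH_AM: float  # 1/(conc day), production by active macrophages
    ch_inf: float  # conc, CH carrying capacity
    # neutrophil fate
    lambda_LPS_N: float  # 1/(conc day), phagocytosis-induced apoptosis
    lambda_ND_AM: float  # 1/(conc day), efferocytosis by active macrophages
    # protein granules
    alpha_G_N: float  # dimensionless, granule release per extravasated neutrophil
    g_inf: float  # conc, granule carrying capacity
    # anti-inflammatory cytokines
    beta_RM_ND: float  # 1/(conc day), production by RM contacting apoptotic N
    alpha_AC_AM: float  # 1/day, production by active macrophages
    ac_inf: float  # conc, AC carrying capacity

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v!r}")
        if self.P_RM_max < self.P_RM_min:
            raise ValueError("P_RM_max must be >= P_RM_min")
        if self.Q_RM_max < self.Q_RM_min:
            raise ValueError("Q_RM_max must be >= Q_RM_min")
        if self.P_N_max < self.P_N_min:
            raise ValueError("P_N_max must be >= P_N_min")
        for name in ("keq_ch", "keq_g", "ch_inf", "g_inf", "ac_inf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def as_array(self) -> np.ndarray:
        """Pack the parameters into a flat float64 array in field order."""
        return np.array(dataclasses.astuple(self), dtype=np.float64)

    def replace(self, **changes: float) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    @property
    def diffusion(self) -> np.ndarray:
        """Diffusion coefficients in species order (mm^2/day)."""
        return np.array(
            [self.D_LPS, self.D_RM, self.D_AM, self.D_CH,
             self.D_N, self.D_ND, self.D_G, self.D_AC]
        )


@dataclasses.dataclass(frozen=True)
class ScenarioFlags:
    """Which sub-model of the five-scenario ablation ladder is active.

    Case 1 keeps only macrophages; each later case adds species/terms:
    Case 2 pro-inflammatory cytokine dynamics (permeability effect and
    chemotaxis), Case 3 neutrophils and their apoptotic pool, Case 4
    protein granules and the granule permeability channel, Case 5
    anti-inflammatory cytokines and both inhibition divisors.
    """

    ch_dynamics: bool
    neutrophils: bool
    granules: bool
    anti_inflammatory: bool
    case: int | None = None

    @classmethod
    def from_case(cls, case: int) -> "ScenarioFlags":
        if case not in (1, 2, 3, 4, 5):
            raise ValueError(f"case must be in 1..5, got {case!r}")
        return cls(
            ch_dynamics=case >= 2,
            neutrophils=case >= 3,
            granules=case >= 4,
            anti_inflammatory=case >= 5,
            case=case,
        )

    @property
    def active(self) -> np.ndarray:
        """Boolean mask over SPECIES: which fields evolve (and are read)."""
        return np.array(
            [True, True, True, self.ch_dynamics, self.neutrophils,
             self.neutrophils, self.granules, self.anti_inflammatory]
        )


@dataclasses.dataclass
class PointState:
    """Values of the eight species at one spatial point (or, elementwise,
    on a whole grid -- every field may be a scalar or an ndarray)."""

    lps: float | np.ndarray
    rm: float | np.ndarray
    am: float | np.ndarray
    ch: float | np.ndarray
    n: float | np.ndarray
    nd: float | np.ndarray
    g: float | np.ndarray
    ac: float | np.ndarray

    def as_tuple(self):
        return tuple(getattr(self, name) for name in SPECIES)


class ReactionRates(NamedTuple):
    """d/dt contributions of the local kinetics, in species order."""

    lps: float | np.ndarray
    rm: float | np.ndarray
    am: float | np.ndarray
    ch: float | np.ndarray
    n: float | np.ndarray
    nd: float | np.ndarray
    g: float | np.ndarray
    ac: float | np.ndarray


def hill_response(c, p_max: float, p_min: float, keq: float):
    """Saturating endothelium permeability as a Hill function of ``c``.

    Returns ``(p_max - p_min) * c / (c + keq) + p_min``: the permeability
    rises from ``p_min`` at zero stimulus to ``p_max`` at saturation, with
    half of the maximal effect at ``c = keq``.

    Parameters are a stimulus concentration (conc), the permeability bounds
    (1/day) and the half-saturation constant (conc).  Raises ``ValueError``
    for negative stimulus, non-positive ``keq`` or disordered bounds.
    """
    c = np.asarray(c, dtype=float) if np.ndim(c) else float(c)
    if np.any(np.asarray(c) < 0):
        raise ValueError("stimulus concentration must be >= 0")
    if keq <= 0:
        raise ValueError("keq must be > 0")
    if not (p_max >= p_min >= 0):
        raise ValueError("require p_max >= p_min >= 0")
    return (p_max - p_min) * c / (c + keq) + p_min


def rm_activation(rm, lps, ac, p: ParameterSet):
    """Rate at which resting macrophages become hyperactivated (conc/day).

    Mass-action recognition of LPS by resting macrophages,
    ``phi_RM_LPS * RM * LPS``, inhibited by anti-inflammatory cytokines
    through the divisor ``1 + theta_AC * AC``.
    """
    return p.phi_RM_LPS * rm * lps / (1.0 + p.theta_AC * ac)


def monocyte_source(ch, g, rm, am, p: ParameterSet, f: ScenarioFlags):
    """Monocyte extravasation into the tissue (conc/day).

    Permeability is the sum of a cytokine-driven and a granule-driven Hill
    channel; the influx is proportional to the remaining vascular pool
    ``M_max - (RM + AM)``.  Scenario flags that disable cytokine dynamics or
    granules evaluate the corresponding channel at zero stimulus, leaving
    only its minimum permeability.  The value may be negative when the
    tissue already holds more macrophages than the vascular reference; the
    time stepper's non-negativity guard handles that regime.
    """
    ch = ch * (1.0 if f.ch_dynamics else 0.0)
    g = g * (1.0 if f.granules else 0.0)
    rm_p = hill_response(ch, p.P_RM_max, p.P_RM_min, p.keq_ch)
    rm_q = hill_response(g, p.Q_RM_max, p.Q_RM_min, p.keq_g)
    return (rm_p + rm_q) * (p.M_max - (rm + am))


def neutrophil_source(ch, n, p: ParameterSet):
    """Neutrophil extravasation into the tissue (conc/day)."""
    return hill_response(ch, p.P_N_max, p.P_N_min, p.keq_ch) * (p.N_max - n)


def reaction_terms(s: PointState, p: ParameterSet, f: ScenarioFlags) -> ReactionRates:
    """Local d/dt of all eight species, excluding diffusion and chemotaxis.

    Species disabled by the scenario flags have rate zero and contribute
    zero to every other balance (their values are read as zero).  Raises
    ``ValueError`` on non-finite input.
    """
    vals = s.as_tuple()
    for name, v in zip(SPECIES, vals):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite value in species {name!r}")

    on = dict(zip(SPECIES, f.active))
    lps, rm, am = s.lps, s.rm, s.am
    ch = s.ch * (1.0 if on["ch"] else 0.0)
    n = s.n * (1.0 if on["n"] else 0.0)
    nd = s.nd * (1.0 if on["nd"] else 0.0)
    g = s.g * (1.0 if on["g"] else 0.0)
    ac = s.ac * (1.0 if on["ac"] else 0.0)

    inhib = 1.0 + p.theta_AC * ac
    act = rm_activation(rm, lps, ac, p)
    src_rm = monocyte_source(ch, g, rm, am, p, f)
    src_n = neutrophil_source(ch, n, p)

    d_lps = -p.mu_LPS * lps - act - (p.lambda_N_LPS * n + p.lambda_AM_LPS * am) * lps
    d_rm = -p.mu_RM * rm - act + src_rm
    d_am = -p.mu_AM * am + act
    d_ch = (-p.mu_CH * ch
            + (p.beta_CH_N * n + p.beta_CH_AM * am) * lps * (1.0 - ch / p.ch_inf) / inhib)
    d_n = -p.mu_N * n - p.lambda_LPS_N * lps * n + src_n
    d_nd = p.mu_N * n + p.lambda_LPS_N * lps * n - p.lambda_ND_AM * nd * am
    d_g = -p.mu_G * g + p.alpha_G_N * src_n * (1.0 - g / p.g_inf)
    d_ac = -p.mu_AC * ac + (p.beta_RM_ND * rm * nd + p.alpha_AC_AM * am) * (1.0 - ac / p.ac_inf)

    zero = {name: 1.0 if on[name] else 0.0 for name in SPECIES}
    return ReactionRates(
        lps=d_lps,
        rm=d_rm,
        am=d_am,
        ch=d_ch * zero["ch"],
        n=d_n * zero["n"],
        nd=d_nd * zero["nd"],
        g=d_g * zero["g"],
        ac=d_ac * zero["ac"],
    )
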