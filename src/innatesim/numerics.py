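"""Spatial discretization and explicit time integration on a 1-D strip.

The strip is discretized on a vertex-centered grid (nodes at 0, dx, ..., L).
Diffusion uses the 3-point central stencil with mirror-ghost nodes, which
makes the zero-flux Neumann condition exact for the stencil; chemotaxis uses
a conservative first-order upwind discretization of the advective flux
``chi * cells * grad(CH)`` evaluated at cell interfaces.  Time integration
is forward Euler, so the scheme is first-order accurate in both dt and dx.

Both operators are finite-volume consistent on the vertex-centered grid
(boundary nodes own half-width cells), so each conserves the trapezoid-rule
total mass to rounding error; the only non-conservative ingredient is the
non-negativity clamp applied after each explicit update.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import _kernels
from .model_core import SPECIES, ParameterSet, PointState, ScenarioFlags, reaction_terms

__all__ = [
    "Grid",
    "TissueState",
    "Trajectory",
    "StabilityError",
    "NonFiniteError",
    "laplacian_neumann",
    "chemotaxis_divergence_upwind",
    "stability_bound",
    "euler_step",
    "simulate",
]

logger = logging.getLogger(__name__)

#: Default LPS magnitude used when bounding the stiffest linear reaction
#: rates (lambda_LPS_N * LPS etc.); matches the standard injection bolus.
LPS_REF = 100.0


class StabilityError(ValueError):
    """Requested time step exceeds the explicit stability bound."""


class NonFiniteError(RuntimeError):
    """A species field left the finite range during integration."""


@dataclasses.dataclass(frozen=True)
class Grid:
    """Vertex-centered 1-D grid: ``nx`` nodes spanning ``[0, length]`` mm."""

    length: float
    nx: int

    def __post_init__(self) -> None:
        if self.nx < 3:
            raise ValueError("grid needs at least 3 nodes")
        if self.length <= 0:
            raise ValueError("grid length must be > 0")

    @property
    def dx(self) -> float:
        return self.length / (self.nx - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.nx)

    @classmethod
    def from_spacing(cls, length: float, dx: float) -> "Grid":
        """Build the grid for a spacing that must tile ``length`` exactly."""
        ncells = length / dx
        if abs(ncells - round(ncells)) > 1e-9:
            raise ValueError(f"dx={dx} does not tile a {length} mm domain")
        return cls(length=length, nx=int(round(ncells)) + 1)


@dataclasses.dataclass
class TissueState:
    """The eight concentration fields on the grid at one time instant.

    ``fields`` is an (8, nx) float array in :data:`SPECIES` order.
    """

    grid: Grid
    time: float
    fields: np.ndarray

    def __post_init__(self) -> None:
        self.fields = np.ascontiguousarray(self.fields, dtype=np.float64)
        if self.fields.shape != (len(SPECIES), self.grid.nx):
            raise ValueError(
                f"fields must have shape {(len(SPECIES), self.grid.nx)}, "
                f"got {self.fields.shape}"
            )

    @classmethod
    def zeros(cls, grid: Grid, time: float = 0.0) -> "TissueState":
        return cls(grid, time, np.zeros((len(SPECIES), grid.nx)))

    def species(self, name: str) -> np.ndarray:
        return self.fields[SPECIES.index(name)]

    def copy(self) -> "TissueState":
        return TissueState(self.grid, self.time, self.fields.copy())


@dataclasses.dataclass
class Trajectory:
    """Snapshots plus per-species spatial totals at the requested times."""

    grid: Grid
    times: np.ndarray
    states: list
    totals: pd.DataFrame  # columns: time + one per species (conc * mm)

    def __post_init__(self) -> None:
        if len(self.states) != len(self.times):
            raise ValueError("one state per snapshot time required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")


def laplacian_neumann(field: np.ndarray, dx: float) -> np.ndarray:
    """3-point Laplacian with zero-flux (mirror-ghost) boundaries.

    Interior node i gets ``(f[i-1] - 2 f[i] + f[i+1]) / dx^2``; the ghosts
    ``f[-1] = f[1]`` and ``f[nx] = f[nx-2]`` seal both ends.  Equivalent to
    the finite-volume form with half-width boundary cells, so the
    trapezoid-weighted sum of the result vanishes for any field.
    """
    f = np.asarray(field, dtype=float)
    if f.ndim != 1 or f.size < 3:
        raise ValueError("field must be 1-D with at least 3 nodes")
    if dx <= 0:
        raise ValueError("dx must be > 0")
    out = np.empty_like(f)
    out[1:-1] = f[:-2] - 2.0 * f[1:-1] + f[2:]
    out[0] = 2.0 * (f[1] - f[0])
    out[-1] = 2.0 * (f[-2] - f[-1])
    return out / dx**2


def chemotaxis_divergence_upwind(
    cells: np.ndarray, chemo: np.ndarray, chi: float, dx: float
) -> np.ndarray:
    """Divergence of the chemotactic flux ``chi * cells * grad(chemo)``.

    The flux is evaluated at the nx-1 cell interfaces with the transported
    cell concentration taken from the upwind side (the side the flux leaves);
    both domain walls are sealed.  Boundary nodes own half-width cells
    (finite-volume view of the vertex-centered grid), so the divergence
    there carries a factor 2/dx -- with that weighting both this operator
    and :func:`laplacian_neumann` conserve the trapezoid-rule mass exactly.
    The returned divergence is the term *subtracted* from the cell balance,
    so cells drift up the chemoattractant gradient.
    """
    u = np.asarray(cells, dtype=float)
    c = np.asarray(chemo, dtype=float)
    if u.shape != c.shape or u.ndim != 1 or u.size < 3:
        raise ValueError("cells and chemo must be equal-length 1-D arrays (>= 3 nodes)")
    if dx <= 0:
        raise ValueError("dx must be > 0")
    if chi < 0:
        raise ValueError("chi must be >= 0")
    v = chi * np.diff(c) / dx  # interface velocities
    upwind = np.where(v > 0, u[:-1], u[1:])
    flux = v * upwind
    padded = np.concatenate(([0.0], flux, [0.0]))  # sealed walls
    div = np.diff(padded) / dx
    div[0] *= 2.0  # half-width boundary cells
    div[-1] *= 2.0
    return div


def stability_bound(p: ParameterSet, dx: float, lps_ref: float = LPS_REF) -> float:
    """Conservative maximum stable dt (day) for the explicit scheme.

    Three constraint families are combined and the minimum returned:

    * diffusion/advection, per species: ``dx^2 / (2 D + 2 chi * ch_inf)``.
      The advective velocity is bounded by ``chi * ch_inf / dx`` (the whole
      cytokine carrying capacity dropping across one cell), which makes the
      advective contribution ``2 chi * ch_inf`` in the denominator.
    * linear reaction rates: ``1 / R_max`` where R_max bounds the fastest
      per-capita loss/turnover of any species, with LPS-dependent rates
      evaluated at ``lps_ref`` and cell pools at their vascular maxima.

    Returns ``inf`` when nothing constrains the step.
    """
    if dx <= 0:
        raise ValueError("dx must be > 0")
    chi = {"rm": p.chi_RM, "am": p.chi_AM, "n": p.chi_N}
    bound = np.inf
    for k, name in enumerate(SPECIES):
        denom = 2.0 * p.diffusion[k] + 2.0 * chi.get(name, 0.0) * p.ch_inf
        if denom > 0:
            bound = min(bound, dx**2 / denom)
    rates = [
        # per-capita turnover of each species, linearized at reference sizes
        p.mu_LPS + p.phi_RM_LPS * p.M_max
        + p.lambda_N_LPS * p.N_max + p.lambda_AM_LPS * p.M_max,
        p.mu_RM + p.phi_RM_LPS * lps_ref + p.P_RM_max + p.Q_RM_max,
        p.mu_AM,
        p.mu_CH + (p.beta_CH_N * p.N_max + p.beta_CH_AM * p.M_max) * lps_ref / p.ch_inf,
        p.mu_N + p.lambda_LPS_N * lps_ref + p.P_N_max,
        p.lambda_ND_AM * p.M_max,
        p.mu_G + p.alpha_G_N * p.P_N_max * p.N_max / p.g_inf,
        p.mu_AC + (p.beta_RM_ND * p.M_max * p.N_max + p.alpha_AC_AM * p.M_max) / p.ac_inf,
    ]
    r_max = max(rates)
    if r_max > 0:
        bound = min(bound, 1.0 / r_max)
    return float(bound)


def _check_dt(p: ParameterSet, dx: float, dt: float) -> None:
    if dt <= 0:
        raise StabilityError("dt must be > 0")
    bound = stability_bound(p, dx)
    if dt > bound:
        # name the binding constraint for the error message
        chi = {"rm": p.chi_RM, "am": p.chi_AM, "n": p.chi_N}
        diff_bounds = {}
        for k, name in enumerate(SPECIES):
            denom = 2.0 * p.diffusion[k] + 2.0 * chi.get(name, 0.0) * p.ch_inf
            if denom > 0:
                diff_bounds[name] = dx**2 / denom
        if diff_bounds and min(diff_bounds.values()) <= bound * (1 + 1e-12):
            worst = min(diff_bounds, key=diff_bounds.get)
            constraint = f"diffusion/chemotaxis CFL for species '{worst}'"
        else:
            constraint = "fastest linear reaction rate"
        raise StabilityError(
            f"dt={dt:g} day exceeds the stability bound {bound:g} day "
            f"(binding constraint: {constraint})"
        )


def euler_step(
    s: TissueState, p: ParameterSet, f: ScenarioFlags, dt: float
) -> TissueState:
    """One forward-Euler step of the full reaction-diffusion-chemotaxis system.

    Pure-numpy reference path (the long-run driver :func:`simulate` uses the
    compiled kernel, which is pinned to this function by a unit test).
    Species disabled by the flags are left untouched.
    """
    _check_dt(p, s.grid.dx, dt)
    dx = s.grid.dx
    rates = np.vstack(reaction_terms(PointState(*s.fields), p, f))
    active = f.active
    chi = {"rm": p.chi_RM, "am": p.chi_AM, "n": p.chi_N}
    ch_field = s.species("ch")
    for k, name in enumerate(SPECIES):
        if not active[k]:
            rates[k] = 0.0
            continue
        if p.diffusion[k] > 0:
            rates[k] += p.diffusion[k] * laplacian_neumann(s.fields[k], dx)
        if name in chi and f.ch_dynamics:
            rates[k] -= chemotaxis_divergence_upwind(s.fields[k], ch_field, chi[name], dx)
    new = s.fields + dt * rates
    clamped = new < 0
    if np.any(clamped):
        for k in np.flatnonzero(clamped.any(axis=1)):
            logger.debug(
                "clamped %d negative node(s) of %s at t=%g",
                int(clamped[k].sum()), SPECIES[k], s.time + dt,
            )
        new[clamped] = 0.0
    return TissueState(s.grid, s.time + dt, new)


def simulate(
    p: ParameterSet,
    f: ScenarioFlags,
    grid: Grid,
    dt: float,
    t_final: float,
    output_times,
    initial: TissueState | None = None,
) -> Trajectory:
    """Integrate the model and record snapshots plus spatial totals.

    ``output_times`` must be strictly increasing and lie in ``[0, t_final]``;
    each requested time is matched to the nearest whole step (always within
    dt/2).  The run starts from the standard initial condition (localized
    LPS bolus, uniform resting macrophages) unless ``initial`` is supplied.
    The integration is fully deterministic: identical inputs give
    bit-identical trajectories.
    """
    output_times = np.asarray(list(output_times), dtype=float)
    if output_times.size == 0:
        raise ValueError("at least one output time is required")
    if np.any(np.diff(output_times) <= 0):
        raise ValueError("output times must be strictly increasing")
    if output_times[0] < 0 or output_times[-1] > t_final + 1e-12:
        raise ValueError("output times must lie within [0, t_final]")
    _check_dt(p, grid.dx, dt)

    if initial is None:
        from .scenarios import initial_state

        initial = initial_state(grid)
    if initial.grid.nx != grid.nx:
        raise ValueError("initial state does not match the grid")

    S = initial.fields.copy()
    R = np.empty_like(S)
    P = p.as_array()
    active = f.active
    clamp = np.zeros(len(SPECIES), dtype=np.int64)
    logger.info("stability bound %.6g day (dt=%.3g day)", stability_bound(p, grid.dx), dt)

    states: list[TissueState] = []
    rows = []
    steps_done = 0
    for t in output_times:
        k = int(round(t / dt))
        n = k - steps_done
        if n > 0:
            bad_k, bad_step = _kernels.run_steps(S, R, n, dt, grid.dx, P, active, clamp)
            if bad_k >= 0:
                t_bad = (steps_done + bad_step + 1) * dt
                raise NonFiniteError(
                    f"species '{SPECIES[bad_k]}' became non-finite at t={t_bad:g} day"
                )
            steps_done = k
        states.append(TissueState(grid, steps_done * dt, S.copy()))
        rows.append([t] + [float(np.trapezoid(S[j], dx=grid.dx)) for j in range(len(SPECIES))])

    if clamp.any():
        detail = ", ".join(
            f"{SPECIES[k]}: {int(c)}" for k, c in enumerate(clamp) if c
        )
        logger.info("negative-value clamps during run: %s", detail)

    totals = pd.DataFrame(rows, columns=("time",) + SPECIES)
    return Trajectory(grid=grid, times=output_times, states=states, totals=totals)
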