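"""Compiled inner loop of the explicit time stepper.

One njit kernel advances the (8, nx) state array by ``nsteps`` forward-Euler
steps: local kinetics, 3-point Neumann diffusion and interface-flux upwind
chemotaxis, then the non-negativity clamp.  The pure-numpy reference path is
``numerics.euler_step``; a unit test pins the two to each other.
"""

from __future__ import annotations

import dataclasses

import numba
import numpy as np

from .model_core import ParameterSet

_ORDER = tuple(f.name for f in dataclasses.fields(ParameterSet))


def _idx(name: str) -> int:
    return _ORDER.index(name)


# Parameter indices into ParameterSet.as_array(); resolved from the dataclass
# field order so the two cannot drift apart.
I_MU_LPS = _idx("mu_LPS")
I_PHI_RM_LPS = _idx("phi_RM_LPS")
I_THETA_AC = _idx("theta_AC")
I_LAMBDA_N_LPS = _idx("lambda_N_LPS")
I_LAMBDA_AM_LPS = _idx("lambda_AM_LPS")
I_D_LPS = _idx("D_LPS")
I_D_RM = _idx("D_RM")
I_D_AM = _idx("D_AM")
I_D_CH = _idx("D_CH")
I_D_N = _idx("D_N")
I_D_ND = _idx("D_ND")
I_D_G = _idx("D_G")
I_D_AC = _idx("D_AC")
I_CHI_RM = _idx("chi_RM")
I_CHI_AM = _idx("chi_AM")
I_CHI_N = _idx("chi_N")
I_P_RM_MAX = _idx("P_RM_max")
I_P_RM_MIN = _idx("P_RM_min")
I_Q_RM_MAX = _idx("Q_RM_max")
I_Q_RM_MIN = _idx("Q_RM_min")
I_P_N_MAX = _idx("P_N_max")
I_P_N_MIN = _idx("P_N_min")
I_KEQ_CH = _idx("keq_ch")
I_KEQ_G = _idx("keq_g")
I_M_MAX = _idx("M_max")
I_N_MAX = _idx("N_max")
I_MU_RM = _idx("mu_RM")
I_MU_AM = _idx("mu_AM")
I_MU_N = _idx("mu_N")
I_MU_CH = _idx("mu_CH")
I_MU_G = _idx("mu_G")
I_MU_AC = _idx("mu_AC")
I_BETA_CH_N = _idx("beta_CH_N")
I_BETA_CH_AM = _idx("beta_CH_AM")
I_CH_INF = _idx("ch_inf")
I_LAMBDA_LPS_N = _idx("lambda_LPS_N")
I_LAMBDA_ND_AM = _idx("lambda_ND_AM")
I_ALPHA_G_N = _idx("alpha_G_N")
I_G_INF = _idx("g_inf")
I_BETA_RM_ND = _idx("beta_RM_ND")
I_ALPHA_AC_AM = _idx("alpha_AC_AM")
I_AC_INF = _idx("ac_inf")


@numba.njit(cache=False)
def run_steps(S, R, nsteps, dt, dx, P, active, clamp_counts):  # pragma: no cover
    """Advance S (8, nx) in place by nsteps; R is an (8, nx) work buffer.

    active[k] tells whether species k evolves; inactive species are neither
    read (treated as zero) nor written.  clamp_counts accumulates, per
    species, how many node-updates were clamped to zero.  Returns
    (bad_species, bad_step): (-1, -1) on success, else the first species and
    step at which a non-finite value appeared.
    """
    nx = S.shape[1]
    inv_dx = 1.0 / dx
    inv_dx2 = inv_dx * inv_dx

    mu_lps = P[I_MU_LPS]
    phi = P[I_PHI_RM_LPS]
    theta = P[I_THETA_AC]
    lam_n_lps = P[I_LAMBDA_N_LPS]
    lam_am_lps = P[I_LAMBDA_AM_LPS]
    p_rm_max = P[I_P_RM_MAX]
    p_rm_min = P[I_P_RM_MIN]
    q_rm_max = P[I_Q_RM_MAX]
    q_rm_min = P[I_Q_RM_MIN]
    p_n_max = P[I_P_N_MAX]
    p_n_min = P[I_P_N_MIN]
    keq_ch = P[I_KEQ_CH]
    keq_g = P[I_KEQ_G]
    m_max = P[I_M_MAX]
    n_max = P[I_N_MAX]
    mu_rm = P[I_MU_RM]
    mu_am = P[I_MU_AM]
    mu_n = P[I_MU_N]
    mu_ch = P[I_MU_CH]
    mu_g = P[I_MU_G]
    mu_ac = P[I_MU_AC]
    b_ch_n = P[I_BETA_CH_N]
    b_ch_am = P[I_BETA_CH_AM]
    ch_inf = P[I_CH_INF]
    lam_lps_n = P[I_LAMBDA_LPS_N]
    lam_nd_am = P[I_LAMBDA_ND_AM]
    a_g_n = P[I_ALPHA_G_N]
    g_inf = P[I_G_INF]
    b_rm_nd = P[I_BETA_RM_ND]
    a_ac_am = P[I_ALPHA_AC_AM]
    ac_inf = P[I_AC_INF]

    D = np.empty(8)
    D[0] = P[I_D_LPS]
    D[1] = P[I_D_RM]
    D[2] = P[I_D_AM]
    D[3] = P[I_D_CH]
    D[4] = P[I_D_N]
    D[5] = P[I_D_ND]
    D[6] = P[I_D_G]
    D[7] = P[I_D_AC]

    ch_on = active[3]
    n_on = active[4]
    g_on = active[6]
    ac_on = active[7]

    for step in range(nsteps):
        # local kinetics
        for i in range(nx):
            lps = S[0, i]
            rm = S[1, i]
            am = S[2, i]
            ch = S[3, i] if ch_on else 0.0
            n = S[4, i] if n_on else 0.0
            nd = S[5, i] if n_on else 0.0
            g = S[6, i] if g_on else 0.0
            ac = S[7, i] if ac_on else 0.0

            inhib = 1.0 + theta * ac
            act = phi * rm * lps / inhib
            rm_p = (p_rm_max - p_rm_min) * ch / (ch + keq_ch) + p_rm_min
            rm_q = (q_rm_max - q_rm_min) * g / (g + keq_g) + q_rm_min
            src_rm = (rm_p + rm_q) * (m_max - (rm + am))
            p_n = (p_n_max - p_n_min) * ch / (ch + keq_ch) + p_n_min
            src_n = p_n * (n_max - n)

            R[0, i] = -mu_lps * lps - act - (lam_n_lps * n + lam_am_lps * am) * lps
            R[1, i] = -mu_rm * rm - act + src_rm
            R[2, i] = -mu_am * am + act
            if ch_on:
                R[3, i] = (-mu_ch * ch
                           + (b_ch_n * n + b_ch_am * am) * lps
                           * (1.0 - ch / ch_inf) / inhib)
            if n_on:
                R[4, i] = -mu_n * n - lam_lps_n * lps * n + src_n
                R[5, i] = mu_n * n + lam_lps_n * lps * n - lam_nd_am * nd * am
            if g_on:
                R[6, i] = -mu_g * g + a_g_n * src_n * (1.0 - g / g_inf)
            if ac_on:
                R[7, i] = (-mu_ac * ac
                           + (b_rm_nd * rm * nd + a_ac_am * am) * (1.0 - ac / ac_inf))

        # diffusion (mirror-ghost Neumann boundaries)
        for k in range(8):
            if not active[k] or D[k] == 0.0:
                continue
            d = D[k]
            R[k, 0] += d * 2.0 * (S[k, 1] - S[k, 0]) * inv_dx2
            for i in range(1, nx - 1):
                R[k, i] += d * (S[k, i - 1] - 2.0 * S[k, i] + S[k, i + 1]) * inv_dx2
            R[k, nx - 1] += d * 2.0 * (S[k, nx - 2] - S[k, nx - 1]) * inv_dx2

        # chemotaxis up the CH gradient (interface-flux upwinding)
        if ch_on:
            for m in range(3):
                if m == 0:
                    k = 1
                    chi = P[I_CHI_RM]
                elif m == 1:
                    k = 2
                    chi = P[I_CHI_AM]
                else:
                    k = 4
                    chi = P[I_CHI_N]
                if chi == 0.0 or not active[k]:
                    continue
                prev = 0.0  # zero flux through the left wall
                for i in range(nx):
                    if i < nx - 1:
                        v = chi * (S[3, i + 1] - S[3, i]) * inv_dx
                        f_r = v * (S[k, i] if v > 0.0 else S[k, i + 1])
                    else:
                        f_r = 0.0  # zero flux through the right wall
                    w = 2.0 if (i == 0 or i == nx - 1) else 1.0  # half cells
                    R[k, i] -= w * (f_r - prev) * inv_dx
                    prev = f_r

        # explicit update with non-negativity clamp
        for k in range(8):
            if not active[k]:
                continue
            for i in range(nx):
                v = S[k, i] + dt * R[k, i]
                if not np.isfinite(v):
                    return k, step
                if v < 0.0:
                    v = 0.0
                    clamp_counts[k] += 1
                S[k, i] = v

    return -1, -1
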