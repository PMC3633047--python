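"""Shared fixtures and the independent kinetics oracle.

The oracle is a deliberately naive, dict-driven transcription of the eight
balance laws, written separately from the package so the two
implementations can disagree.  Long Case runs are session-scoped: several
tests read the same trajectories.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import innatesim as im

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


# --- independent oracle -----------------------------------------------------

def _hill(c, hi, lo, keq):
    return lo + (hi - lo) * c / (c + keq)


def oracle_rates(y, q, case):
    """Naive right-hand side of the eight balance laws for a given case.

    ``y`` is (lps, rm, am, ch, n, nd, g, ac); ``q`` a plain dict of
    parameter values; ``case`` the ablation rung 1..5.  Returns a list of
    eight rates.
    """
    lps, rm, am, ch, n, nd, g, ac = [float(v) for v in y]
    if case < 2:
        ch = 0.0
    if case < 3:
        n = 0.0
        nd = 0.0
    if case < 4:
        g = 0.0
    if case < 5:
        ac = 0.0

    inhibition = 1.0 + q["theta_AC"] * ac
    activation = q["phi_RM_LPS"] * rm * lps / inhibition
    perm_rm = _hill(ch, q["P_RM_max"], q["P_RM_min"], q["keq_ch"])
    perm_rm_g = _hill(g, q["Q_RM_max"], q["Q_RM_min"], q["keq_g"])
    source_rm = (perm_rm + perm_rm_g) * (q["M_max"] - rm - am)
    source_n = _hill(ch, q["P_N_max"], q["P_N_min"], q["keq_ch"]) * (q["N_max"] - n)

    rates = [
        -q["mu_LPS"] * lps - activation
        - q["lambda_N_LPS"] * n * lps - q["lambda_AM_LPS"] * am * lps,
        -q["mu_RM"] * rm - activation + source_rm,
        -q["mu_AM"] * am + activation,
        -q["mu_CH"] * ch
        + (q["beta_CH_N"] * n * lps + q["beta_CH_AM"] * am * lps)
        * (1.0 - ch / q["ch_inf"]) / inhibition,
        -q["mu_N"] * n - q["lambda_LPS_N"] * lps * n + source_n,
        q["mu_N"] * n + q["lambda_LPS_N"] * lps * n - q["lambda_ND_AM"] * nd * am,
        -q["mu_G"] * g + q["alpha_G_N"] * source_n * (1.0 - g / q["g_inf"]),
        -q["mu_AC"] * ac
        + (q["beta_RM_ND"] * rm * nd + q["alpha_AC_AM"] * am) * (1.0 - ac / q["ac_inf"]),
    ]
    if case < 2:
        rates[3] = 0.0
    if case < 3:
        rates[4] = 0.0
        rates[5] = 0.0
    if case < 4:
        rates[6] = 0.0
    if case < 5:
        rates[7] = 0.0
    return rates


@pytest.fixture(scope="session")
def params():
    return im.default_parameters()


@pytest.fixture(scope="session")
def param_dict(params):
    return dataclasses.asdict(params)


@pytest.fixture(scope="session")
def grid51():
    return im.Grid.from_spacing(5.0, 0.1)


def _run_case(case, grid):
    times = [i * 0.01 for i in range(501)]
    return im.simulate(
        im.default_parameters(),
        im.ScenarioFlags.from_case(case),
        grid,
        1e-5,
        5.0,
        times,
        initial=im.initial_state(grid),
    )


@pytest.fixture(scope="session")
def case5_run(grid51):
    """Full-model 5-day trajectory at the standard resolution."""
    return _run_case(5, grid51)


@pytest.fixture(scope="session")
def all_case_totals(grid51, case5_run):
    """Spatial-total time series for every ablation rung."""
    totals = {c: _run_case(c, grid51).totals for c in (1, 2, 3, 4)}
    totals[5] = case5_run.totals
    return totals


def random_point_states(rng, n=60, scale=100.0):
    """Non-negative random states spanning several magnitudes."""
    vals = rng.uniform(0.0, 1.0, size=(n, 8)) * rng.choice(
        [0.0, 0.01, 1.0, scale], size=(n, 8)
    )
    return [im.PointState(*row) for row in vals]
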