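"""Cohort simulation under the irreversible illness-death model.

Latent trajectories are drawn per subject: entry offset ``l`` (years since
age 45), binary exposures, log-normal frailty, a healthy->diseased waiting
time ``t12`` and a healthy->dead time ``t13`` — both left-truncated at ``l``
so that every subject is alive and disease-free at entry — and an
exponential loss-to-follow-up time.  Truths are then mapped to observed
analysis records under either continuous or panel (every-Delta-years)
ascertainment of disease onset, and exposures can be non-differentially
misclassified.

The subject-level 1->2 hazard is the calibrated marginal Weibull hazard
times ``exp(bE*xE + bG*xG + bGxE*xE*xG + f) / c`` where ``c`` is the
population-average multiplier, so the cohort-average hazard matches the
disease preset.  Under proportional hazards a multiplier ``m`` on a Weibull
hazard is a rescaling of the scale parameter by ``m**(-1/shape)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CONTINUOUS, CohortDesign, ExposureSpec, Scenario, calibrate_baseline_multiplier
from .truncweibull import WeibullParams, cumulative_hazard, trunc_hazard

__all__ = [
    "draw_cohort_truth",
    "apply_observation",
    "apply_misclassification",
    "simulate_dataset",
    "expected_incident_trajectory",
    "export_dataset",
    "read_dataset",
]

#: column order of the tab-separated dataset dialect
DATASET_COLUMNS = ["l", "t", "event", "x_env_obs", "x_gen_obs", "x_env_true", "x_gen_true"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit seed (or Generator) is required")
    return np.random.default_rng(seed)


def _sample_trunc_weibull(
    rng: np.random.Generator, scale, shape: float, l: np.ndarray
) -> np.ndarray:
    """Vectorised inverse-CDF draw from Weibull(scale, shape) truncated at l."""
    u = rng.random(l.shape)
    return scale * ((l / scale) ** shape - np.log1p(-u)) ** (1.0 / shape)


def draw_cohort_truth(scenario: Scenario, seed) -> pd.DataFrame:
    """Draw latent per-subject truths for one replicate cohort.

    Returns a DataFrame with columns ``l`` (entry offset), ``x_env``,
    ``x_gen``, ``frailty``, ``t12``, ``t13`` (years since age 45, both > l)
    and ``t_ltfu`` (years after entry).
    """
    rng = _as_rng(seed)
    d, ex, ef = scenario.design, scenario.exposures, scenario.effects
    n = d.n_subjects
    l = rng.uniform(0.0, d.entry_age_max - d.entry_age_min, n)
    x_env = (rng.random(n) < ex.prevalence_env).astype(np.int8)
    x_gen = (rng.random(n) < ex.prevalence_gen).astype(np.int8)
    frailty = rng.normal(0.0, scenario.frailty.sd, n)

    c = calibrate_baseline_multiplier(scenario)
    eta = ef.beta_env * x_env + ef.beta_gen * x_gen + ef.beta_gxe * x_env * x_gen
    mult = np.exp(eta + frailty) / c

    p12 = scenario.transitions.healthy_to_diseased
    scale12 = scenario.population_scale_12 * mult ** (-1.0 / p12.shape)
    t12 = _sample_trunc_weibull(rng, scale12, p12.shape, l)

    p13 = scenario.transitions.healthy_to_dead
    t13 = _sample_trunc_weibull(rng, p13.scale, p13.shape, l)

    if d.ltfu_rate > 0:
        t_ltfu = rng.exponential(1.0 / d.ltfu_rate, n)
    else:
        t_ltfu = np.full(n, np.inf)

    return pd.DataFrame(
        {
            "l": l,
            "x_env": x_env,
            "x_gen": x_gen,
            "frailty": frailty,
            "t12": t12,
            "t13": t13,
            "t_ltfu": t_ltfu,
        }
    )


def apply_observation(
    truths: pd.DataFrame, design: CohortDesign, scheme: str | None = None
) -> pd.DataFrame:
    """Convert latent truths into observed (l, t, event) analysis records.

    ``scheme`` is ``"continuous"`` or ``"panel"``; by default it follows
    ``design.visit_interval_years``.  Death and loss to follow-up are treated
    as exactly observed (registry-style ascertainment); only disease onset is
    interval-detected under the panel scheme, at the first scheduled visit at
    or after onset, provided the subject is still under observation then.  A
    visit falling exactly at the end of follow-up still takes place.
    """
    if scheme is None:
        scheme = CONTINUOUS if design.is_continuous else "panel"
    if scheme not in (CONTINUOUS, "panel"):
        raise ValueError(f"unknown observation scheme {scheme!r}")
    if scheme == "panel" and design.is_continuous:
        raise ValueError("panel scheme requested but design has no visit interval")
    if len(truths) == 0:
        return pd.DataFrame(
            columns=["l", "t", "event", "x_env", "x_gen"]
        ).astype({"event": np.int8, "x_env": np.int8, "x_gen": np.int8})

    l = truths["l"].to_numpy()
    t12 = truths["t12"].to_numpy()
    t13 = truths["t13"].to_numpy()
    end = np.minimum.reduce([t13, l + truths["t_ltfu"].to_numpy(), l + design.followup_years])

    if scheme == CONTINUOUS:
        event = t12 < end
        t = np.where(event, t12, end)
    else:
        delta = float(design.visit_interval_years)
        # first scheduled visit at or after onset (onset > l, so k >= 1)
        k = np.ceil((t12 - l) / delta - 1e-12)
        v = l + k * delta
        detected = (
            (v <= l + design.followup_years + 1e-9)
            & (v < t13)
            & (v < l + truths["t_ltfu"].to_numpy())
        )
        event = detected
        t = np.where(detected, v, end)

    return pd.DataFrame(
        {
            "l": l,
            "t": t,
            "event": event.astype(np.int8),
            "x_env": truths["x_env"].to_numpy(),
            "x_gen": truths["x_gen"].to_numpy(),
        }
    )


def apply_misclassification(
    records: pd.DataFrame, exposures: ExposureSpec, seed
) -> pd.DataFrame:
    """Add non-differentially misclassified exposure columns.

    Each subject's observed exposure equals the truth flipped independently
    with the configured rate, once per subject per dataset, independent of
    the outcome.  Event times are untouched; the returned frame carries both
    ``x_*_obs`` (analysis covariates) and ``x_*_true`` columns.
    """
    out = records.rename(columns={"x_env": "x_env_true", "x_gen": "x_gen_true"}).copy()
    rng = _as_rng(seed)
    n = len(out)
    for name, rate in (("env", exposures.misclass_env), ("gen", exposures.misclass_gen)):
        true = out[f"x_{name}_true"].to_numpy()
        if rate == 0:
            obs = true.copy()
        else:
            flip = rng.random(n) < rate
            obs = np.where(flip, 1 - true, true).astype(np.int8)
        out[f"x_{name}_obs"] = obs
    return out


def simulate_dataset(scenario: Scenario, seed, scheme: str | None = None) -> pd.DataFrame:
    """Simulate one analysis-ready dataset (single RNG stream per dataset)."""
    rng = _as_rng(seed)
    truths = draw_cohort_truth(scenario, rng)
    records = apply_observation(truths, scenario.design, scheme)
    return apply_misclassification(records, scenario.exposures, rng)


def expected_incident_trajectory(
    scenario: Scenario,
    horizon_years: float,
    n_reps: int = 20,
    seed=None,
    method: str = "mc",
) -> pd.DataFrame:
    """Expected cumulative number of incident (detected) cases by each year.

    ``method="mc"`` averages continuous-observation event counts over
    ``n_reps`` simulated cohorts.  ``method="quadrature"`` integrates the
    illness-death cause-specific incidence over the uniform entry-age
    distribution, the four exposure cells and Gauss-Hermite frailty nodes,
    with loss to follow-up as independent exponential censoring.  Returns a
    DataFrame with columns ``year`` and ``cum_cases`` scaled to the cohort
    size.
    """
    if horizon_years < 0 or horizon_years > scenario.design.followup_years:
        raise ValueError("horizon must lie within the follow-up period")
    years = np.arange(0, int(np.floor(horizon_years)) + 1)
    if method == "mc":
        rng = _as_rng(seed)
        counts = np.zeros(len(years))
        for _ in range(n_reps):
            truths = draw_cohort_truth(scenario, rng)
            rec = apply_observation(truths, scenario.design, CONTINUOUS)
            elapsed = rec.loc[rec["event"] == 1, "t"].to_numpy() - rec.loc[
                rec["event"] == 1, "l"
            ].to_numpy()
            counts += (elapsed[None, :] <= years[:, None]).sum(axis=1)
        counts /= n_reps
    elif method == "quadrature":
        counts = np.array([_incident_quadrature(scenario, float(y)) for y in years])
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame({"year": years, "cum_cases": counts})


def _incident_quadrature(scenario: Scenario, horizon: float, n_nodes: int = 64) -> float:
    """Closed-form (quadrature) expected incident count by ``horizon`` years."""
    if horizon == 0:
        return 0.0
    d, ex, ef = scenario.design, scenario.exposures, scenario.effects
    p12 = WeibullParams(scenario.population_scale_12, scenario.transitions.healthy_to_diseased.shape)
    p13 = scenario.transitions.healthy_to_dead
    c = calibrate_baseline_multiplier(scenario)
    span = d.entry_age_max - d.entry_age_min

    pe, pg = ex.prevalence_env, ex.prevalence_gen
    cells = [
        ((1 - pe) * (1 - pg), 0.0),
        (pe * (1 - pg), ef.beta_env),
        ((1 - pe) * pg, ef.beta_gen),
        (pe * pg, ef.beta_env + ef.beta_gen + ef.beta_gxe),
    ]
    # Gauss-Hermite for the Normal(0, sd^2) frailty
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(16)
    gh_w = gh_w / gh_w.sum()
    f_nodes = gh_x * scenario.frailty.sd

    gl_x, gl_w = np.polynomial.legendre.leggauss(n_nodes)

    def prob_given_entry(l: np.ndarray) -> np.ndarray:
        """P(onset detected by `horizon` years | entry offset l), vectorised."""
        upper = l + min(horizon, d.followup_years)
        # map GL nodes to (l, upper) per entry offset
        tt = l[:, None] + (gl_x[None, :] + 1) / 2 * (upper - l)[:, None]
        ww = gl_w[None, :] * (upper - l)[:, None] / 2
        q12 = trunc_hazard(tt, p12)
        h12 = cumulative_hazard(l[:, None], tt, p12)
        h13 = cumulative_hazard(l[:, None], tt, p13)
        ltfu = d.ltfu_rate * (tt - l[:, None])
        total = np.zeros(l.shape)
        for w_cell, eta in cells:
            if w_cell == 0:
                continue
            for wf, f in zip(gh_w, f_nodes):
                m = np.exp(eta + f) / c
                integrand = m * q12 * np.exp(-m * h12 - h13 - ltfu)
                total += w_cell * wf * (integrand * ww).sum(axis=1)
        return total

    l_nodes = (gl_x + 1) / 2 * span
    l_w = gl_w / 2  # uniform density over entry offsets
    probs = prob_given_entry(l_nodes)
    return float(d.n_subjects * (probs * l_w).sum())


def export_dataset(records: pd.DataFrame, path) -> None:
    """Write the tab-separated dataset dialect (header, 1 = event)."""
    records.loc[:, DATASET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset written by :func:`export_dataset`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset at {path} is missing columns {missing}")
    return df


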