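"""Monte-Carlo power estimation and minimum-detectable-hazard-ratio search.

Statistical power for a coefficient is the proportion of independently
simulated replicate cohorts in which the two-sided Wald test rejects the null
of no effect at the scenario's significance level.  The MDHR is the smallest
hazard ratio reaching a target power (default 80%) at the fixed cohort size,
found by bisection on the HR with common random numbers — each bracket point
reuses the same per-replicate seed streams, so the power curve is evaluated
on matched noise and the bisection is stable.

Scan conventions follow the study design: when scanning a main effect the
other hazard ratios are held at 1; when scanning the gene-environment
interaction both main-effect hazard ratios are held at 1.5.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import EffectSpec, Scenario
from .estimate import fit_weibull_ph, wald_test
from .simulate import simulate_dataset

__all__ = [
    "PowerEstimate",
    "MDHRResult",
    "COEFFICIENTS",
    "scenario_with_effect",
    "estimate_power",
    "find_mdhr",
    "classify_effect",
    "run_grid",
]

logger = logging.getLogger(__name__)

COEFFICIENTS = ("beta_env", "beta_gen", "beta_gxe")

#: log hazard ratio for the nuisance main effects during an interaction scan
_INTERACTION_MAIN_HR = 1.5


class FitFailureBudgetExceeded(RuntimeError):
    """Raised when too many replicate fits fail in one Monte-Carlo cell."""


@dataclass(frozen=True)
class PowerEstimate:
    scenario: Scenario
    coefficient: str
    true_hr: float
    n_reps: int
    rejections: int
    power: float
    mc_interval: tuple[float, float]
    n_failures: int = 0

    @property
    def mc_stderr(self) -> float:
        return math.sqrt(self.power * (1 - self.power) / max(self.n_reps, 1))


@dataclass(frozen=True)
class MDHRResult:
    scenario: Scenario
    coefficient: str
    mdhr: float | None  # None when not detectable within the bracket
    label: str  # "1.27" or ">3.00"
    category: str
    target_power: float
    reps_per_point: int
    trace: tuple[tuple[float, int, float], ...]  # (hr, reps used, power)

    @property
    def detectable(self) -> bool:
        return self.mdhr is not None


def scenario_with_effect(scenario: Scenario, coefficient: str, true_hr: float) -> Scenario:
    """Scenario with the scanned coefficient set to log(true_hr).

    Main-effect scans zero the other effects; interaction scans hold both
    main-effect hazard ratios at 1.5.
    """
    if coefficient not in COEFFICIENTS:
        raise ValueError(f"coefficient must be one of {COEFFICIENTS}")
    if true_hr <= 0:
        raise ValueError("true_hr must be > 0")
    beta = math.log(true_hr)
    if coefficient == "beta_gxe":
        main = math.log(_INTERACTION_MAIN_HR)
        effects = EffectSpec(beta_env=main, beta_gen=main, beta_gxe=beta)
    else:
        effects = EffectSpec(**{coefficient: beta})
    return scenario.replace(effects=effects)


def _replicate_rejects(scenario: Scenario, coefficient: str, seed) -> bool | None:
    """Simulate, fit and test one replicate; None signals a fit failure."""
    data = simulate_dataset(scenario, np.random.default_rng(seed))
    try:
        fit = fit_weibull_ph(data)
        test = wald_test(fit, coefficient, scenario.alpha)
    except Exception as exc:  # noqa: BLE001 - counted toward the failure budget, never silent
        logger.warning("replicate fit failed: %s", exc)
        return None
    return test.reject


def _wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return 0.0, 1.0
    z = stats.norm.isf((1 - confidence) / 2)
    phat = k / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def estimate_power(
    scenario: Scenario,
    coefficient: str,
    true_hr: float,
    n_reps: int,
    master_seed: int,
    failure_budget: float = 0.01,
    early_stop_target: float | None = None,
    early_stop_confidence: float = 0.999,
    _check_interval: int = 50,
) -> PowerEstimate:
    """Monte-Carlo power over ``n_reps`` independent replicate cohorts.

    Replicate r uses the seed stream SeedSequence([master_seed, r]), so
    results are reproducible and two calls with the same master seed share
    random numbers replicate-by-replicate (the common-random-numbers device
    used by the MDHR bisection).  When ``early_stop_target`` is set, the run
    stops early once a Wilson interval at ``early_stop_confidence`` excludes
    the target — the decision "above or below target power" is then already
    settled to that confidence, and remaining replicates would only sharpen
    an estimate the bisection does not need.

    Replicates whose fit fails are counted and excluded from the denominator;
    if their fraction exceeds ``failure_budget`` the cell raises.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    scen = scenario_with_effect(scenario, coefficient, true_hr)
    rejections = 0
    failures = 0
    used = 0
    for r in range(n_reps):
        seed = np.random.SeedSequence([int(master_seed), r])
        result = _replicate_rejects(scen, coefficient, seed)
        used += 1
        if result is None:
            failures += 1
        elif result:
            rejections += 1
        if (
            early_stop_target is not None
            and used % _check_interval == 0
            and used < n_reps
        ):
            lo, hi = _wilson_interval(rejections, used - failures, early_stop_confidence)
            if lo > early_stop_target or hi < early_stop_target:
                break
    denom = used - failures
    if failures > failure_budget * used or denom == 0:
        raise FitFailureBudgetExceeded(
            f"{failures}/{used} replicate fits failed (budget {failure_budget:.0%})"
        )
    power = rejections / denom
    return PowerEstimate(
        scenario=scen,
        coefficient=coefficient,
        true_hr=true_hr,
        n_reps=denom,
        rejections=rejections,
        power=power,
        mc_interval=_wilson_interval(rejections, denom),
        n_failures=failures,
    )


def classify_effect(hr: float) -> str:
    """Effect-size category of a detectable hazard ratio.

    Half-open bins: small (1, 1.5], moderate (1.5, 2], large (2, 3],
    substantial (> 3).
    """
    if not hr > 1:
        raise ValueError("hr must be > 1")
    if hr <= 1.5:
        return "small"
    if hr <= 2.0:
        return "moderate"
    if hr <= 3.0:
        return "large"
    return "substantial"


def find_mdhr(
    scenario: Scenario,
    coefficient: str,
    target_power: float = 0.8,
    reps_per_point: int = 1000,
    hr_bracket: tuple[float, float] = (1.0, 3.0),
    resolution: float = 0.01,
    master_seed: int = 0,
    early_stop: bool = True,
    pre_scan: int = 0,
) -> MDHRResult:
    """Smallest hazard ratio reaching ``target_power``, by bisection.

    Power is assumed nondecreasing in the hazard ratio; with common random
    numbers across bracket points the assumption is checked on the realised
    trace and violations beyond twice the Monte-Carlo standard error are
    warned about (with the trace attached).  Returns the MDHR rounded up to
    ``resolution`` (two decimals by default), or the sentinel ``">3.00"``
    when power at the upper bracket falls short of the target.

    ``pre_scan`` > 0 evaluates power on that many equispaced HRs first (at a
    quarter of ``reps_per_point``) as a coarse monotonicity guard.
    """
    lo, hi = hr_bracket
    if not 1.0 <= lo < hi:
        raise ValueError("hr_bracket must satisfy 1 <= lo < hi")
    trace: list[tuple[float, int, float]] = []

    def power_at(hr: float, reps: int) -> float:
        est = estimate_power(
            scenario,
            coefficient,
            hr,
            reps,
            master_seed,
            early_stop_target=target_power if early_stop else None,
        )
        trace.append((hr, est.n_reps, est.power))
        return est.power

    if pre_scan > 0:
        for hr in np.linspace(lo + resolution, hi, pre_scan):
            power_at(float(hr), max(reps_per_point // 4, 20))

    p_hi = power_at(hi, reps_per_point)
    if p_hi < target_power:
        result_hr: float | None = None
    else:
        while hi - lo > resolution:
            mid = (lo + hi) / 2
            if power_at(mid, reps_per_point) >= target_power:
                hi = mid
            else:
                lo = mid
        result_hr = round(math.ceil(hi / resolution - 1e-9) * resolution, 10)

    _warn_if_nonmonotone(trace, target_power)
    if result_hr is None:
        label = f">{hr_bracket[1]:.2f}"
        category = classify_effect(hr_bracket[1] + resolution)
    else:
        label = f"{result_hr:.2f}"
        category = classify_effect(result_hr)
    return MDHRResult(
        scenario=scenario,
        coefficient=coefficient,
        mdhr=result_hr,
        label=label,
        category=category,
        target_power=target_power,
        reps_per_point=reps_per_point,
        trace=tuple(trace),
    )


def _warn_if_nonmonotone(trace: list[tuple[float, int, float]], target: float) -> None:
    pts = sorted(trace)
    for (hr1, n1, p1), (hr2, n2, p2) in zip(pts, pts[1:]):
        se = math.sqrt(
            p1 * (1 - p1) / max(n1, 1) + p2 * (1 - p2) / max(n2, 1)
        )
        if p2 < p1 - 2 * se - 1e-12:
            warnings.warn(
                f"power trace non-monotone beyond noise: "
                f"P({hr1:.3f})={p1:.3f} > P({hr2:.3f})={p2:.3f}; trace={pts}",
                RuntimeWarning,
                stacklevel=3,
            )
            return


def run_grid(
    cells: list[dict],
    master_seed: int,
    mode: str = "power",
    n_reps: int = 1000,
    target_power: float = 0.8,
    skip: set[str] | None = None,
) -> pd.DataFrame:
    """Run a grid of power or MDHR cells; one row per cell, deterministic.

    Each cell is a dict with keys ``scenario`` (a :class:`Scenario`),
    ``coefficient`` and, in power mode, ``true_hr``.  Cell seeds derive from
    the master seed and the cell's position-independent name, so a partially
    completed grid can be resumed by passing the finished cell names in
    ``skip``.  Failures are recorded per cell; the run continues.
    """
    if mode not in ("power", "mdhr"):
        raise ValueError("mode must be 'power' or 'mdhr'")
    skip = skip or set()
    rows = []
    for cell in cells:
        scen: Scenario = cell["scenario"]
        coef = cell["coefficient"]
        name = cell.get("name") or _cell_name(scen, coef, cell.get("true_hr"))
        if name in skip:
            continue
        cell_seed = _cell_seed(master_seed, name)
        row = {
            "cell": name,
            "disease": scen.disease_label,
            "prevalence_env": scen.exposures.prevalence_env,
            "prevalence_gen": scen.exposures.prevalence_gen,
            "misclass_env": scen.exposures.misclass_env,
            "misclass_gen": scen.exposures.misclass_gen,
            "scheme": "continuous" if scen.design.is_continuous else "panel",
            "alpha": scen.alpha,
            "coefficient": coef,
            "seed": cell_seed,
            "error": "",
        }
        try:
            if mode == "power":
                est = estimate_power(scen, coef, cell["true_hr"], n_reps, cell_seed)
                row.update(
                    true_hr=est.true_hr,
                    power=est.power,
                    mc_low=est.mc_interval[0],
                    mc_high=est.mc_interval[1],
                    n_reps=est.n_reps,
                    n_failures=est.n_failures,
                )
            else:
                res = find_mdhr(
                    scen,
                    coef,
                    target_power=target_power,
                    reps_per_point=n_reps,
                    master_seed=cell_seed,
                )
                row.update(mdhr=res.label, category=res.category, n_reps=n_reps)
        except Exception as exc:  # noqa: BLE001 - recorded per cell
            logger.error("cell %s failed: %s", name, exc)
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _cell_name(scenario: Scenario, coefficient: str, true_hr: float | None) -> str:
    parts = [
        scenario.disease_label or "custom",
        f"pE{scenario.exposures.prevalence_env:g}",
        f"pG{scenario.exposures.prevalence_gen:g}",
        f"mE{scenario.exposures.misclass_env:g}",
        f"mG{scenario.exposures.misclass_gen:g}",
        "continuous" if scenario.design.is_continuous else "panel",
        f"a{scenario.alpha:g}",
        coefficient,
    ]
    if true_hr is not None:
        parts.append(f"hr{true_hr:g}")
    return "_".join(parts)


def _cell_seed(master_seed: int, name: str) -> int:
    import hashlib

    digest = hashlib.sha256(name.encode()).digest()
    return (int(master_seed) * 2654435761 + int.from_bytes(digest[:4], "big")) % (2**31)
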