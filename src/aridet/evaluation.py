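"""Calibration metrics, acceptance gates and LH-OAT sensitivity screening.

Model skill is judged the way the district study judges it: relative error
(RE) on annual ET totals, squared Pearson correlation (R²) and
Nash–Sutcliffe efficiency (Ens) on monthly series, gated at |RE| < 20%,
R² > 0.6 and Ens > 0.5. Parameter screening uses LH-OAT: Latin-hypercube
base points, one-at-a-time relative perturbations, and ranking by the mean
normalized elementary effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import NumericalError, ValidationError

# ---------------------------------------------------------------------------
# metrics


def relative_error(sim: float, obs: float) -> float:
    """Relative error in percent: (sim − obs)/obs × 100."""
    if obs == 0:
        raise ValidationError("relative error undefined for obs = 0")
    return (sim - obs) / obs * 100.0


def r_squared(sim, obs) -> float:
    """Squared Pearson correlation between simulated and observed series."""
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape or sim.size < 3:
        raise ValidationError("need >= 3 paired points")
    ds, do = sim - sim.mean(), obs - obs.mean()
    sxx, syy = float(ds @ ds), float(do @ do)
    if sxx == 0.0 or syy == 0.0:
        raise ValidationError("R² undefined for a constant series")
    return float((do @ ds) ** 2 / (syy * sxx))


def nash_sutcliffe(sim, obs) -> float:
    """Nash–Sutcliffe efficiency: 1 − Σ(sim−obs)²/Σ(obs−ōbs)².

    Equals 1 for a perfect match and 0 when the simulation is no better
    than the observed mean; unbounded below for poor simulations.
    """
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape or sim.size < 2:
        raise ValidationError("need >= 2 paired points")
    denom = float(((obs - obs.mean()) ** 2).sum())
    if denom == 0.0:
        raise ValidationError("Ens undefined for constant observations")
    return 1.0 - float(((sim - obs) ** 2).sum()) / denom


@dataclass(frozen=True)
class MetricReport:
    """Annual RE values (%), monthly R² and monthly Ens for one run."""

    re_by_year: tuple[float, ...]
    r2_monthly: float
    ens_monthly: float


@dataclass(frozen=True)
class GateResult:
    re_pass: bool
    r2_pass: bool
    ens_pass: bool

    @property
    def all_pass(self) -> bool:
        return self.re_pass and self.r2_pass and self.ens_pass


def evaluate_gates(
    report: MetricReport,
    re_limit: float = 20.0,
    r2_min: float = 0.6,
    ens_min: float = 0.5,
) -> GateResult:
    """Apply the standard acceptance gates (strict inequalities)."""
    return GateResult(
        re_pass=all(abs(re) < re_limit for re in report.re_by_year),
        r2_pass=report.r2_monthly > r2_min,
        ens_pass=report.ens_monthly > ens_min,
    )


def metric_report(sim_annual, obs_annual, sim_monthly, obs_monthly) -> MetricReport:
    """Build a report from paired annual totals and monthly series."""
    res = tuple(relative_error(s, o) for s, o in zip(sim_annual, obs_annual, strict=True))
    return MetricReport(
        re_by_year=res,
        r2_monthly=r_squared(sim_monthly, obs_monthly),
        ens_monthly=nash_sutcliffe(sim_monthly, obs_monthly),
    )


# ---------------------------------------------------------------------------
# LH-OAT sensitivity


@dataclass(frozen=True)
class SensitivityReport:
    """Ranked mean elementary effects from an LH-OAT screening."""

    params: tuple[str, ...]
    effects: dict[str, float]
    ranks: dict[str, int]            # 1 = most influential
    n_strata: int
    perturb_fraction: float
    seed: int


def lh_oat_sensitivity(
    objective,
    param_ranges: dict[str, tuple[float, float]],
    n_strata: int = 10,
    perturb_fraction: float = 0.05,
    seed: int = 0,
) -> SensitivityReport:
    """LH-OAT screening of a scalar objective over a parameter hyperbox.

    For each Latin-hypercube base point x and each parameter j, the
    normalized elementary effect is

        |100 · (M(x_j·(1+f)) − M(x)) / mean(M(x_j·(1+f)), M(x)) / f|

    averaged over base points; when the mean magnitude is below 1e-12 the
    normalization switches to the absolute difference. Parameters are
    ranked by descending mean effect, ties broken by declaration order.
    """
    if n_strata < 2:
        raise ValidationError("n_strata must be >= 2")
    if not 0.0 < perturb_fraction < 1.0:
        raise ValidationError("perturb_fraction must be in (0, 1)")
    names = list(param_ranges)
    for name, (lo, hi) in param_ranges.items():
        if not lo < hi:
            raise ValidationError(f"invalid range for {name}: [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    n = len(names)
    # Latin hypercube: one stratified sample per stratum per dimension
    u = (rng.permuted(np.tile(np.arange(n_strata), (n, 1)), axis=1).T + rng.random((n_strata, n))) / n_strata
    lows = np.array([param_ranges[k][0] for k in names])
    highs = np.array([param_ranges[k][1] for k in names])
    base_points = lows + u * (highs - lows)

    def _eval(x: np.ndarray) -> float:
        m = float(objective({k: float(v) for k, v in zip(names, x)}))
        if not np.isfinite(m):
            raise NumericalError(f"objective non-finite at {dict(zip(names, x))}")
        return m

    sums = np.zeros(n)
    for x in base_points:
        m0 = _eval(x)
        for j in range(n):
            xj = x.copy()
            cand = xj[j] * (1.0 + perturb_fraction)
            if not lows[j] <= cand <= highs[j]:
                # flip the perturbation direction at the box edge
                cand = xj[j] * (1.0 - perturb_fraction)
            xj[j] = min(max(cand, lows[j]), highs[j])
            mj = _eval(xj)
            mean = 0.5 * (mj + m0)
            if abs(mean) < 1e-12:
                eff = abs(mj - m0) / perturb_fraction
            else:
                eff = abs(100.0 * (mj - m0) / mean / perturb_fraction)
            sums[j] += eff
    effects = {k: float(s / n_strata) for k, s in zip(names, sums)}
    order = sorted(range(n), key=lambda j: (-sums[j], j))
    ranks = {names[j]: i + 1 for i, j in enumerate(order)}
    return SensitivityReport(
        params=tuple(names),
        effects=effects,
        ranks=ranks,
        n_strata=n_strata,
        perturb_fraction=perturb_fraction,
        seed=seed,
    )
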