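"""Cross-model universality analysis: rescaled information measures vs C_V.

The experiment: for each neuron model (NIF, LIF, QIF, GISI) and each target
coefficient of variation, generate spike-train ISIs, estimate the four
rescaled quantities (C*, h*, E, b* - see the continuum module) from the
empirical ISI distribution, and compare the curves as functions of C_V.
The integrate-and-fire family (NIF, LIF, QIF) collapses onto a single
curve; gamma-distributed ISIs deviate, most visibly on the entropy-rate
panel (gamma ISIs are less random than integrate-and-fire ISIs at matched
rate and C_V).

NIF rows are simulated through the exact first-passage sampler and GISI
rows are evaluated analytically (their ISI laws are known in closed form);
LIF and QIF are integrated by Euler-Maruyama.  All rows carry seeds, sizes
and block-subsample standard errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .continuum import rescaled_universal_quantities, rescaled_with_errors
from .discretize import discretize_distribution
from .isi import ISIDistribution
from .machine import anatomy_discrete, build_renewal_machine
from .simulate import NeuronModel, calibrate_params, sample_nif_exact, simulate_isis

log = logging.getLogger("spikeinfo.sweep")

PANELS = ("cmu_rescaled", "hmu_rescaled", "E", "bmu_rescaled")

#: empirical b* is unreliable below this C_V (cross-term estimation floor)
BMU_CV_FLOOR = 0.25


@dataclass
class SweepConfig:
    """One universality sweep: which models, which C_V targets, how much data.

    The default scaled-down sweep covers C_V in [0.3, 1.2] with 10^4 ISIs
    per grid point at unit target rate; the full printed parameter grids of
    the LIF/QIF models are available through spikeinfo.simulate.parameter_grid
    for users who want the complete picture.
    """

    models: tuple = ("NIF", "LIF", "QIF", "GISI")
    cv_targets: tuple = (0.3, 0.5, 0.75, 1.0, 1.2)
    target_rate: float = 1.0
    n_isis: int = 10_000
    seed: int = 0
    n_blocks: int = 4

    def __post_init__(self):
        if not self.models or not len(self.cv_targets):
            raise ValueError("models and cv_targets must be nonempty")
        if self.n_isis < 10**3:
            raise ValueError("n_isis below 10^3 gives unusable estimates")


def _row_from_samples(samples, seed, n_blocks):
    vals, se = rescaled_with_errors(samples, n_blocks=n_blocks, seed=seed)
    row = {
        "mu_hat": vals.firing_rate,
        "cv_hat": vals.cv,
        "cmu_rescaled": vals.cmu_rescaled,
        "hmu_rescaled": vals.hmu_rescaled,
        "E": vals.E,
        "bmu_rescaled": (np.nan if vals.bmu_rescaled is None
                         else vals.bmu_rescaled),
        "se_cmu_rescaled": se[0],
        "se_hmu_rescaled": se[1],
        "se_E": se[2],
        "se_bmu_rescaled": se[3],
        "bmu_excluded": vals.bmu_rescaled is None,
    }
    return row


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run the sweep; returns a tidy table with one row per grid point.

    Individual grid-point failures are logged and flagged (``failed``
    column), and the sweep continues.
    """
    rows = []
    rng = np.random.default_rng(config.seed)
    for model_kind in config.models:
        for cv in config.cv_targets:
            seed = int(rng.integers(2**31))
            row = {"model": model_kind, "cv_target": cv,
                   "rate_target": config.target_rate, "seed": seed,
                   "n": config.n_isis, "failed": False}
            try:
                row.update(_sweep_point(model_kind, cv, config, seed))
            except Exception as exc:  # noqa: BLE001 - flagged, sweep continues
                log.warning("grid point %s cv=%.3g failed: %s",
                            model_kind, cv, exc)
                row["failed"] = True
                row["error"] = str(exc)
            rows.append(row)
            log.info("done %s cv=%.3g", model_kind, cv)
    return pd.DataFrame(rows)


def _sweep_point(kind: str, cv: float, config: SweepConfig, seed: int) -> dict:
    model = calibrate_params(kind, config.target_rate, cv, seed=seed % 2**16)
    if kind == "GISI":
        # the ISI law is exact; evaluate the quantities analytically
        vals = rescaled_universal_quantities(model.isi_distribution())
        return {
            "mu_hat": vals.firing_rate, "cv_hat": vals.cv,
            "cmu_rescaled": vals.cmu_rescaled,
            "hmu_rescaled": vals.hmu_rescaled, "E": vals.E,
            "bmu_rescaled": (np.nan if vals.bmu_rescaled is None
                             else vals.bmu_rescaled),
            "se_cmu_rescaled": 0.0, "se_hmu_rescaled": 0.0, "se_E": 0.0,
            "se_bmu_rescaled": 0.0,
            "bmu_excluded": vals.bmu_rescaled is None,
            "params": _params_of(model),
        }
    if kind == "NIF":
        isis = sample_nif_exact(model, config.n_isis, seed=seed)
    else:
        isis = simulate_isis(model, config.n_isis, seed=seed)
    out = _row_from_samples(isis.intervals, seed, config.n_blocks)
    out["params"] = _params_of(model)
    return out


def _params_of(m: NeuronModel) -> str:
    if m.kind == "GISI":
        return f"shape={m.shape:.6g},scale={m.scale:.6g}"
    return f"b={m.b:.6g},noise={m.noise:.6g},tau={m.tau:.6g}"


@dataclass
class CollapseReport:
    """Per-panel maximum deviations from the reference model on a shared
    C_V grid, the tolerance used, and the universality verdict."""

    cv_grid: np.ndarray
    tolerance: dict
    deviations: dict          # (model, panel) -> max |model - ref|
    pooled_se: dict           # (model, panel) -> max pooled s.e.
    if_collapse: bool
    gisi_deviates_on_hmu: bool
    reference: str = "NIF"

    @property
    def passed(self) -> bool:
        return self.if_collapse and self.gisi_deviates_on_hmu


def collapse_test(table: pd.DataFrame, cv_grid, tolerance=None,
                  reference: str = "NIF",
                  se_factor: float = 3.0) -> CollapseReport:
    """Test the universality claim on a sweep table.

    Each model's panels are linearly interpolated in C_V onto ``cv_grid``
    (restricted to the models' common range).  Pass iff every
    integrate-and-fire model deviates from the reference by less than the
    tolerance on every panel, while GISI deviates beyond it on the
    entropy-rate panel.  ``tolerance`` defaults to se_factor times the
    maximum pooled standard error per panel.
    """
    table = table[~table.get("failed", False)]
    models = [m for m in table["model"].unique()]
    if reference not in models or len(models) < 2:
        raise ValueError("need the reference model plus at least one other")
    cv_grid = np.asarray(cv_grid, float)
    lo = max(table[table.model == m]["cv_hat"].min() for m in models)
    hi = min(table[table.model == m]["cv_hat"].max() for m in models)
    grid = cv_grid[(cv_grid >= lo) & (cv_grid <= hi)]
    if grid.size < 2:
        raise ValueError(
            f"insufficient C_V overlap: common range [{lo:.3g}, {hi:.3g}] "
            f"covers fewer than two grid points")

    def interp(model, col):
        sub = table[table.model == model].sort_values("cv_hat")
        good = ~sub[col].isna()
        if good.sum() < 2:
            return None
        return np.interp(grid, sub["cv_hat"][good], sub[col][good])

    ref_vals = {p: interp(reference, p) for p in PANELS}
    ref_se = {p: interp(reference, "se_" + p) for p in PANELS}
    deviations, pooled = {}, {}
    for m in models:
        if m == reference:
            continue
        for p in PANELS:
            v = interp(m, p)
            if v is None or ref_vals[p] is None:
                continue
            deviations[(m, p)] = float(np.max(np.abs(v - ref_vals[p])))
            s = interp(m, "se_" + p)
            if s is not None and ref_se[p] is not None:
                pooled[(m, p)] = float(np.max(np.sqrt(s**2 + ref_se[p]**2)))
    if tolerance is None:
        tolerance = {p: se_factor * max(
            [pooled[k] for k in pooled if k[1] == p] or [np.inf])
            for p in PANELS}
    elif np.isscalar(tolerance):
        tolerance = {p: float(tolerance) for p in PANELS}
    if_models = [m for m in models if m in ("LIF", "QIF", "NIF")
                 and m != reference]
    if_collapse = all(
        deviations.get((m, p), np.inf) < tolerance[p]
        for m in if_models for p in PANELS
        if (m, p) in deviations)
    gisi_dev = deviations.get(("GISI", "hmu_rescaled"))
    gisi_deviates = (gisi_dev is not None
                     and gisi_dev > tolerance["hmu_rescaled"])
    return CollapseReport(cv_grid=grid, tolerance=tolerance,
                          deviations=deviations, pooled_se=pooled,
                          if_collapse=if_collapse,
                          gisi_deviates_on_hmu=gisi_deviates,
                          reference=reference)


def dt_scaling_curves(dist: ISIDistribution, dt_grid,
                      window_ms: float | None = None) -> pd.DataFrame:
    """Resolution dependence of the information measures for one ISI law.

    For each dt (descending): C_mu, h_mu, h_mu/dt, E and b_mu/dt from the
    epsilon-machine route.  The continuum limits are attached as
    ``DataFrame.attrs["limits"]`` for use as horizontal asymptotes.
    """
    dt_grid = np.asarray(dt_grid, float)
    if np.any(dt_grid <= 0) or np.any(np.diff(dt_grid) > 0):
        raise ValueError("dt_grid must be positive and descending")
    m0 = dist.moments()
    window = window_ms or 10.0 * m0.mean_isi * (1 + 2 * m0.cv)
    rows = []
    for dt in dt_grid:
        mach = build_renewal_machine(discretize_distribution(dist, dt))
        an = anatomy_discrete(mach, max(int(window / dt), 8))
        rows.append({"dt": dt, "C_mu": an.C_mu, "h_mu": an.h_mu,
                     "h_mu_per_ms": an.h_mu / dt, "E": an.E,
                     "b_mu_per_ms": an.b_mu / dt,
                     "sigma_mu": an.sigma_mu, "n_states": mach.n_states})
    df = pd.DataFrame(rows)
    from .continuum import bmu_rate_limit, excess_entropy_limit, hmu_scaling

    df.attrs["limits"] = {
        "E": excess_entropy_limit(dist),
        "b_mu_per_ms": bmu_rate_limit(dist),
        "h_mu_coefficient": hmu_scaling(dist).divergence_coefficient,
        "h_mu_nondivergent": hmu_scaling(dist).nondivergent_part,
    }
    return df
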