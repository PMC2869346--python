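"""Dose-response experiments, steady-state extraction, and Hill fitting.

A dose-response experiment holds the attractant concentration fixed,
allows the lattice a stabilization window (default 1500 iterations), then
averages the next few recorded activity values (default 5 points at the
100-iteration record interval) — the same protocol at every concentration
of a logarithmic grid, repeated over replicate seeds.  The resulting curve
is summarized by nonlinear least squares against the Hill equation

    A(l) = Mf + (M0 - Mf) / (1 + (l / K_half)^H)

where ``M0`` is pre-stimulus activity, ``Mf`` the residual activity at
saturating attractant, ``K_half`` the concentration at half response, and
``H`` the Hill coefficient — the cooperativity readout of the lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .engine import LigandSchedule, SimulationConfig, TimeSeries, run

__all__ = [
    "DoseResponseCurve",
    "HillFitResult",
    "hill_curve",
    "steady_state_activity",
    "fit_hill",
    "dose_response_experiment",
    "dual_ligand_experiment",
    "methylation_sweep_experiment",
    "dynamic_range_experiment",
    "saturation_concentration",
    "log_grid",
]

#: measurement protocol defaults
STABILIZATION_ITERS = 1500
N_MEASURE_POINTS = 5


def log_grid(lo_exp: float, hi_exp: float, per_decade: int = 8,
             include_zero: bool = True) -> np.ndarray:
    """Logarithmic concentration grid 10^lo .. 10^hi (mol/L), optionally
    prefixed with 0 for the pre-stimulus point."""
    n = int(round((hi_exp - lo_exp) * per_decade)) + 1
    g = np.logspace(lo_exp, hi_exp, n)
    return np.concatenate([[0.0], g]) if include_zero else g


@dataclass
class DoseResponseCurve:
    """Steady-state activity vs concentration, with per-replicate values."""

    concentrations: np.ndarray
    mean_activity: np.ndarray
    replicate_activity: np.ndarray  # (n_conc, n_replicates)
    readout: str = "total"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    @property
    def minima(self) -> np.ndarray:
        return self.replicate_activity.min(axis=1)

    @property
    def maxima(self) -> np.ndarray:
        return self.replicate_activity.max(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"concentration_M": self.concentrations,
                           "mean_activity": self.mean_activity})
        for r in range(self.replicate_activity.shape[1]):
            df[f"replicate_{r}"] = self.replicate_activity[:, r]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class HillFitResult:
    """Hill-equation fit of a dose-response curve (deactivating ligand:
    ``mf <= m0``)."""

    m0: float
    mf: float
    k_half: float
    hill: float
    residual_norm: float
    converged: bool
    message: str = ""

    def to_dict(self) -> dict:
        return {"M0": self.m0, "Mf": self.mf, "K_half": self.k_half,
                "H": self.hill, "residual_norm": self.residual_norm,
                "converged": self.converged, "message": self.message}


def hill_curve(l, m0, mf, k_half, hill):
    """The fitted model: Mf + (M0 - Mf) / (1 + (l / K_half)^H)."""
    l = np.asarray(l, dtype=float)
    with np.errstate(over="ignore"):
        return mf + (m0 - mf) / (1.0 + (l / k_half) ** hill)


def steady_state_activity(series: TimeSeries,
                          stabilization_iters: int = STABILIZATION_ITERS,
                          n_points: int = N_MEASURE_POINTS,
                          readout: str = "total") -> float:
    """Mean activity after the last concentration change has settled.

    Finds the last iteration at which any ligand concentration changed,
    discards the stabilization window after it, and averages the next
    ``n_points`` recorded values.
    """
    last_change = 0
    for arr in series.concentrations.values():
        d = np.nonzero(np.diff(arr))[0]
        if d.size:
            last_change = max(last_change,
                              int(series.iteration[d[-1] + 1]))
    vals = _window(series, last_change, stabilization_iters, n_points,
                   readout)
    return float(np.mean(vals))


def _window(series: TimeSeries, t_change: int, stabilization_iters: int,
            n_points: int, readout: str) -> np.ndarray:
    """The n_points recorded activity values following a stabilization
    window that starts at iteration ``t_change``."""
    act = series.activity(readout)
    sel = np.nonzero(series.iteration > t_change + stabilization_iters)[0]
    if sel.size < n_points:
        raise ValueError(
            f"series too short: need {n_points} records after iteration "
            f"{t_change + stabilization_iters}, have {sel.size}")
    return act[sel[:n_points]]


def fit_hill(curve: DoseResponseCurve) -> HillFitResult:
    """Nonlinear least-squares Hill fit.

    Initialization: M0 = first point, Mf = last point, K_half = the
    concentration nearest half activity, H = 1.  A curve with no
    appreciable transition, or a failed optimization, is returned flagged
    (``converged=False``) rather than silently.
    """
    conc = np.asarray(curve.concentrations, dtype=float)
    act = np.asarray(curve.mean_activity, dtype=float)
    if conc.size < 4:
        raise ValueError("need at least 4 points to fit the Hill equation")
    m0_0, mf_0 = act[0], act[-1]
    if abs(m0_0 - mf_0) < 0.05:
        return HillFitResult(m0_0, mf_0, np.nan, np.nan, np.nan, False,
                             "degenerate curve: no transition")
    half = (m0_0 + mf_0) / 2.0
    pos = conc > 0
    k0 = conc[pos][np.argmin(np.abs(act[pos] - half))]
    lo = conc[pos].min()
    hi = conc[pos].max()
    try:
        popt, _ = curve_fit(
            hill_curve, conc, act,
            p0=[m0_0, mf_0, k0, 1.0],
            bounds=([0.0, 0.0, lo / 100.0, 0.05],
                    [1.5, 1.5, hi * 100.0, 100.0]),
            maxfev=20000)
    except RuntimeError as exc:
        return HillFitResult(m0_0, mf_0, np.nan, np.nan, np.nan, False,
                             f"fit failed: {exc}")
    resid = act - hill_curve(conc, *popt)
    return HillFitResult(float(popt[0]), float(popt[1]), float(popt[2]),
                         float(popt[3]), float(np.linalg.norm(resid)), True)


def _staircase_schedule(concentrations: np.ndarray, species: str,
                        hold_iters: int,
                        background: list[tuple[int, str, float]] | None = None
                        ) -> LigandSchedule:
    changes = list(background or [])
    for j, c in enumerate(concentrations):
        changes.append((j * hold_iters, species, float(c)))
    return LigandSchedule(sorted(changes, key=lambda x: x[0]))


def _replicate_rngs(seed: int, replicates: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(replicates)]


def dose_response_experiment(
        base_config: SimulationConfig,
        concentrations: np.ndarray,
        replicates: int = 3,
        species: str = "MeAsp",
        stabilization_iters: int = STABILIZATION_ITERS,
        n_points: int = N_MEASURE_POINTS,
        readout: str = "total",
        background: list[tuple[int, str, float]] | None = None,
) -> tuple[DoseResponseCurve, HillFitResult]:
    """Measure a full dose-response curve and fit the Hill equation.

    Each replicate performs one sequential run over the concentration
    grid (change, stabilize, measure), using a distinct seed; replicate
    means form the fitted curve.  ``background`` may preload other
    species (e.g. a constant Ser background) as schedule entries at
    iteration 0.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    conc = np.asarray(concentrations, dtype=float)
    R = base_config.record_interval
    hold = stabilization_iters + n_points * R
    schedule = _staircase_schedule(conc, species, hold, background)
    config = base_config.replace(schedule=schedule,
                                 iterations=hold * len(conc))
    values = np.empty((len(conc), replicates))
    for rep, rng in enumerate(_replicate_rngs(config.seed, replicates)):
        series = run(config, rng=rng)
        for j in range(len(conc)):
            vals = _window(series, j * hold, stabilization_iters, n_points,
                           readout)
            values[j, rep] = vals.mean()
    order = np.argsort(conc)
    curve = DoseResponseCurve(conc[order], values[order].mean(axis=1),
                              values[order], readout=readout)
    return curve, fit_hill(curve)


def dual_ligand_experiment(
        config: SimulationConfig,
        concentrations: np.ndarray,
        ser_concentration: float = 1e-5,
        replicates: int = 3,
        **kw,
) -> dict:
    """MeAsp dose-response of a mixed Tar/Tsr field with and without a
    constant Ser background (cross-binding off: each ligand binds only its
    preferred receptor type).

    Returns both curves and fits plus the zero-MeAsp baselines and the
    K_half pair — the leftward K_half shift with Ser present is the
    cooperative sensitization readout.
    """
    without = dose_response_experiment(
        config, concentrations, replicates=replicates, **kw)
    with_ser = dose_response_experiment(
        config, concentrations, replicates=replicates,
        background=[(0, "Ser", float(ser_concentration))], **kw)
    return {
        "without_ser": {"curve": without[0], "fit": without[1]},
        "with_ser": {"curve": with_ser[0], "fit": with_ser[1]},
        "baseline_without_ser": float(without[0].mean_activity[0]),
        "baseline_with_ser": float(with_ser[0].mean_activity[0]),
        "k_half_without_ser": without[1].k_half,
        "k_half_with_ser": with_ser[1].k_half,
    }


def methylation_sweep_experiment(
        config: SimulationConfig,
        concentrations: np.ndarray,
        tar_methylations: tuple[int, ...] = (2, 3, 4),
        omegas: tuple[float, ...] = (0.0, 0.2),
        replicates: int = 3,
        **kw,
) -> dict:
    """Combined-activity MeAsp dose-response of a 1:2 Tar:Tsr field at
    several fixed Tar methylation levels, with methylation-independent
    (omega=0) and methylation-dependent (omega>0) coupling.

    MeAsp binds both types here (Tsr at 1e5-fold weaker affinity), so the
    curves are biphasic: a low-dose Tar response dragging Tsr along
    cooperatively, and a high-dose direct Tsr response.
    """
    import dataclasses
    out: dict = {}
    for omega in omegas:
        for m_tar in tar_methylations:
            cfg = config.replace(
                m_tar=m_tar,
                energy=dataclasses.replace(config.energy, omega=omega))
            curve, fit = dose_response_experiment(
                cfg, concentrations, replicates=replicates, **kw)
            out[(omega, m_tar)] = {"curve": curve, "fit": fit}
    return out


def saturation_concentration(series: TimeSeries, schedule: LigandSchedule,
                             species: str = "MeAsp",
                             threshold: float = 0.1) -> float:
    """First staircase concentration whose plateau pins activity at its
    all-inactive floor.

    A step counts as saturated when the mean activity over its final
    third is below ``threshold``.  The default 0.1 sits between the
    thermal/boundary flicker floor a fully pinned lattice retains under
    the calibrated thermal scale (0.04-0.09) and the weakest genuinely
    responsive plateau observed (>= 0.13).  Returns NaN if no step
    saturates.
    """
    changes = [(it, c) for it, s, c in schedule.changes if s == species]
    for idx, (start, conc) in enumerate(changes):
        end = (changes[idx + 1][0] if idx + 1 < len(changes)
               else int(series.iteration[-1]) + 1)
        lo = start + 2 * (end - start) // 3
        sel = (series.iteration >= lo) & (series.iteration < end)
        if sel.any() and series.frac_active[sel].mean() < threshold:
            return float(conc)
    return float("nan")


def dynamic_range_experiment(
        variants: dict[str, SimulationConfig],
        step_iters: int = 30000,
        exponents: tuple[float, float] = (-8.0, 0.0),
        species: str = "MeAsp",
) -> dict:
    """Staircase dynamic-range protocol: one ligand-free hold, then the
    concentration raised tenfold per step from 10^-8 M to 1 M.

    Runs each configured variant (e.g. homogeneous Tar, 50/50 Tar/Tsr with
    omega 0 or 0.2) with the full pathway and reports its time series and
    saturation concentration.
    """
    concs = np.concatenate([[0.0], np.logspace(exponents[0], exponents[1],
                                               int(exponents[1] - exponents[0])
                                               + 1)])
    schedule = _staircase_schedule(concs, species, step_iters)
    out = {}
    for name, cfg in variants.items():
        cfg = cfg.replace(schedule=schedule,
                          iterations=step_iters * len(concs))
        series = run(cfg)
        out[name] = {
            "series": series,
            "saturation_M": saturation_concentration(series, schedule,
                                                     species),
        }
    return out
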