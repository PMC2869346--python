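"""Named, ready-to-run experiment scenarios.

Each scenario builds its configuration from the default model (1083
receptors on a 100x60 lattice, the standard energy and reaction
parameters) and runs one of the canonical experiments:

``cooperativity``
    MeAsp dose-response of a homogeneous doubly-methylated Tar array at
    G0 = -600, Ej = -700 cal/mol; the Hill fit quantifies lattice gain.
``cooperativity-sweep``
    Hill coefficient as a function of interaction strength Ej for several
    baseline offsets G0 (including the G0 = 0 ceiling).
``mixed-ratio``
    Hill coefficient of the primary (Tar) response as the Tar:Tsr ratio
    varies; cooperativity rises toward the homogeneous value.
``dual-ligand``
    MeAsp response of a 1:2 Tar:Tsr field with and without a 1e-5 M Ser
    background; Ser suppresses baseline activity to about one third and
    sensitizes the MeAsp response severalfold.
``methylation-coupling``
    Biphasic MeAsp response of a 1:2 Tar:Tsr field (MeAsp binds Tsr at
    1e5-fold weaker affinity) at Tar methylation 2/3/4 with omega = 0 and
    omega = 0.2.
``adaptation``
    Full-pathway run: 4e-6 M MeAsp added at iteration 30000 and removed
    at 60000; excitation, methylation-driven recovery, and the faster
    recovery after removal (demethylation outpaces methylation).
``dynamic-range``
    Full-pathway staircase from 1e-8 M to 1 M MeAsp, tenfold per step,
    for a homogeneous Tar array and 50/50 Tar/Tsr arrays with omega 0 and
    0.2; reports each variant's saturation concentration.
"""

from __future__ import annotations

import numpy as np

from .analysis import (dose_response_experiment, dual_ligand_experiment,
                       dynamic_range_experiment, log_grid,
                       methylation_sweep_experiment)
from .engine import LigandSchedule, SimulationConfig, run
from .receptor_field import EnergyParams, default_ligands

__all__ = ["SCENARIOS", "scenario_names", "run_scenario",
           "base_receptor_config", "base_pathway_config"]

#: default concentration grid for monophasic MeAsp responses (mol/L)
MONO_GRID = log_grid(-7.0, -4.0, per_decade=12)
#: wide grid for biphasic responses with weak Tsr cross-binding
BIPHASIC_GRID = log_grid(-8.0, -0.5, per_decade=6)


def base_receptor_config(seed: int = 0, **kw) -> SimulationConfig:
    """Receptor-only configuration (methylation fixed, no soluble agents)."""
    defaults = dict(frac_tar=1.0, m_tar=2, m_tsr=2,
                    include_pathway=False, seed=seed)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def base_pathway_config(seed: int = 0, **kw) -> SimulationConfig:
    """Full-pathway configuration (all six soluble species, adaptation on)."""
    defaults = dict(include_pathway=True, include_adaptation_enzymes=True,
                    seed=seed)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def _sc_cooperativity(seed: int = 0, replicates: int = 3,
                      concentrations: np.ndarray | None = None) -> dict:
    cfg = base_receptor_config(seed)
    grid = MONO_GRID if concentrations is None else concentrations
    curve, fit = dose_response_experiment(cfg, grid, replicates=replicates)
    return {"curve": curve, "fit": fit}


def _sc_cooperativity_sweep(seed: int = 0, replicates: int = 3,
                            g0_values=(0.0, -200.0, -400.0, -600.0),
                            ej_values=tuple(-100.0 * k for k in range(10)),
                            concentrations: np.ndarray | None = None) -> dict:
    grid = MONO_GRID if concentrations is None else concentrations
    results = {}
    for g0 in g0_values:
        for ej in ej_values:
            cfg = base_receptor_config(
                seed, energy=EnergyParams(g0=g0, ej=ej))
            curve, fit = dose_response_experiment(cfg, grid,
                                                  replicates=replicates)
            results[(g0, ej)] = {"curve": curve, "fit": fit}
    return {"results": results,
            "hill_by_params": {k: v["fit"].hill for k, v in results.items()}}


def _sc_mixed_ratio(seed: int = 0, replicates: int = 3,
                    tar_fractions=(1 / 3, 1 / 2, 2 / 3, 0.8, 0.9, 1.0),
                    concentrations: np.ndarray | None = None) -> dict:
    grid = MONO_GRID if concentrations is None else concentrations
    results = {}
    for frac in tar_fractions:
        cfg = base_receptor_config(seed, frac_tar=float(frac))
        curve, fit = dose_response_experiment(cfg, grid,
                                              replicates=replicates,
                                              readout="tar")
        results[float(frac)] = {"curve": curve, "fit": fit}
    return {"results": results,
            "hill_by_fraction": {f: v["fit"].hill
                                 for f, v in results.items()}}


def _sc_dual_ligand(seed: int = 0, replicates: int = 3,
                    concentrations: np.ndarray | None = None) -> dict:
    # 1:1 Tar:Tsr: with the Tsr half clamped inactive by Ser, the mixed
    # field settles at ~30% total activity (partial cooperative drag on
    # Tar); a Tsr majority would collapse the whole field instead
    cfg = base_receptor_config(
        seed, frac_tar=0.5,
        ligands=default_ligands(cross_binding=False, include_ser=True))
    grid = MONO_GRID if concentrations is None else concentrations
    return dual_ligand_experiment(cfg, grid, ser_concentration=1e-5,
                                  replicates=replicates)


def _sc_methylation_coupling(seed: int = 0, replicates: int = 3,
                             concentrations: np.ndarray | None = None) -> dict:
    cfg = base_receptor_config(
        seed, frac_tar=1 / 3,
        ligands=default_ligands(cross_binding=True))
    grid = BIPHASIC_GRID if concentrations is None else concentrations
    return {"results": methylation_sweep_experiment(
        cfg, grid, replicates=replicates)}


def _sc_adaptation(seed: int = 0, replicates: int = 1,
                   stimulus: float = 4e-6,
                   add_at: int = 30000, remove_at: int = 60000,
                   total: int = 90000) -> dict:
    cfg = base_pathway_config(
        seed,
        schedule=LigandSchedule([(add_at, "MeAsp", stimulus),
                                 (remove_at, "MeAsp", 0.0)]),
        iterations=total)
    return {"series": run(cfg), "config": cfg}


def _sc_dynamic_range(seed: int = 0, step_iters: int = 3000) -> dict:
    # default is the desk-scale protocol (steps shortened tenfold);
    # pass step_iters=30000 for the full-length staircase
    hetero = dict(frac_tar=0.5,
                  ligands=default_ligands(cross_binding=True))
    variants = {
        "homogeneous": base_pathway_config(seed),
        "heterogeneous": base_pathway_config(seed, **hetero),
        "heterogeneous-omega": base_pathway_config(
            seed, energy=EnergyParams(omega=0.2), **hetero),
    }
    out = dynamic_range_experiment(variants, step_iters=step_iters)
    out["saturation_M"] = {k: v["saturation_M"]
                           for k, v in out.items() if isinstance(v, dict)
                           and "saturation_M" in v}
    return out


SCENARIOS = {
    "cooperativity": _sc_cooperativity,
    "cooperativity-sweep": _sc_cooperativity_sweep,
    "mixed-ratio": _sc_mixed_ratio,
    "dual-ligand": _sc_dual_ligand,
    "methylation-coupling": _sc_methylation_coupling,
    "adaptation": _sc_adaptation,
    "dynamic-range": _sc_dynamic_range,
}


def scenario_names() -> list[str]:
    return sorted(SCENARIOS)


def run_scenario(name: str, **kw) -> dict:
    """Run a named scenario; raises KeyError for unknown names."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"available: {', '.join(scenario_names())}")
    return SCENARIOS[name](**kw)
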