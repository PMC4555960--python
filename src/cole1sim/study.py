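"""The published study protocol, end to end.

For each strain (low-copy, Rom-carrying; high-copy, rom-deleted):

1. build the replication-control network and load the published constants;
2. calibrate k3, k4, k26 against the measured copy number at the second
   harvest point (T2), simulated under normal nutrients (k24 x 0.01) for
   one generation starting from half the measured pre-division PCN;
3. validate on the held-out time points T1 and T3;
4. for the high-copy strain, run the three predictive nutrient scenarios
   from the T3 state for one generation (347 min).
"""

from __future__ import annotations

from dataclasses import dataclass

from .fitting import FitResult, FitSpec, fit_parameters, validate
from .network import (KineticParameters, ReactionNetwork, build_network,
                      load_parameters, load_study_table)
from .simulate import (InitialConditions, Trajectory, apply_scenario,
                       pcn_delta, simulate_generation)

#: fraction of tRNA assumed uncharged under normal nutrient supply
NORMAL_K24_FACTOR = 0.01


def initial_conditions(plasmid_type: str, time_point: str) -> InitialConditions:
    row = load_study_table()[plasmid_type]["timepoints"][time_point]
    return InitialConditions(row["rnaI"], row["rnaII"], row["pcn"], row["mu"],
                             time_point)


def duration_min(plasmid_type: str, time_point: str) -> float:
    """Simulation time = printed generation time of the harvest point."""
    return float(load_study_table()[plasmid_type]["timepoints"][time_point]
                 ["generation_min"])


@dataclass
class CalibratedModel:
    plasmid_type: str
    network: ReactionNetwork
    params: KineticParameters          # with fitted k3, k4, k26
    fit: FitResult
    spec: FitSpec


def calibrate(plasmid_type: str, n_starts: int = 16,
              seed: int = 0) -> CalibratedModel:
    """Fit k3/k4/k26 to the T2 anchor of one strain."""
    network = build_network(plasmid_type)
    base = load_parameters(plasmid_type)
    study = load_study_table()[plasmid_type]["timepoints"]
    spec = FitSpec(network=network, base_params=base,
                   ic_t2=initial_conditions(plasmid_type, "T2"),
                   duration_t2_min=duration_min(plasmid_type, "T2"),
                   target_pcn=float(study["T2"]["pcn"]),
                   k24_factor=NORMAL_K24_FACTOR)
    fit = fit_parameters(spec, n_starts=n_starts, seed=seed)
    return CalibratedModel(plasmid_type, network, fit.as_params(base), fit,
                           spec)


def simulate_timepoint(model: CalibratedModel, time_point: str,
                       scenario: str = "normal",
                       duration: float | None = None,
                       n_points: int = 50) -> Trajectory:
    """One single-generation run of a calibrated model."""
    ic = initial_conditions(model.plasmid_type, time_point)
    params, mu = apply_scenario(model.params, scenario, ic.mu)
    dur = duration if duration is not None else duration_min(
        model.plasmid_type, time_point)
    return simulate_generation(ic, model.network, params, dur, mu_per_h=mu,
                               n_points=n_points)


def validation_report(model: CalibratedModel) -> list[dict]:
    """Simulated vs measured copy number at the held-out points T1, T3."""
    study = load_study_table()[model.plasmid_type]["timepoints"]
    cases = {}
    for tp in ("T1", "T3"):
        cases[tp] = (initial_conditions(model.plasmid_type, tp),
                     duration_min(model.plasmid_type, tp),
                     float(study[tp]["pcn"]), float(study[tp]["pcn_sd"]))
    return validate(model.fit, model.spec, cases)


def scenario_production(model: CalibratedModel, time_point: str = "T3",
                        duration: float | None = None) -> dict[str, float]:
    """Net plasmid production per scenario over one generation."""
    out = {}
    for name in ("normal", "starvation", "modified_trna"):
        traj = simulate_timepoint(model, time_point, scenario=name,
                                  duration=duration)
        out[name] = pcn_delta(traj)
    return out
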