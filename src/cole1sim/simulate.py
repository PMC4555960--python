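"""Single-generation simulations of plasmid replication control.

A simulation follows one cell from a harvest time point to the moment just
before its next division: the state starts from the measured free RNAI and
RNAII pools plus half the measured plasmid copy number (the measured value
is taken to be the pre-division copy number), every unmeasured pool starts
at zero, and the ODE system is integrated for one generation time at the
growth rate measured for that time point.

Three predictive nutrient scenarios rescale the rate constants:

* ``normal``        -- amino acids plentiful; only 1% of tRNA is uncharged,
  so the tRNA synthesis constant k24 is multiplied by 0.01;
* ``starvation``    -- amino-acid starvation; every rate constant and the
  growth rate are multiplied by 0.1 while k24 stays at its full value;
* ``modified_trna`` -- a genome-encoded tRNA that can no longer be charged;
  all constants at full value, k24 included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import KineticParameters, ReactionNetwork
from .units import CELL_VOLUME_L, molecules_to_molar

#: solver tolerances; absolute tolerance in molar
RTOL = 1e-8
ATOL = 1e-12


class IntegrationError(RuntimeError):
    pass


def generation_time(mu_per_h: float) -> float:
    """Generation (doubling) time in minutes for growth rate ``mu`` (h^-1).

    Reported tables round this to the nearest minute; the exact float is
    returned here.
    """
    if mu_per_h <= 0:
        raise ValueError(f"growth rate must be positive, got {mu_per_h}")
    return math.log(2.0) / mu_per_h * 60.0


@dataclass(frozen=True)
class Scenario:
    """Multiplicative factors describing a nutrient condition."""
    name: str
    k24_factor: float
    global_k_factor: float
    mu_factor: float


SCENARIOS: dict[str, Scenario] = {
    "normal": Scenario("normal", k24_factor=0.01, global_k_factor=1.0, mu_factor=1.0),
    "starvation": Scenario("starvation", k24_factor=1.0, global_k_factor=0.1,
                           mu_factor=0.1),
    "modified_trna": Scenario("modified_trna", k24_factor=1.0,
                              global_k_factor=1.0, mu_factor=1.0),
}


def apply_scenario(params: KineticParameters, scenario: Scenario | str,
                   mu_per_h: float) -> tuple[KineticParameters, float]:
    """Rescale rate constants and growth rate for a nutrient scenario.

    Every constant is multiplied by the global factor; k24 additionally by
    its own factor.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    scaled = params.scaled(scenario.global_k_factor, {24: scenario.k24_factor})
    return scaled, mu_per_h * scenario.mu_factor


@dataclass(frozen=True)
class InitialConditions:
    """Measured state at one harvest time point (per-cell molecule counts)."""
    rnaI: float
    rnaII: float
    pcn_measured: float
    mu: float              # specific growth rate, h^-1
    time_point: str = ""

    def __post_init__(self):
        for name in ("rnaI", "rnaII", "pcn_measured", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def state_vector(self, network: ReactionNetwork,
                     volume_l: float = CELL_VOLUME_L) -> np.ndarray:
        """Initial molar state: measured RNAI/RNAII, half the measured
        plasmid copy number as free pDNA, everything else zero."""
        conc = np.zeros(network.n_species)
        conc[network.index["RNAI"]] = molecules_to_molar(self.rnaI, volume_l)
        conc[network.index["RNAII"]] = molecules_to_molar(self.rnaII, volume_l)
        conc[network.index["pDNA"]] = molecules_to_molar(
            self.pcn_measured / 2.0, volume_l)
        return conc


@dataclass
class Trajectory:
    """Integrated trajectory with per-cell plasmid copy-number readout."""
    times_min: np.ndarray
    concentrations: np.ndarray      # shape (n_times, n_species), molar
    network: ReactionNetwork
    volume_l: float
    mu_per_h: float

    @property
    def pcn_series(self) -> np.ndarray:
        from .units import AVOGADRO
        total = self.concentrations[:, self.network.plasmid_mask].sum(axis=1)
        return total * AVOGADRO * self.volume_l

    @property
    def initial_pcn(self) -> float:
        return float(self.pcn_series[0])

    @property
    def final_pcn(self) -> float:
        return float(self.pcn_series[-1])

    @property
    def final_pcn_rounded(self) -> int:
        return round(self.final_pcn)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(np.clip(self.concentrations, 0.0, None),
                          columns=list(self.network.species_names))
        df.insert(0, "time_min", self.times_min)
        df["PCN"] = self.pcn_series
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def pcn_delta(trajectory: Trajectory) -> float:
    """Net plasmid production over the run: final minus initial copy number."""
    return trajectory.final_pcn - trajectory.initial_pcn


def simulate_generation(ic: InitialConditions, network: ReactionNetwork,
                        params: KineticParameters, duration_min: float,
                        mu_per_h: float | None = None,
                        volume_l: float = CELL_VOLUME_L,
                        n_points: int = 200,
                        dilution: str = "plasmid_exempt",
                        rtol: float = RTOL, atol: float = ATOL) -> Trajectory:
    """Integrate the replication-control ODEs for one generation.

    ``mu_per_h`` defaults to the growth rate stored in the initial
    conditions; it is held constant over the run (one generation of a
    single cell at the harvest-time growth rate).

    ``dilution`` defaults to ``"plasmid_exempt"``: the run starts from half
    the measured pre-division copy number, so division halving already
    accounts for plasmid dilution and the continuous -mu[S] term is applied
    to the diffusible species only.  Pass ``"all"`` for the plain
    growth-dilution ODE on every species.
    """
    if duration_min <= 0:
        raise ValueError(f"duration must be positive, got {duration_min}")
    if mu_per_h is None:
        mu_per_h = ic.mu
    y0 = ic.state_vector(network, volume_l)
    return integrate(y0, network, params, duration_min, mu_per_h,
                     volume_l=volume_l, n_points=n_points, dilution=dilution,
                     rtol=rtol, atol=atol)


def integrate(y0: np.ndarray, network: ReactionNetwork,
              params: KineticParameters, duration_min: float, mu_per_h: float,
              volume_l: float = CELL_VOLUME_L, n_points: int = 200,
              dilution: str = "plasmid_exempt",
              rtol: float = RTOL, atol: float = ATOL) -> Trajectory:
    """Low-level stiff integration from an explicit molar state."""
    k_vec = network.rate_vector(params)

    def rhs(_t, y):
        return network.rhs(y, params, mu_per_h, k_vec=k_vec, dilution=dilution)

    t_eval = np.linspace(0.0, duration_min, n_points)
    sol = solve_ivp(rhs, (0.0, duration_min), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t = {sol.t[-1]:.3f} min: {sol.message}")
    conc = sol.y.T
    if conc.min() < -1e-8 * max(1.0, conc.max()):
        raise IntegrationError(
            f"negative concentration beyond tolerance: min = {conc.min():.3e} M")
    return Trajectory(sol.t, conc, network, volume_l, mu_per_h)
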