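"""Species, reactions and mass-action rate laws of the ColE1 control network.

The replication-control circuit is loaded from a packaged YAML table
(``data/network.yaml``) that fixes the mapping between the 26 reactions and
the 26 rate constants.  Two plasmid types are supported:

* ``low``  -- Rom-carrying low-copy plasmid: the full 26-reaction network;
* ``high`` -- rom-deleted high-copy plasmid: the same network with the five
  Rom-dependent reactions (and the Rom-containing species) removed.

All reactions follow mass-action kinetics.  Catalytic synthesis reactions
flagged ``gene_dosage`` use the summed concentration of all plasmid-bearing
species as their substrate, reflecting that every plasmid copy carries the
rnaI and rom genes regardless of origin occupancy.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

PLASMID_TYPES = ("low", "high")

#: constants that have no high-copy value; their reactions form the Rom layer
ROM_K_INDICES = frozenset({1, 2, 13, 20, 23})

_SPECIES_ROLES = ("plasmid-bearing", "free-RNA", "protein", "tRNA", "complex",
                  "bookkeeping")


class ConfigurationError(ValueError):
    """Raised for an invalid plasmid type or an inconsistent network table."""


@dataclass(frozen=True)
class Species:
    name: str
    role: str

    def __post_init__(self):
        if self.role not in _SPECIES_ROLES:
            raise ConfigurationError(f"unknown species role {self.role!r}")

    @property
    def is_plasmid(self) -> bool:
        return self.role == "plasmid-bearing"


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction referencing a single rate constant.

    ``order`` is the kinetic order (0, 1 or 2) and equals the total
    reactant stoichiometry except for the zeroth-order synthesis reactions.
    """

    rid: str
    k_index: int
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rom_dependent: bool = False
    gene_dosage: bool = False
    note: str = ""

    @property
    def order(self) -> int:
        return sum(s for _, s in self.reactants)

    def net_stoichiometry(self) -> dict[str, int]:
        net: dict[str, int] = {}
        for name, s in self.reactants:
            net[name] = net.get(name, 0) - s
        for name, s in self.products:
            net[name] = net.get(name, 0) + s
        return {k: v for k, v in net.items() if v != 0}


@dataclass
class KineticParameters:
    """Rate constants k1..k26 for one plasmid type.

    For ``plasmid_type='high'`` the five Rom-layer indices are absent.
    Units: min^-1 (first order), M^-1 min^-1 (second order) and M min^-1
    for the single zeroth-order constant k24.
    """

    k: dict[int, float]
    plasmid_type: str
    units: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.plasmid_type not in PLASMID_TYPES:
            raise ConfigurationError(
                f"unknown plasmid_type {self.plasmid_type!r}; "
                f"expected one of {PLASMID_TYPES}")
        for idx, value in self.k.items():
            if value < 0:
                raise ConfigurationError(
                    f"k{idx} must be non-negative, got {value}")
        if self.plasmid_type == "high" and ROM_K_INDICES & set(self.k):
            raise ConfigurationError(
                "high-copy parameters must not define the Rom-layer constants "
                f"{sorted(ROM_K_INDICES & set(self.k))}")

    def __getitem__(self, idx: int) -> float:
        try:
            return self.k[idx]
        except KeyError:
            raise ConfigurationError(
                f"k{idx} is not available for the {self.plasmid_type}-copy "
                "plasmid") from None

    def scaled(self, global_factor: float = 1.0,
               per_index: Mapping[int, float] | None = None) -> "KineticParameters":
        """Return a copy with every constant multiplied by ``global_factor``
        and, additionally, index-specific factors from ``per_index``."""
        per_index = dict(per_index or {})
        new_k = {i: v * global_factor * per_index.get(i, 1.0)
                 for i, v in self.k.items()}
        return KineticParameters(new_k, self.plasmid_type, dict(self.units))

    def replace(self, **by_index: float) -> "KineticParameters":
        """Return a copy with constants overridden, e.g. ``replace(k3=1e8)``."""
        new_k = dict(self.k)
        for key, value in by_index.items():
            if not key.startswith("k"):
                raise ConfigurationError(f"expected kN-style keyword, got {key!r}")
            new_k[int(key[1:])] = value
        return KineticParameters(new_k, self.plasmid_type, dict(self.units))


def _load_yaml_resource(name: str) -> dict:
    with resources.files("cole1sim.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def load_parameter_table() -> dict:
    """Raw published parameter table (all indices, both plasmid types)."""
    return _load_yaml_resource("parameters.yaml")["k"]


def load_parameters(plasmid_type: str) -> KineticParameters:
    """Published rate constants for one plasmid type."""
    if plasmid_type not in PLASMID_TYPES:
        raise ConfigurationError(f"unknown plasmid_type {plasmid_type!r}")
    table = load_parameter_table()
    k, units = {}, {}
    for idx, row in table.items():
        value = row[plasmid_type]
        if value is None:
            continue
        if float(value) <= 0:
            raise ConfigurationError(f"published k{idx} must be positive")
        k[int(idx)] = float(value)
        units[int(idx)] = row["unit"]
    return KineticParameters(k, plasmid_type, units)


def load_study_table() -> dict:
    """Measured growth rates and molecule counts per strain and time point."""
    return _load_yaml_resource("study.yaml")


class ReactionNetwork:
    """An immutable reaction network with precompiled stoichiometry."""

    def __init__(self, species: Iterable[Species], reactions: Iterable[Reaction],
                 plasmid_type: str):
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.plasmid_type = plasmid_type
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigurationError("species names must be unique")
        self.index = {name: i for i, name in enumerate(names)}
        for r in self.reactions:
            for name, _ in (*r.reactants, *r.products):
                if name not in self.index:
                    raise ConfigurationError(
                        f"reaction {r.rid} references unknown species {name!r}")
        self._compile()

    # -- structural views -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def plasmid_mask(self) -> np.ndarray:
        """Boolean mask over species that carry one plasmid copy each."""
        return self._plasmid_mask

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.rid == rid:
                return r
        raise KeyError(rid)

    def _compile(self) -> None:
        ns, nr = self.n_species, self.n_reactions
        self._stoich = np.zeros((ns, nr))
        self._plasmid_mask = np.array([s.is_plasmid for s in self.species])
        self._dilution_masks = {
            "all": np.array([s.role != "bookkeeping" for s in self.species],
                            dtype=float),
            "plasmid_exempt": np.array(
                [s.role != "bookkeeping" and not s.is_plasmid
                 for s in self.species], dtype=float),
        }
        # reactant index lists per reaction for flux evaluation
        self._r_idx: list[tuple[int, ...]] = []
        self._gene_dosage = np.array([r.gene_dosage for r in self.reactions])
        for j, r in enumerate(self.reactions):
            for name, s in r.net_stoichiometry().items():
                self._stoich[self.index[name], j] = s
            idx: list[int] = []
            if not r.gene_dosage:
                for name, s in r.reactants:
                    idx.extend([self.index[name]] * s)
            self._r_idx.append(tuple(idx))

    # -- kinetics ---------------------------------------------------------
    def rate_vector(self, params: KineticParameters) -> np.ndarray:
        return np.array([params[r.k_index] for r in self.reactions])

    def fluxes(self, conc: np.ndarray, params: KineticParameters,
               k_vec: np.ndarray | None = None) -> np.ndarray:
        """Mass-action flux of every reaction (M/min) at concentrations
        ``conc`` (M).  ``k_vec`` may be supplied to avoid re-extraction."""
        k = self.rate_vector(params) if k_vec is None else k_vec
        flux = k.copy()
        plasmid_total = float(conc[self._plasmid_mask].sum())
        for j, idx in enumerate(self._r_idx):
            if self._gene_dosage[j]:
                flux[j] *= plasmid_total
            else:
                for i in idx:
                    flux[j] *= conc[i]
        return flux

    def rhs(self, conc: np.ndarray, params: KineticParameters, mu_per_h: float,
            k_vec: np.ndarray | None = None,
            dilution: str = "all") -> np.ndarray:
        """Time derivative of the state (M/min).

        d[S]/dt = sum of stoichiometry-weighted fluxes - (mu/60)[S],
        with the specific growth rate converted from h^-1 to min^-1.

        ``dilution`` selects which species carry the growth-dilution term:

        * ``"all"`` -- every physical species (the plain continuous-culture
          reading of the growth-dilution ODE);
        * ``"plasmid_exempt"`` -- diffusible species only.  This is the
          single-generation bookkeeping used for the study simulations:
          the run starts from half the measured pre-division copy number,
          so halving at division already accounts for plasmid dilution and
          a continuous -mu[S] on the plasmid pool would double-count it.

        The bookkeeping replication counter is never diluted.
        """
        if mu_per_h < 0:
            raise ValueError(f"growth rate must be non-negative, got {mu_per_h}")
        try:
            mask = self._dilution_masks[dilution]
        except KeyError:
            raise ValueError(f"unknown dilution mode {dilution!r}") from None
        flux = self.fluxes(conc, params, k_vec=k_vec)
        return self._stoich @ flux - (mu_per_h / 60.0) * mask * conc

    def pcn(self, conc: np.ndarray, volume_l: float) -> float:
        """Plasmid copy number: total concentration of plasmid-bearing
        species converted to molecules per cell."""
        from .units import molar_to_molecules
        return molar_to_molecules(float(conc[self._plasmid_mask].sum()), volume_l)


def reaction_rate(reaction: Reaction, conc: Mapping[str, float] | np.ndarray,
                  params: KineticParameters,
                  network: "ReactionNetwork | None" = None) -> float:
    """Mass-action flux (M/min) of a single reaction.

    ``conc`` may be a mapping species name -> molar concentration, or a
    state vector aligned with ``network.species``.
    """
    k = params[reaction.k_index]
    if reaction.gene_dosage:
        if network is None or not isinstance(conc, np.ndarray):
            raise ConfigurationError(
                "gene-dosage reactions need a network-aligned state vector")
        return k * float(conc[network.plasmid_mask].sum())
    flux = k
    for name, s in reaction.reactants:
        c = conc[network.index[name]] if isinstance(conc, np.ndarray) else conc[name]
        flux *= float(c) ** s
    return flux


def _load_network_table() -> dict:
    return _load_yaml_resource("network.yaml")


def build_network(plasmid_type: str) -> ReactionNetwork:
    """Build the replication-control network for one plasmid type.

    ``low`` yields the full 26-reaction network; ``high`` removes the five
    Rom-dependent reactions together with the Rom-containing species.
    """
    if plasmid_type not in PLASMID_TYPES:
        raise ConfigurationError(
            f"unknown plasmid_type {plasmid_type!r}; expected one of {PLASMID_TYPES}")
    table = _load_network_table()
    species = [Species(row["name"], row["role"]) for row in table["species"]]
    reactions = []
    for row in table["reactions"]:
        reactions.append(Reaction(
            rid=row["id"],
            k_index=int(row["k"]),
            reactants=tuple((n, int(s)) for n, s in (row.get("reactants") or {}).items()),
            products=tuple((n, int(s)) for n, s in (row.get("products") or {}).items()),
            rom_dependent=bool(row.get("rom_dependent", False)),
            gene_dosage=bool(row.get("gene_dosage", False)),
            note=row.get("note", ""),
        ))
    rom_rids = {r.rid for r in reactions if r.rom_dependent}
    rom_k = {r.k_index for r in reactions if r.rom_dependent}
    if rom_k != set(ROM_K_INDICES):
        raise ConfigurationError(
            f"Rom-dependent constants in the table are {sorted(rom_k)}, "
            f"expected {sorted(ROM_K_INDICES)}")
    if plasmid_type == "high":
        reactions = [r for r in reactions if not r.rom_dependent]
        used = {n for r in reactions for n, _ in (*r.reactants, *r.products)}
        species = [s for s in species
                   if s.name in used or s.role == "bookkeeping"]
    net = ReactionNetwork(species, reactions, plasmid_type)
    _check_reachability(net)
    return net


def _check_reachability(net: ReactionNetwork) -> None:
    used = {n for r in net.reactions for n, _ in (*r.reactants, *r.products)}
    orphans = set(net.species_names) - used
    if orphans:
        raise ConfigurationError(f"species take part in no reaction: {sorted(orphans)}")
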