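"""Parameter containers and loaders.

Two documents drive the model:

* ``data/network.yml`` — the versioned kinetic defaults of the reduced
  NADP-ME network (compartment volumes, per-reaction constants, light
  activation coefficients, temperature-response assignments, the
  dark-adaptation reference state).
* ``data/species.yml`` — the 11 gas-exchange-derived inputs per species
  (Ball-Berry slope/intercept, stomatal rate constants, Vpmax, Vcmax,
  tau_Rubisco, f_VmPEPC, f_VmRubisco, [PDRP], Rd).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import yaml

_NETWORK_KEYS = {
    "version",
    "compartments",
    "gas_exchange",
    "carbonic_anhydrase",
    "enzymes",
    "transports",
    "light_reactions",
    "stomata",
    "sinks",
    "pools",
    "pdrp",
    "light_activation",
    "temperature",
    "initial_state",
}

_ENZYME_KEYS = {
    "PEPC",
    "MDH",
    "ME",
    "PPDK",
    "mutase_enolase",
    "Rubisco",
    "GAPDH_bs",
    "GAPDH_mc",
    "FBPase",
    "SBPase",
    "PRK",
}


@dataclass(frozen=True)
class SpeciesParams:
    """The 11 species-level inputs of the dynamic model."""

    slope_bb: float
    intercept_bb: float
    gs_ki: float              # min-1
    gs_kd: float              # min-1
    vpmax: float              # umol m-2 s-1
    vcmax: float              # umol m-2 s-1
    tau_rubisco: float        # min
    f_vmpepc: float
    f_vmrubisco: float
    pdrp: float               # umol ([PDRP])
    rd: float                 # umol m-2 s-1
    name: str = "custom"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "name":
                continue
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or v <= 0:
                raise ValueError(f"SpeciesParams.{f.name} must be positive, got {v!r}")
        for f_name in ("f_vmpepc", "f_vmrubisco"):
            v = getattr(self, f_name)
            if not 0 < v <= 1.5:
                raise ValueError(f"SpeciesParams.{f_name} must be in (0, 1.5], got {v}")

    @property
    def vmax_pepc_model(self) -> float:
        """Model-level maximal PEPC activity, Vpmax / f_VmPEPC."""
        return self.vpmax / self.f_vmpepc

    @property
    def vmax_rubisco_model(self) -> float:
        """Model-level maximal Rubisco activity, Vcmax / f_VmRubisco."""
        return self.vcmax / self.f_vmrubisco


_NETWORK_CACHE: dict = {}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("c4dyn").joinpath("data", name)))


def load_network(path: str | Path | None = None) -> dict:
    """Load and schema-check the network kinetic defaults.

    The parsed document is cached per path; callers must treat the
    returned mapping as read-only (deep-copy before modifying).
    """
    path = Path(path) if path is not None else _data_path("network.yml")
    cached = _NETWORK_CACHE.get(path)
    if cached is not None:
        return cached
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    unknown = set(cfg) - _NETWORK_KEYS
    if unknown:
        raise ValueError(f"unknown network config keys: {sorted(unknown)}")
    missing = _NETWORK_KEYS - set(cfg)
    if missing:
        raise ValueError(f"missing network config keys: {sorted(missing)}")
    missing_enz = _ENZYME_KEYS - set(cfg["enzymes"])
    if missing_enz:
        raise ValueError(f"network config missing enzymes: {sorted(missing_enz)}")
    for comp, vol in cfg["compartments"].items():
        if vol <= 0:
            raise ValueError(f"compartment volume must be positive: {comp}={vol}")
    _NETWORK_CACHE[path] = cfg
    return cfg


def load_species_table(path: str | Path | None = None) -> dict[str, SpeciesParams]:
    """Load all species parameter sets keyed by name."""
    path = Path(path) if path is not None else _data_path("species.yml")
    with open(path, "r", encoding="utf-8") as fh:
        table = yaml.safe_load(fh)
    return {name: SpeciesParams(name=name, **vals) for name, vals in table.items()}


def get_species(name: str) -> SpeciesParams:
    """Look up one species parameter set ('original', 'maize', ...)."""
    table = load_species_table()
    if name not in table:
        raise KeyError(
            f"unknown species {name!r}; available: {sorted(table)}"
        )
    return table[name]
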