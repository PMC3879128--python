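"""Model constants for a kinesin ensemble pulling a shared cargo.

Units are fixed package-wide: length in nm, force in nN, time in s,
concentration in M, temperature in K.  Stiffness is nN/nm and energies
(k_B*T) come out in nN*nm (1 nN*nm = 1e-18 J).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Boltzmann constant in nN*nm / K (1.380649e-23 J/K, 1 J = 1e18 nN*nm).
BOLTZMANN_NN_NM = 1.380649e-5


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic and mechanical constants of the motor-ensemble model.

    Defaults are the experimentally determined kinesin-1 set used
    throughout the analysis.  ``l0`` (tether rest length) and
    ``sigma_th`` (thermal std of the cargo position) are not part of
    the measured set: ``l0`` defaults to 110 nm, a typical kinesin
    tether rest length, and ``sigma_th`` defaults to the equipartition
    value sqrt(k_B*T / k_el) ~ 3.60 nm.  Set ``sigma_th=0`` for the
    noiseless model variant.
    """

    k_cat: float = 105.0          # catalytic (hydrolysis) rate, 1/s
    k_on: float = 2.0e6           # ATP binding rate, 1/(M*s)
    k0_off: float = 55.0          # zero-force backward hydrolysis rate, 1/s
    atp: float = 2.0e-3           # ATP concentration, M
    F_s: float = 0.006            # stall force, nN
    d_s: float = 8.0              # lattice period, nm
    d_l: float = 1.6              # hydrolysis force-sensitivity length, nm
    delta_l: float = 1.3          # detachment force-sensitivity length, nm
    proc_A: float = 107.0         # processivity constant, dimensionless
    proc_B: float = 2.9e-8        # processivity constant, M
    T: float = 300.0              # temperature, K
    k_el: float = 0.32e-3         # linkage stiffness, nN/nm
    l0: float = 110.0             # linkage rest length, nm
    P_att: float = 5.0            # attachment rate per unattached motor, 1/s
    P_back: float = 2.0           # above-stall detachment rate, 1/s
    F_load: float = 0.0           # constant cargo load, nN
    sigma_th: float | None = None # thermal std of cargo position, nm
    m_bar: int = 2                # ensemble size
    n_cap: int | None = None      # optional user cap on the extent, sites
    quad_order: int = 21          # Gauss-Legendre order per smooth piece
    att_per_site: bool = False    # P_att per admissible site instead of total

    def __post_init__(self) -> None:
        if self.sigma_th is None:
            if self.k_el > 0 and self.T > 0:
                sigma = math.sqrt(BOLTZMANN_NN_NM * self.T / self.k_el)
            else:
                sigma = 0.0  # validation below rejects the parameters anyway
            object.__setattr__(self, "sigma_th", sigma)
        self.validate()

    def validate(self) -> None:
        positive = {
            "k_cat": self.k_cat, "k_on": self.k_on, "k0_off": self.k0_off,
            "atp": self.atp, "F_s": self.F_s, "d_s": self.d_s,
            "d_l": self.d_l, "delta_l": self.delta_l,
            "proc_A": self.proc_A, "proc_B": self.proc_B,
            "T": self.T, "k_el": self.k_el,
            "P_att": self.P_att, "P_back": self.P_back,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ParameterError(f"{name} must be strictly positive, got {value!r}")
        if self.F_load < 0:
            raise ParameterError(f"F_load must be >= 0, got {self.F_load!r}")
        if self.sigma_th < 0:
            raise ParameterError(f"sigma_th must be >= 0, got {self.sigma_th!r}")
        if self.l0 < 0:
            raise ParameterError(f"l0 must be >= 0, got {self.l0!r}")
        if int(self.m_bar) != self.m_bar or self.m_bar < 1:
            raise ParameterError(f"m_bar must be an integer >= 1, got {self.m_bar!r}")
        if self.n_cap is not None and self.n_cap < 1:
            raise ParameterError(f"n_cap must be >= 1 when set, got {self.n_cap!r}")
        if self.quad_order < 2:
            raise ParameterError(f"quad_order must be >= 2, got {self.quad_order!r}")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with selected fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def noiseless(self) -> "ModelParameters":
        """Copy with thermal fluctuations of the cargo switched off."""
        return self.replace(sigma_th=0.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_parameters(**overrides) -> ModelParameters:
    """The reference kinesin-1 parameter set (optionally overridden)."""
    return ModelParameters(**overrides)


def thermal_energy(p: ModelParameters) -> float:
    """k_B*T in nN*nm."""
    if not p.T > 0:
        raise ParameterError(f"T must be strictly positive, got {p.T!r}")
    return BOLTZMANN_NN_NM * p.T


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelParameters)}


def parameters_from_dict(data: dict) -> ModelParameters:
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParameters(**data)


def load_parameters(path: str | Path) -> ModelParameters:
    """Read a parameter file (YAML or JSON, chosen by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"parameter file {path} does not contain a mapping")
    return parameters_from_dict(data)


def save_parameters(p: ModelParameters, path: str | Path) -> None:
    path = Path(path)
    data = p.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
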