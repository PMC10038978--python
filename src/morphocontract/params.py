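"""Model parameters and biochemical equilibria.

The contraction model couples four biochemical species (fibroblasts ``N``,
myofibroblasts ``M``, signaling molecules ``c``, collagen ``rho``) with a
visco-elastic momentum balance for the displacement velocity ``v`` and a
morphoelastic evolution law for the effective strain ``eps``.  All 33
parameters live in the fixed unit system cm / day / g / cells / N; the
bundled defaults reproduce the published simulation values verbatim.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "ModelParameters",
    "StrainEquilibrium",
    "EquilibriumState",
    "derive_equilibrium",
    "DegenerateParameterError",
]


class DegenerateParameterError(ValueError):
    """Raised when a parameter combination makes the model degenerate."""


PARAMETER_UNITS: dict[str, str] = {
    "D_F": "cm^5/(cells day)",
    "chi_F": "cm^5/(g day)",
    "D_c": "cm^2/day",
    "r_F": "cm^{3q}/(cells^q day)",
    "r_F_max": "-",
    "a_c_I": "g/cm^3",
    "kappa_F": "cm^3/cells",
    "q": "-",
    "k_F": "cm^3/(g day)",
    "delta_N": "1/day",
    "delta_M": "1/day",
    "k_c": "g/(cells day)",
    "eta_I": "-",
    "eta_II": "-",
    "a_c_II": "cm^3/g",
    "a_c_III": "g/cm^3",
    "a_c_IV": "g/cm^3",
    "delta_c": "cm^6/(cells g day)",
    "k_rho": "g/(cells day)",
    "k_rho_max": "-",
    "delta_rho": "cm^6/(cells g day)",
    "N_bar": "cells/cm^3",
    "M_bar": "cells/cm^3",
    "c_bar": "g/cm^3",
    "rho_bar": "g/cm^3",
    "rho_t": "g/cm^3",
    "mu_1": "(N day)/cm^2",
    "mu_2": "(N day)/cm^2",
    "nu": "-",
    "E": "N/((g cm)^0.5)",
    "xi": "(N g)/(cells cm^2)",
    "R": "g/cm^3",
    "zeta": "cm^6/(cells g day)",
}


@dataclass(frozen=True)
class ModelParameters:
    """The full parameter set of the contraction model.

    Validation enforces: every parameter nonnegative except ``q`` (negative in
    the default set), ``nu`` strictly inside (0, 1/2), and the crowding bound
    ``kappa_F * N_bar < 1`` (required for a positive fibroblast apoptosis
    rate at equilibrium).
    """

    D_F: float
    chi_F: float
    D_c: float
    r_F: float
    r_F_max: float
    a_c_I: float
    kappa_F: float
    q: float
    k_F: float
    delta_N: float
    delta_M: float
    k_c: float
    eta_I: float
    eta_II: float
    a_c_II: float
    a_c_III: float
    a_c_IV: float
    delta_c: float
    k_rho: float
    k_rho_max: float
    delta_rho: float
    N_bar: float
    M_bar: float
    c_bar: float
    rho_bar: float
    rho_t: float
    mu_1: float
    mu_2: float
    nu: float
    E: float
    xi: float
    R: float
    zeta: float

    def __post_init__(self) -> None:
        for name in PARAMETER_UNITS:
            value = getattr(self, name)
            if name == "q":
                continue
            if value < 0:
                raise ValueError(f"parameter {name} must be nonnegative, got {value}")
        if not 0.0 < self.nu < 0.5:
            raise ValueError(f"nu must lie strictly in (0, 1/2), got {self.nu}")
        if self.kappa_F * self.N_bar >= 1.0:
            raise ValueError(
                "kappa_F * N_bar must be < 1 for a positive equilibrium "
                f"apoptosis rate, got {self.kappa_F * self.N_bar}"
            )

    # -- construction -----------------------------------------------------

    @classmethod
    def defaults(cls, **overrides: float) -> "ModelParameters":
        """Published default parameter set, with optional keyword overrides."""
        ref = importlib.resources.files("morphocontract").joinpath(
            "data/parameters_default.yaml"
        )
        values = yaml.safe_load(ref.read_text())
        return cls.from_dict({**values, **overrides})

    @classmethod
    def from_dict(cls, values: dict) -> "ModelParameters":
        unknown = set(values) - set(PARAMETER_UNITS)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAMETER_UNITS) - set(values)
        if missing:
            raise KeyError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in values.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        """Read a key/value YAML config; omitted keys fall back to defaults."""
        values = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(values) - set(PARAMETER_UNITS)
        if unknown:
            raise KeyError(f"unknown parameter keys in {path}: {sorted(unknown)}")
        return cls.defaults(**values)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    # -- derived quantities ------------------------------------------------

    @property
    def apoptosis_balance(self) -> float:
        """r_F (1 - kappa_F N_bar) N_bar^q, the equilibrium apoptosis rate.

        Equals ``delta_N`` when the parameter table is self-consistent.
        """
        return self.r_F * (1.0 - self.kappa_F * self.N_bar) * self.N_bar**self.q

    @property
    def delta_N_residual(self) -> float:
        """Relative inconsistency between delta_N and the division balance."""
        return (self.delta_N - self.apoptosis_balance) / self.delta_N

    def consistent(self) -> "ModelParameters":
        """Copy with delta_N, k_rho and rho_bar satisfying the equilibrium
        identities to machine precision (the printed table satisfies them only
        to its own precision)."""
        return self.replace(
            delta_N=self.apoptosis_balance,
            rho_bar=math.sqrt(self.k_rho / self.delta_rho),
        )


@dataclass(frozen=True)
class StrainEquilibrium:
    """A spatially uniform effective-strain equilibrium (symmetric tensor)."""

    e11: float
    e12: float
    e22: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.e11, self.e12, self.e22)

    def swapped(self) -> "StrainEquilibrium":
        """Exchange the two normal components (x <-> y relabelling)."""
        return StrainEquilibrium(self.e22, self.e12, self.e11)


@dataclass(frozen=True)
class EquilibriumState:
    """The biochemical/mechanical equilibrium around which stability is studied."""

    N_eq: float
    M_eq: float
    c_eq: float
    rho_eq: float
    v_eq: tuple[float, float]
    strain_eq: StrainEquilibrium
    delta_N_residual: float


def derive_equilibrium(
    params: ModelParameters,
    strain_eq: StrainEquilibrium = StrainEquilibrium(0.0, 0.0, 0.0),
) -> EquilibriumState:
    """Equilibrium of the kinetic system: ``(N_bar, 0, 0, sqrt(k_rho/delta_rho))``.

    Collagen balance requires ``k_rho = delta_rho * rho_eq^2``; the fibroblast
    balance requires ``delta_N = r_F (1 - kappa_F N_bar) N_bar^q``, whose
    relative residual is reported (the printed table satisfies it to ~3e-4).
    """
    if params.delta_rho == 0.0:
        raise DegenerateParameterError("delta_rho = 0: collagen equilibrium undefined")
    rho_eq = math.sqrt(params.k_rho / params.delta_rho)
    return EquilibriumState(
        N_eq=params.N_bar,
        M_eq=0.0,
        c_eq=0.0,
        rho_eq=rho_eq,
        v_eq=(0.0, 0.0),
        strain_eq=strain_eq,
        delta_N_residual=params.delta_N_residual,
    )
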