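"""Parameter containers and the packaged default parameter set.

Two frozen dataclasses hold the model constants: :class:`DEBParams` for the
individual energy-budget model and :class:`IBMParams` for the population
layer (hatching, mortalities, spawning, scaling).  The packaged defaults are
the published estimates for the East China Sea hairtail stock and load via
:func:`default_deb_params` / :func:`default_ibm_params` or, from a user file,
:func:`load_params`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "DEBParams",
    "IBMParams",
    "default_deb_params",
    "default_ibm_params",
    "load_params",
    "dump_params",
]


@dataclass(frozen=True)
class DEBParams:
    """Constants of the abj (metabolic-acceleration) energy-budget model.

    Rates are specified at the reference temperature ``T_ref`` and scaled
    at run time by the five-parameter Arrhenius correction.
    """

    z: float            # zoom factor relative to L_m = 1 cm [-]
    v_dot: float        # energy conductance [cm/d]
    kappa: float        # allocation fraction to soma [-]
    kappa_R: float      # reproduction efficiency [-]
    p_M_vol: float      # volume-specific somatic maintenance [J/cm^3/d]
    E_G: float          # volume-specific cost of structure [J/cm^3]
    k_J_dot: float      # maturity maintenance rate coefficient [1/d]
    delta_M: float      # shape coefficient [-]
    T_A: float          # Arrhenius temperature [K]
    T_H: float          # upper tolerance boundary [K]
    T_L: float          # lower tolerance boundary [K]
    T_AH: float         # Arrhenius temperature above T_H [K]
    T_AL: float         # Arrhenius temperature below T_L [K]
    E_Hb: float         # maturity at birth [J]
    E_Hj: float         # maturity at metamorphosis [J]
    E_Hp: float         # maturity at puberty [J]
    h_a_ddot: float     # Weibull ageing acceleration [1/d^2]
    s_G: float          # Gompertz stress coefficient [-]
    e_j_content: float  # energy content of reserve [J/g]
    d_V: float          # specific density of structure [g/cm^3]
    T_ref: float = 293.15  # reference temperature [K]

    def __post_init__(self) -> None:
        if not 0.0 < self.kappa <= 1.0:
            raise ValueError(f"kappa must be in (0, 1], got {self.kappa}")
        if not 0.0 < self.kappa_R <= 1.0:
            raise ValueError(f"kappa_R must be in (0, 1], got {self.kappa_R}")
        for name in ("z", "v_dot", "p_M_vol", "E_G", "k_J_dot", "delta_M",
                     "e_j_content", "d_V", "E_Hb", "E_Hj", "E_Hp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.T_L < self.T_ref < self.T_H:
            raise ValueError(
                f"tolerance range must bracket T_ref: "
                f"{self.T_L} < {self.T_ref} < {self.T_H} violated")
        if not self.E_Hb < self.E_Hj < self.E_Hp:
            raise ValueError("maturity thresholds must satisfy E_Hb < E_Hj < E_Hp")

    # Derived quantities ---------------------------------------------------

    @property
    def p_Am(self) -> float:
        """Maximum surface-specific assimilation rate [J/cm^2/d].

        From the zoom-factor definition L_m = kappa*{p_Am}/[p_M] = z cm.
        """
        return self.z * self.p_M_vol / self.kappa

    @property
    def L_m(self) -> float:
        """Maximum structural length before acceleration [cm]."""
        return self.z

    @property
    def E_m(self) -> float:
        """Maximum reserve density [J/cm^3] (invariant under acceleration)."""
        return self.p_Am / self.v_dot

    def replace(self, **changes: float) -> "DEBParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class IBMParams:
    """Constants of the population layer on the reference area."""

    T_min: float        # minimum temperature for egg development [deg C]
    R_h: float          # hatching success probability [-]
    DD_min: float       # degree-day threshold for hatching [deg C d]
    M_egg: float        # maximum egg predation mortality [1/d]
    B_eggh: float       # half-saturation density, egg predation [kg/km^2]
    M_d: float          # maximum density-dependent mortality [1/d]
    B_fh: float         # half-saturation density, density mortality [kg/km^2]
    M_cm: float         # climate-related background mortality [1/d]
    M_flow: float       # river-flow mortality coefficient [1/d]
    M_rain: float       # rainfall mortality coefficient [1/d]
    e_age: float        # ageing mortality slope [1/d^2]
    Age_min: float      # age threshold for ageing mortality [d]
    area: float = 1000.0            # reference area [km^2]
    spawn_window: tuple[int, int] = (105, 288)  # day-of-year window
    spawn_T_min: float = 14.0       # minimum spawning temperature [deg C]
    fishing_min_length_cm: float = 10.0  # preanal length at first capture [cm]
    mean_individual_weight_g: float = 140.0  # survey conversion weight [g]
    cohort_floor: float = 1e-3      # pruning threshold [individuals]
    dry_to_wet: float = 1.0         # model- to survey-weight factor [-]

    def __post_init__(self) -> None:
        for name in ("M_egg", "M_d", "M_cm", "M_flow", "M_rain", "e_age"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.R_h <= 1.0:
            raise ValueError(f"R_h must be in [0, 1], got {self.R_h}")
        if self.area <= 0:
            raise ValueError("area must be positive")

    def replace(self, **changes) -> "IBMParams":
        return dataclasses.replace(self, **changes)


def _default_mapping() -> dict:
    text = resources.files("debibm.data").joinpath("params_default.yaml").read_text()
    return yaml.safe_load(text)


def _build(mapping: dict) -> tuple[DEBParams, IBMParams]:
    deb = dict(mapping.get("deb", {}))
    ibm = dict(mapping.get("ibm", {}))
    missing = [f.name for f in dataclasses.fields(DEBParams)
               if f.name not in deb and f.default is dataclasses.MISSING]
    missing += [f.name for f in dataclasses.fields(IBMParams)
                if f.name not in ibm and f.default is dataclasses.MISSING]
    if missing:
        raise KeyError(f"parameter file is missing required keys: {sorted(missing)}")
    if "spawn_window" in ibm:
        ibm["spawn_window"] = tuple(int(v) for v in ibm["spawn_window"])
    return DEBParams(**deb), IBMParams(**ibm)


def default_deb_params() -> DEBParams:
    """The packaged DEB parameter set for the hairtail."""
    return _build(_default_mapping())[0]


def default_ibm_params() -> IBMParams:
    """The packaged population (IBM) parameter set for the hairtail."""
    return _build(_default_mapping())[1]


def load_params(path: str | Path) -> tuple[DEBParams, IBMParams]:
    """Load a ``deb:``/``ibm:`` YAML parameter file.

    Keys absent from the file fall back to the packaged defaults; unknown
    keys raise.
    """
    mapping = _default_mapping()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section in ("deb", "ibm"):
        block = user.get(section, {}) or {}
        known = {f.name for f in dataclasses.fields(
            DEBParams if section == "deb" else IBMParams)}
        unknown = set(block) - known
        if unknown:
            raise KeyError(f"unknown keys in [{section}]: {sorted(unknown)}")
        mapping[section].update(block)
    return _build(mapping)


def dump_params(deb: DEBParams, ibm: IBMParams, path: str | Path) -> None:
    """Write a parameter file readable by :func:`load_params`."""
    out = {"deb": dataclasses.asdict(deb), "ibm": dataclasses.asdict(ibm)}
    out["ibm"]["spawn_window"] = list(out["ibm"]["spawn_window"])
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
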