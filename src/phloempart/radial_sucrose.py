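"""SWEET-mediated sucrose efflux, SWEET+SUT retrieval and the apoplast pool.

Along the long-distance phloem, bidirectional SWEET transporters leak
sucrose from the sieve tubes into the apoplast (the extracellular space
between phloem and surrounding tissues) down its concentration gradient,
while SWEETs and proton-coupled SUT importers retrieve part of it.  Sucrose
that is neither retrieved nor delivered is consumed by the surrounding
tissues, modelled as first-order removal from the apoplast pool.  The
tuberigen SP6A binds SWEET transporters and reduces their transport
capacity by ~40% (``sp6a_factor = 0.6``).

Transporter rates are volumetric (mol per m^3 of phloem per s), so at a
spatially uniform phloem concentration the efflux is constant per unit
pathway length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "TransporterKinetics",
    "RadialSucroseConfig",
    "sweet_efflux_rate",
    "retrieval_rate",
    "apoplast_derivative",
    "net_efflux_fraction",
]


@dataclass
class TransporterKinetics:
    """Michaelis-Menten kinetics of a sucrose transporter population.

    ``v_max`` is volumetric (mol m^-3 s^-1, per phloem volume); ``k_m`` is in
    mol/m^3 (numerically equal to mM).
    """

    v_max: float
    k_m: float

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.k_m <= 0:
            raise ValueError("transporter v_max and K_m must be positive")

    def rate(self, c: np.ndarray | float) -> np.ndarray | float:
        return self.v_max * c / (self.k_m + c)


@dataclass
class RadialSucroseConfig:
    """Configuration of the phloem <-> apoplast sucrose exchange."""

    sweet_efflux: TransporterKinetics = field(
        default_factory=lambda: TransporterKinetics(0.148, 70.0))
    sweet_retrieval: TransporterKinetics = field(
        default_factory=lambda: TransporterKinetics(0.148, 10.0))
    sut_retrieval: TransporterKinetics = field(
        default_factory=lambda: TransporterKinetics(0.117, 1.0))
    #: apoplast pool volume as a fraction of the phloem element volume;
    #: affects only the transient, not the steady state (removal is
    #: first-order in apoplast concentration, see below).
    apoplast_volume_fraction: float = 0.05
    #: removal from the apoplast by the surrounding tissues, first-order in
    #: the apoplast concentration and scaled by the phloem element volume:
    #: ``removal = rate * c_apo * V_elem`` (rate in s^-1).  Calibrated once
    #: so the maximum net efflux over the standard loading scan is ~23% of
    #: the loading rate.
    apoplast_removal_rate: float = 0.0
    #: whether SP6A also scales the retrieval-side SWEET activity (it binds
    #: the transporter itself, so the default is to scale both directions).
    sp6a_affects_retrieval: bool = True
    #: zones that exchange sucrose with the apoplast.
    zones: tuple[str, ...] = ("pathway_1", "pathway_2")

    def __post_init__(self) -> None:
        if not 0 < self.apoplast_volume_fraction <= 1:
            raise ValueError("apoplast_volume_fraction must be in (0, 1]")
        if self.apoplast_removal_rate < 0:
            raise ValueError("apoplast_removal_rate must be >= 0")
        self.zones = tuple(self.zones)

    def check(self) -> list[tuple[str, str]]:
        out = []
        if self.apoplast_removal_rate == 0:
            out.append(("warning",
                        "apoplast removal rate is zero: effluxed sucrose is "
                        "fully retrieved at steady state"))
        return out

    def to_dict(self) -> dict:
        return {
            "sweet_efflux": vars(self.sweet_efflux).copy(),
            "sweet_retrieval": vars(self.sweet_retrieval).copy(),
            "sut_retrieval": vars(self.sut_retrieval).copy(),
            "apoplast_volume_fraction": self.apoplast_volume_fraction,
            "apoplast_removal_rate": self.apoplast_removal_rate,
            "sp6a_affects_retrieval": self.sp6a_affects_retrieval,
            "zones": list(self.zones),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RadialSucroseConfig":
        d = dict(d)
        for key in ("sweet_efflux", "sweet_retrieval", "sut_retrieval"):
            if key in d:
                d[key] = TransporterKinetics(**d[key])
        if "zones" in d:
            d["zones"] = tuple(d["zones"])
        return cls(**d)

    def copy(self, **kwargs) -> "RadialSucroseConfig":
        return replace(self, **kwargs)


def sweet_efflux_rate(
    c_phloem: np.ndarray | float,
    kinetics: TransporterKinetics,
    sp6a_factor: float,
    element_volume: np.ndarray | float,
) -> np.ndarray | float:
    """SWEET-mediated efflux from the phloem, mol/s per element.

    ``element_volume`` is the phloem reference volume of the element, which
    makes the rate constant per unit length at uniform concentration.
    """
    return sp6a_factor * kinetics.rate(c_phloem) * element_volume


def retrieval_rate(
    c_apoplast: np.ndarray | float,
    config: RadialSucroseConfig,
    element_volume: np.ndarray | float,
    sp6a_factor: float = 1.0,
) -> np.ndarray | float:
    """SWEET plus SUT retrieval from the apoplast into the phloem, mol/s."""
    sweet_scale = sp6a_factor if config.sp6a_affects_retrieval else 1.0
    rate = (sweet_scale * config.sweet_retrieval.rate(c_apoplast)
            + config.sut_retrieval.rate(c_apoplast))
    return rate * element_volume


def apoplast_derivative(
    c_phloem: np.ndarray,
    s_apoplast: np.ndarray,
    element_volume: np.ndarray,
    config: RadialSucroseConfig,
    sp6a_factor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apoplast sucrose balance for the exchanging elements.

    Returns ``(dS_apo/dt, J_S_rad_phloem)`` in mol/s, where the phloem term
    is retrieval minus efflux (positive into the phloem).  Removal is
    first-order in the apoplast concentration and scales with the phloem
    element volume, so the steady state does not depend on the assumed
    apoplast volume fraction (which only sets the pool's inertia).
    """
    v_apo = config.apoplast_volume_fraction * element_volume
    c_apo = s_apoplast / v_apo
    efflux = sweet_efflux_rate(c_phloem, config.sweet_efflux, sp6a_factor,
                               element_volume)
    retrieval = retrieval_rate(c_apo, config, element_volume, sp6a_factor)
    removal = config.apoplast_removal_rate * c_apo * element_volume
    ds_apo = efflux - retrieval - removal
    j_s_rad = retrieval - efflux
    return ds_apo, j_s_rad


def net_efflux_fraction(result) -> float:
    """Fraction of loaded sucrose permanently lost through the apoplast.

    ``(loading - total unloading) / loading`` at steady state.  Returns 0.0
    when radial sucrose exchange is disabled; NaN (flagged undefined) at zero
    loading.
    """
    rs_cfg = result.config.radial_sucrose
    if rs_cfg is None or not rs_cfg.zones:
        return 0.0
    v0 = result.fluxes["v0"]
    if v0 == 0:
        return float("nan")
    return (v0 - result.fluxes["v1"] - result.fluxes.get("v2", 0.0)) / v0
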