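"""Fat-fraction-dependent tissue property model for hepatic microwave ablation.

Maps the voxel/ROI fat percentage of mDIXON-style fat-quantification imaging to
the dielectric, thermal, perfusion and Arrhenius parameters used by the wave
and bioheat solvers:

* thermal conductivity follows an exponential constitutive curve between the
  zero-fat liver value and the pure-fat value,
  ``k(f) = (k_liver - k_fat) * exp(tau_k * f) + k_fat`` with ``f`` in percent;
* electrical conductivity and relative permittivity follow a volume-fraction
  mixture of the liver and fat endpoint values;
* blood perfusion decreases linearly from the healthy rate toward a cirrhotic
  floor, saturating at a fat fraction of ``f_sat`` percent.

Disease states are indexed 0-4 (no infiltrative fat, low, mild, moderate and
high fatty liver disease) with the clinical fat-percent class boundaries at
6, 17 and 22 percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import PhysicalConstants, CONSTANTS

__all__ = [
    "MaterialModelParams",
    "TissueProperties",
    "DiseaseState",
    "DISEASE_LABELS",
    "DISEASE_FAT_MEANS",
    "DISEASE_FAT_SDS",
    "thermal_conductivity",
    "mix_dielectric",
    "perfusion_rate",
    "properties_for",
    "classify_disease",
    "disease_property_table",
    "export_property_table",
]


@dataclass(frozen=True)
class MaterialModelParams:
    """Parameters of the fat-dependent constitutive model.

    All endpoint values refer to 915 MHz human tissue data; ``tau_k`` is the
    (negative, dimensionless) exponent of the thermal-conductivity curve and
    ``f_sat`` the fat percentage at which perfusion saturates at the cirrhotic
    floor ``omega_cirr``.
    """

    k_liver: float = 0.521        # W/(m K), zero-fat parenchyma
    k_fat: float = 0.21           # W/(m K), pure fat
    tau_k: float = -0.0546        # 1/percent
    sigma_liver: float = 0.861    # S/m
    sigma_fat: float = 0.11       # S/m
    eps_liver: float = 46.8       # relative permittivity
    eps_fat: float = 10.8
    omega_0: float = 0.018        # 1/s, healthy perfusion
    omega_cirr: float = 0.011     # 1/s, cirrhotic floor
    f_sat: float = 35.0           # percent
    tumor_k: float = 0.624        # W/(m K)
    tumor_sigma: float = 1.24     # S/m
    tumor_eps: float = 55.7
    cp_liver: float = 3400.0      # J/(kg K)
    cp_fat: float = 2348.0
    rho_liver: float = 1050.0     # kg/m^3
    rho_fat: float = 911.0
    A_liver: float = 7.39e39      # 1/s, Arrhenius frequency factor
    A_fat: float = 4.43e16
    dE_liver: float = 2.58e5      # J/mol, activation energy
    dE_fat: float = 1.30e5

    def __post_init__(self) -> None:
        if not (self.k_liver > self.k_fat > 0):
            raise ValueError("require k_liver > k_fat > 0")
        if not (self.sigma_liver > self.sigma_fat > 0):
            raise ValueError("require sigma_liver > sigma_fat > 0")
        if not (self.eps_liver > self.eps_fat > 1):
            raise ValueError("require eps_liver > eps_fat > 1")
        if not (self.omega_0 > self.omega_cirr > 0):
            raise ValueError("require omega_0 > omega_cirr > 0")
        if not (0 < self.f_sat <= 100):
            raise ValueError("require 0 < f_sat <= 100")
        if self.tau_k >= 0:
            raise ValueError("tau_k must be negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MaterialModelParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def replace(self, **kw) -> "MaterialModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class TissueProperties:
    """Complete property set of one tissue role at one fat fraction."""

    k: float          # thermal conductivity, W/(m K)
    sigma: float      # electrical conductivity, S/m
    eps_r: float      # relative permittivity
    omega_b: float    # blood perfusion, 1/s
    cp: float         # heat capacity, J/(kg K)
    rho: float        # density, kg/m^3
    A: float          # Arrhenius frequency factor, 1/s
    dE: float         # activation energy, J/mol
    mu_r: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k", "sigma", "eps_r", "cp", "rho", "A", "dE"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.omega_b < 0:
            raise ValueError("omega_b must be >= 0")
        if self.mu_r != 1.0:
            raise ValueError("all tissues are non-magnetic (mu_r = 1)")


DISEASE_LABELS = ("None", "Low", "Mild", "Moderate", "High")
#: cohort mean fat percentage per disease index
DISEASE_FAT_MEANS = {0: 0.0, 1: 3.9, 2: 14.70, 3: 21.20, 4: 29.90}
#: cohort standard deviation of the ROI fat percentage per disease index
DISEASE_FAT_SDS = {0: 0.0, 1: 2.3, 2: 3.6, 3: 2.9, 4: 3.7}


@dataclass(frozen=True)
class DiseaseState:
    index: int
    label: str
    fat_percent: float

    def __post_init__(self) -> None:
        if not 0 <= self.index <= 4:
            raise ValueError("disease index must be 0-4")
        if DISEASE_LABELS[self.index] != self.label:
            raise ValueError("index/label mismatch")
        if self.fat_percent < 0:
            raise ValueError("fat_percent must be >= 0")


def _check_fat(f: float) -> float:
    f = float(f)
    if not np.isfinite(f) or f < 0:
        raise ValueError(f"fat percentage must be finite and >= 0, got {f}")
    return f


def thermal_conductivity(f: float, params: MaterialModelParams | None = None) -> float:
    """Thermal conductivity in W/(m K) at fat percentage ``f``.

    Exponential decay from the zero-fat liver value toward (but never
    reaching) the pure-fat value.
    """
    p = params or MaterialModelParams()
    f = _check_fat(f)
    return (p.k_liver - p.k_fat) * np.exp(p.tau_k * f) + p.k_fat


def mix_dielectric(f: float, params: MaterialModelParams | None = None) -> tuple[float, float]:
    """(electrical conductivity S/m, relative permittivity) at fat percent ``f``.

    Volume-fraction weighting of the liver and fat endpoint values; exact at
    both endpoints.
    """
    p = params or MaterialModelParams()
    f = _check_fat(f)
    if f > 100:
        raise ValueError("fat percentage must be <= 100 for the mixture model")
    w = f / 100.0
    sigma = p.sigma_liver * (1 - w) + p.sigma_fat * w
    eps_r = p.eps_liver * (1 - w) + p.eps_fat * w
    return sigma, eps_r


def perfusion_rate(f: float, params: MaterialModelParams | None = None) -> float:
    """Blood perfusion in 1/s at fat percentage ``f``.

    Linear interpolation from the healthy rate at zero fat to the cirrhotic
    floor at ``f_sat`` percent; constant at the floor beyond saturation.
    """
    p = params or MaterialModelParams()
    f = _check_fat(f)
    frac = min(f, p.f_sat) / p.f_sat
    return p.omega_0 + (p.omega_cirr - p.omega_0) * frac


def properties_for(
    role: str,
    f: float = 0.0,
    params: MaterialModelParams | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> TissueProperties:
    """Full property set for one tissue role.

    ``parenchyma`` evaluates the three constitutive curves at fat percent
    ``f`` with the bulk liver density/heat-capacity/Arrhenius constants (the
    bulk constants do not vary with fat fraction).  ``tumor`` uses the fixed
    HCC dielectric/thermal values with liver bulk constants; its perfusion
    defaults to that of the surrounding parenchyma at ``f``.  ``pure_fat``
    returns the fat endpoint constants (modelled as unperfused).
    """
    p = params or MaterialModelParams()
    if role == "parenchyma":
        sigma, eps_r = mix_dielectric(f, p)
        return TissueProperties(
            k=thermal_conductivity(f, p), sigma=sigma, eps_r=eps_r,
            omega_b=perfusion_rate(f, p),
            cp=p.cp_liver, rho=p.rho_liver, A=p.A_liver, dE=p.dE_liver,
        )
    if role == "tumor":
        return TissueProperties(
            k=p.tumor_k, sigma=p.tumor_sigma, eps_r=p.tumor_eps,
            omega_b=perfusion_rate(f, p),
            cp=p.cp_liver, rho=p.rho_liver, A=p.A_liver, dE=p.dE_liver,
        )
    if role == "pure_fat":
        return TissueProperties(
            k=p.k_fat, sigma=p.sigma_fat, eps_r=p.eps_fat, omega_b=0.0,
            cp=p.cp_fat, rho=p.rho_fat, A=p.A_fat, dE=p.dE_fat,
        )
    raise ValueError(f"unknown tissue role {role!r}")


def classify_disease(mean_fat: float) -> DiseaseState:
    """Clinical disease-state class of a mean liver fat percentage.

    0 maps to the no-infiltrative-fat index; the low/mild/moderate/high class
    boundaries at 6, 17 and 22 percent are left-closed/right-open so the
    partition is exhaustive and non-overlapping.
    """
    f = _check_fat(mean_fat)
    if f == 0:
        idx = 0
    elif f < 6:
        idx = 1
    elif f < 17:
        idx = 2
    elif f < 22:
        idx = 3
    else:
        idx = 4
    return DiseaseState(index=idx, label=DISEASE_LABELS[idx], fat_percent=f)


def disease_property_table(params: MaterialModelParams | None = None) -> pd.DataFrame:
    """Property table over the five disease states plus tumor and pure fat.

    Columns are keyed by disease index (and 'Tumor'/'Fat'); rows are the fat
    percentage and the four fat-dependent properties.
    """
    p = params or MaterialModelParams()
    cols: dict[str, dict[str, float]] = {}
    for idx in range(5):
        f = DISEASE_FAT_MEANS[idx]
        sigma, eps = mix_dielectric(f, p)
        cols[str(idx)] = {
            "fat_percent": f,
            "thermal_conductivity_W_per_mK": thermal_conductivity(f, p),
            "electrical_conductivity_S_per_m": sigma,
            "relative_permittivity": eps,
            "perfusion_per_s": perfusion_rate(f, p),
        }
    cols["Tumor"] = {
        "fat_percent": float("nan"),
        "thermal_conductivity_W_per_mK": p.tumor_k,
        "electrical_conductivity_S_per_m": p.tumor_sigma,
        "relative_permittivity": p.tumor_eps,
        "perfusion_per_s": float("nan"),
    }
    cols["Fat"] = {
        "fat_percent": 100.0,
        "thermal_conductivity_W_per_mK": p.k_fat,
        "electrical_conductivity_S_per_m": p.sigma_fat,
        "relative_permittivity": p.eps_fat,
        "perfusion_per_s": float("nan"),
    }
    return pd.DataFrame(cols)


def export_property_table(path: str | Path, params: MaterialModelParams | None = None) -> None:
    """Write the disease property table as CSV or JSON, by file suffix."""
    table = disease_property_table(params)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(json.loads(table.to_json()), indent=2))
    else:
        table.to_csv(path)
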