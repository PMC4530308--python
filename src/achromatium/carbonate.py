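"""Carbonate-system speciation for brackish spring water.

Computes stoichiometric carbonic-acid dissociation constants and the
calcite solubility product at in-situ temperature and salinity, speciates
dissolved inorganic carbon from the two quantities a field campaign
actually reports (pH and bicarbonate), evaluates the calcite saturation
state Omega, and expresses the proton stoichiometry of intracellular
calcite precipitation:

    Ca2+ + HCO3-  ->  CaCO3 + H+            (1 mol H+ per mol calcite)

Two independently published constant parameterizations are provided:

``millero06``
    K1/K2 fit of Millero et al. (2006), valid S 0-50, T 0-50 degC, on the
    seawater (concentration, mol/kg) scale.  Field pH measured against NBS
    buffers is an activity; by default it is converted to a concentration
    with a single-ion activity coefficient from the Davies equation, which
    has the correct freshwater limit (gamma -> 1 as S -> 0) and is well
    suited to the brackish ionic strengths (I ~ 0.35 at S ~ 17.5) of the
    spring this package models.  For open-ocean salinities the empirical
    seawater ``fH`` factor (Takahashi et al. 1982) is available instead.

``cai_wang98``
    K1/K2 fit of Cai & Wang (1998) for estuarine waters, valid S 0-49,
    expressed natively on the NBS (activity) scale, so NBS field pH is
    used directly with no conversion.

Calcite solubility uses the Mucci (1983) fit, whose zero-salinity limit is
the Plummer & Busenberg (1982) freshwater curve.  Constants are returned
in a :class:`ConstantSet` tagged with ``formulation_id`` so any derived
number is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import pandas as pd

from .errors import InputError, ValidityError

__all__ = [
    "WaterSample",
    "ConstantSet",
    "CarbonateSpeciation",
    "compute_constants",
    "speciate",
    "omega_calcite",
    "calcite_proton_yield",
    "conductivity_to_salinity",
    "hydrogen_activity_coefficient",
    "read_water_samples",
    "FORMULATIONS",
]

#: Conductivity of standard seawater (S = 35) at 25 degC, mS/cm.
SEAWATER_CONDUCTIVITY_25C = 53.087
#: Linear temperature coefficient of conductivity, per degC about 25 degC.
_COND_TEMP_COEFF = 0.0191

FORMULATIONS = ("millero06", "cai_wang98")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class WaterSample:
    """One water-chemistry observation.

    pH is on the NBS scale (what field meters calibrated against NBS
    buffers report); concentrations are mol/L unless suffixed otherwise.
    """

    label: str
    temperature_c: float
    ph: float
    bicarbonate_molar: float
    salinity_psu: Optional[float] = None
    calcium_molar: Optional[float] = None
    conductivity_ms_cm: Optional[float] = None
    sulfide_um: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.temperature_c <= 50.0:
            raise ValidityError(
                f"temperature_c={self.temperature_c} outside [0, 50] degC"
            )
        if not 2.0 <= self.ph <= 12.0:
            raise ValidityError(f"ph={self.ph} outside [2, 12]")
        if self.salinity_psu is not None and not 0.0 <= self.salinity_psu <= 50.0:
            raise ValidityError(f"salinity_psu={self.salinity_psu} outside [0, 50]")
        for name in ("bicarbonate_molar", "calcium_molar", "conductivity_ms_cm",
                     "sulfide_um"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InputError(f"{name} must be >= 0, got {v}")

    @property
    def salinity(self) -> float:
        """Salinity, derived from conductivity when not given directly."""
        if self.salinity_psu is not None:
            return self.salinity_psu
        if self.conductivity_ms_cm is not None:
            return conductivity_to_salinity(
                self.conductivity_ms_cm, self.temperature_c
            )
        raise InputError(
                f"sample {self.label!r} has neither salinity nor conductivity"
        )


@dataclass(frozen=True)
class ConstantSet:
    """Stoichiometric carbonate constants at one (T, S) condition.

    ``k1``/``k2`` are the first and second carbonic-acid dissociation
    constants and ``ksp_calcite`` the calcite solubility product, all on
    the mol-per-solution-mass/volume (not activity) basis of the tagged
    formulation; ``scale`` records the hydrogen-ion scale the constants
    expect ("concentration" or "nbs").
    """

    k1: float
    k2: float
    ksp_calcite: float
    temperature_c: float
    salinity_psu: float
    formulation_id: str
    scale: str = "concentration"

    def __post_init__(self):
        if not (self.k1 > self.k2 > 0.0):
            raise ValidityError(
                f"require k1 > k2 > 0, got k1={self.k1}, k2={self.k2}"
            )
        if self.ksp_calcite <= 0:
            raise ValidityError(f"ksp_calcite must be > 0, got {self.ksp_calcite}")

    @property
    def pk1(self) -> float:
        return -math.log10(self.k1)

    @property
    def pk2(self) -> float:
        return -math.log10(self.k2)


@dataclass(frozen=True)
class CarbonateSpeciation:
    """CO2(aq) / HCO3- / CO3-- split of DIC for one sample, mol/L."""

    co2_aq_molar: float
    hco3_molar: float
    co3_molar: float
    dic_molar: float
    omega_calcite: Optional[float] = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for name in ("co2_aq_molar", "hco3_molar", "co3_molar", "dic_molar"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        total = self.co2_aq_molar + self.hco3_molar + self.co3_molar
        if abs(total - self.dic_molar) > 1e-12 * max(self.dic_molar, 1e-300):
            raise InputError("DIC does not equal the sum of its species")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["units"] = "mol/L"
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# equilibrium-constant formulations


def _pk12_millero06(t_k: float, s: float) -> tuple[float, float]:
    # Millero et al. (2006) stoichiometric K1, K2; S 0-50, concentration scale.
    sr = math.sqrt(s)
    lnt = math.log(t_k)
    pk1_0 = -126.34048 + 6320.813 / t_k + 19.568224 * lnt
    pk1 = (
        pk1_0
        + 13.4191 * sr + 0.0331 * s - 5.33e-5 * s * s
        + (-530.123 * sr - 6.103 * s) / t_k
        + (-2.06950 * sr) * lnt
    )
    pk2_0 = -90.18333 + 5143.692 / t_k + 14.613358 * lnt
    pk2 = (
        pk2_0
        + 21.0894 * sr + 0.1248 * s - 3.687e-4 * s * s
        + (-772.483 * sr - 20.051 * s) / t_k
        + (-3.3336 * sr) * lnt
    )
    return pk1, pk2


def _pk12_cai_wang98(t_k: float, s: float) -> tuple[float, float]:
    # Cai & Wang (1998) estuarine K1, K2; S 0-49, NBS (activity) scale.
    sr = math.sqrt(s)
    f1 = 200.1 / t_k + 0.3220
    pk1 = (
        3404.71 / t_k + 0.032786 * t_k - 14.8435
        - 0.071692 * f1 * sr + 0.0021487 * s
    )
    f2 = -129.24 / t_k + 1.4381
    pk2 = (
        2902.39 / t_k + 0.02379 * t_k - 6.4980
        - 0.3191 * f2 * sr + 0.0198 * s
    )
    return pk1, pk2


def _log10_ksp_calcite_mucci83(t_k: float, s: float) -> float:
    # Mucci (1983); S -> 0 limit is Plummer & Busenberg (1982).
    sr = math.sqrt(s)
    log10t = math.log10(t_k)
    base = -171.9065 - 0.077993 * t_k + 2839.319 / t_k + 71.595 * log10t
    salt = (
        (-0.77712 + 0.0028426 * t_k + 178.34 / t_k) * sr
        - 0.07711 * s + 0.0041249 * s ** 1.5
    )
    return base + salt


_VALID_RANGES = {
    # formulation: (t_min, t_max, s_min, s_max), degC / psu
    "millero06": (0.0, 50.0, 0.0, 50.0),
    "cai_wang98": (0.0, 45.0, 0.0, 49.0),
}


def compute_constants(
    temperature_c: float,
    salinity_psu: float,
    formulation_id: str = "millero06",
) -> ConstantSet:
    """Evaluate K1, K2 and Ksp(calcite) at the requested T and S.

    Deterministic for fixed inputs; raises :class:`ValidityError` naming
    the violated bound when T or S falls outside the formulation's range.
    """
    if formulation_id not in _VALID_RANGES:
        raise InputError(
            f"unknown formulation {formulation_id!r}; choose from {FORMULATIONS}"
        )
    t_min, t_max, s_min, s_max = _VALID_RANGES[formulation_id]
    if not t_min <= temperature_c <= t_max:
        raise ValidityError(
            f"temperature {temperature_c} degC outside {formulation_id} "
            f"validity [{t_min}, {t_max}]"
        )
    if not s_min <= salinity_psu <= s_max:
        raise ValidityError(
            f"salinity {salinity_psu} outside {formulation_id} "
            f"validity [{s_min}, {s_max}]"
        )
    t_k = temperature_c + 273.15
    if formulation_id == "millero06":
        pk1, pk2 = _pk12_millero06(t_k, salinity_psu)
        scale = "concentration"
    else:
        pk1, pk2 = _pk12_cai_wang98(t_k, salinity_psu)
        scale = "nbs"
    ksp = 10.0 ** _log10_ksp_calcite_mucci83(t_k, salinity_psu)
    return ConstantSet(
        k1=10.0 ** -pk1,
        k2=10.0 ** -pk2,
        ksp_calcite=ksp,
        temperature_c=temperature_c,
        salinity_psu=salinity_psu,
        formulation_id=formulation_id,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# hydrogen-ion scale handling


def _debye_huckel_a(temperature_c: float) -> float:
    # Quadratic fit to the Debye-Huckel limiting slope for water
    # (0.4918 at 0, 0.5092 at 25, 0.5373 at 50 degC).
    t = temperature_c
    return 0.4918 + 4.82e-4 * t + 8.56e-6 * t * t


def ionic_strength_from_salinity(salinity_psu: float) -> float:
    """Seawater-composition ionic strength (mol/kg) at a given salinity."""
    return 19.924 * salinity_psu / (1000.0 - 1.005 * salinity_psu)


def hydrogen_activity_coefficient(
    temperature_c: float, salinity_psu: float, model: str = "davies"
) -> float:
    """Single-ion activity coefficient used to turn NBS pH into [H+].

    ``davies``: Davies equation at the seawater-composition ionic strength;
    exact freshwater limit, appropriate for brackish water (I <~ 0.7).
    ``fh_seawater``: empirical total-hydrogen factor fH of Takahashi et al.
    (1982); only meaningful at near-seawater salinities (S >~ 19).
    ``none``: returns 1 (treat the NBS pH as if it were a concentration;
    the "mixed-scale" shortcut).
    """
    if model == "none":
        return 1.0
    if model == "davies":
        i = ionic_strength_from_salinity(salinity_psu)
        if i == 0.0:
            return 1.0
        a = _debye_huckel_a(temperature_c)
        sqrt_i = math.sqrt(i)
        log10_gamma = -a * (sqrt_i / (1.0 + sqrt_i) - 0.3 * i)
        return 10.0 ** log10_gamma
    if model == "fh_seawater":
        t_k = temperature_c + 273.15
        return (
            1.2948 - 2.036e-3 * t_k
            + (4.607e-4 - 1.475e-6 * t_k) * salinity_psu ** 2
        )
    raise InputError(f"unknown activity model {model!r}")


# ---------------------------------------------------------------------------
# operations


def speciate(
    sample: WaterSample,
    constants: ConstantSet,
    ph_scale: str = "nbs",
    activity_model: str = "davies",
) -> CarbonateSpeciation:
    """Split DIC into CO2(aq)/HCO3-/CO3-- from measured pH and bicarbonate.

        CO2(aq) = [HCO3-] * [H+] / K1
        CO3--   = [HCO3-] * K2 / [H+]

    ``ph_scale`` declares what the sample's pH means: ``"nbs"`` (an
    activity; converted per ``activity_model`` when the constants are
    concentration-based) or ``"free"`` (already a concentration; used
    as-is).  NBS-native constants (cai_wang98) always consume the NBS pH
    directly.  Omega is populated iff the sample carries calcium.
    """
    if sample.bicarbonate_molar is None or not sample.bicarbonate_molar > 0:
        raise InputError(
            f"sample {sample.label!r}: bicarbonate_molar must be > 0 to speciate"
        )
    if ph_scale not in ("nbs", "free"):
        raise InputError(f"unknown ph_scale {ph_scale!r}")

    a_h = 10.0 ** (-sample.ph)
    if constants.scale == "nbs" or ph_scale == "free":
        h = a_h
        gamma = 1.0
    else:
        gamma = hydrogen_activity_coefficient(
            constants.temperature_c, constants.salinity_psu, activity_model
        )
        h = a_h / gamma

    hco3 = sample.bicarbonate_molar
    co2 = hco3 * h / constants.k1
    co3 = hco3 * constants.k2 / h
    omega = None
    if sample.calcium_molar is not None and sample.calcium_molar > 0:
        omega = omega_calcite(sample.calcium_molar, co3, constants.ksp_calcite)
    return CarbonateSpeciation(
        co2_aq_molar=co2,
        hco3_molar=hco3,
        co3_molar=co3,
        dic_molar=co2 + hco3 + co3,
        omega_calcite=omega,
        meta={
            "label": sample.label,
            "formulation_id": constants.formulation_id,
            "ph_scale": ph_scale,
            "activity_model": activity_model,
            "hydrogen_activity_coefficient": gamma,
        },
    )


def omega_calcite(calcium_molar: float, co3_molar: float, ksp: float) -> float:
    """Calcite saturation state Omega = [Ca2+][CO3--]/Ksp (> 1: supersaturated)."""
    for name, v in (
        ("calcium_molar", calcium_molar), ("co3_molar", co3_molar), ("ksp", ksp)
    ):
        if v <= 0:
            raise InputError(f"{name} must be > 0, got {v}")
    return calcium_molar * co3_molar / ksp


def calcite_proton_yield(calcite_mol: float) -> float:
    """Protons released by precipitating ``calcite_mol`` of CaCO3 (1:1)."""
    if calcite_mol < 0:
        raise InputError(f"calcite_mol must be >= 0, got {calcite_mol}")
    return calcite_mol


def conductivity_to_salinity(conductivity_ms_cm: float, temperature_c: float) -> float:
    """Approximate practical salinity from specific conductivity.

    Ratio-to-standard-seawater conversion: the reading is first adjusted
    to 25 degC with a linear 1.91 %/degC coefficient, then scaled by
    35 / 53.087 (standard seawater at 25 degC).  Approximate by design
    (a few percent against PSS-78 over brackish ranges); monotone
    increasing in conductivity.
    """
    if conductivity_ms_cm < 0:
        raise InputError(
            f"conductivity must be >= 0, got {conductivity_ms_cm}"
        )
    c25 = conductivity_ms_cm / (1.0 + _COND_TEMP_COEFF * (temperature_c - 25.0))
    return 35.0 * c25 / SEAWATER_CONDUCTIVITY_25C


# ---------------------------------------------------------------------------
# IO


def read_water_samples(path) -> list[WaterSample]:
    """Read a water-sample table from CSV.

    Expected header: label, temperature_c, ph, bicarbonate_mM and either
    salinity_psu or conductivity_ms_cm; optional calcium_mM, sulfide_uM.
    Millimolar columns are converted to mol/L on load; blanks are allowed
    for optional fields.
    """
    df = pd.read_csv(path)
    required = {"label", "temperature_c", "ph", "bicarbonate_mM"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"water-sample CSV missing columns: {sorted(missing)}")

    def _opt(row, col, scale=1.0):
        if col in row.index and pd.notna(row[col]):
            return float(row[col]) * scale
        return None

    samples = []
    for _, row in df.iterrows():
        samples.append(
            WaterSample(
                label=str(row["label"]),
                temperature_c=float(row["temperature_c"]),
                ph=float(row["ph"]),
                bicarbonate_molar=float(row["bicarbonate_mM"]) * 1e-3,
                salinity_psu=_opt(row, "salinity_psu"),
                conductivity_ms_cm=_opt(row, "conductivity_ms_cm"),
                calcium_molar=_opt(row, "calcium_mM", 1e-3),
                sulfide_um=_opt(row, "sulfide_uM"),
            )
        )
    return samples


def speciation_table(results: Iterable[CarbonateSpeciation]) -> pd.DataFrame:
    """Flatten speciation results into a DataFrame (mol/L columns)."""
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.meta.get("label", ""),
                "co2_aq_molar": r.co2_aq_molar,
                "hco3_molar": r.hco3_molar,
                "co3_molar": r.co3_molar,
                "dic_molar": r.dic_molar,
                "omega_calcite": r.omega_calcite,
                "formulation_id": r.meta.get("formulation_id", ""),
                "units": "mol/L",
            }
        )
    return pd.DataFrame(rows)
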