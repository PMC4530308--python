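"""Sediment sulfide reservoir budget.

For a bulk sediment volume, compares the two pools of reduced sulfur a
sulfide-oxidizing bacterium could draw on: sulfide dissolved in the pore
water, and sulfide locked in acid-volatile sulfide (AVS) minerals on the
solid phase.  Per cm3 of bulk sediment:

    dissolved (umol) = porosity * [sulfide]_porewater(uM) * 1e-3
    AVS       (umol) = (1 - porosity) * rho_solid(g/cm3) * AVS(umol/g)

The default solid grain density of 1.67 g/cm3 is a back-calibrated value:
it is the density that makes the printed AVS inventory endpoints follow
exactly from the measured 0.3-0.6 umol/g at porosity 0.9 (no grain
density was reported with the field data), and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import InputError, UndefinedRatioError
from .util import round_half_away

__all__ = [
    "SedimentSample",
    "dissolved_sulfide_inventory",
    "avs_inventory",
    "reservoir_ratio",
    "read_sediment_samples",
    "budget_table",
]

DEFAULT_GRAIN_DENSITY_G_CM3 = 1.67


@dataclass(frozen=True)
class SedimentSample:
    """One bulk sediment observation (concentrations per the field assay)."""

    label: str
    porosity: float
    dissolved_sulfide_um: float
    avs_umol_per_g: float
    solid_grain_density_g_cm3: float = DEFAULT_GRAIN_DENSITY_G_CM3
    bulk_volume_cm3: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.porosity <= 1.0:
            raise InputError(f"porosity must be in [0, 1], got {self.porosity}")
        if self.dissolved_sulfide_um < 0 or self.avs_umol_per_g < 0:
            raise InputError("sulfide concentrations must be >= 0")
        if self.solid_grain_density_g_cm3 <= 0 or self.bulk_volume_cm3 <= 0:
            raise InputError("density and bulk volume must be > 0")


def dissolved_sulfide_inventory(sample: SedimentSample) -> float:
    """Pore-water dissolved sulfide in the bulk volume, umol.

    uM * cm3 of pore water = nmol, hence the 1e-3 to umol.
    """
    return (
        sample.bulk_volume_cm3 * sample.porosity
        * sample.dissolved_sulfide_um * 1e-3
    )


def avs_inventory(sample: SedimentSample) -> float:
    """Mineral-bound (acid-volatile) sulfide in the bulk volume, umol."""
    return (
        sample.bulk_volume_cm3 * (1.0 - sample.porosity)
        * sample.solid_grain_density_g_cm3 * sample.avs_umol_per_g
    )


def reservoir_ratio(sample: SedimentSample) -> dict:
    """AVS : dissolved sulfide inventory ratio and which pool is larger."""
    dissolved = dissolved_sulfide_inventory(sample)
    if dissolved <= 0:
        raise UndefinedRatioError(
            f"sample {sample.label!r}: dissolved sulfide inventory is zero"
        )
    avs = avs_inventory(sample)
    ratio = avs / dissolved
    return {"avs_to_dissolved": ratio, "avs_larger": ratio > 1.0}


def read_sediment_samples(path) -> list[SedimentSample]:
    """Read sediment samples from CSV (label, porosity, dissolved_sulfide_uM,
    avs_umol_per_g; optional solid_grain_density_g_cm3, bulk_volume_cm3)."""
    df = pd.read_csv(path)
    required = {"label", "porosity", "dissolved_sulfide_uM", "avs_umol_per_g"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"sediment CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in ("solid_grain_density_g_cm3", "bulk_volume_cm3"):
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        out.append(
            SedimentSample(
                label=str(row["label"]),
                porosity=float(row["porosity"]),
                dissolved_sulfide_um=float(row["dissolved_sulfide_uM"]),
                avs_umol_per_g=float(row["avs_umol_per_g"]),
                **kwargs,
            )
        )
    return out


def budget_table(samples: Iterable[SedimentSample]) -> pd.DataFrame:
    """Inventory/ratio report, with display values rounded to 2 decimals
    (half away from zero) alongside full precision."""
    rows = []
    for s in samples:
        dissolved = dissolved_sulfide_inventory(s)
        avs = avs_inventory(s)
        rows.append(
            {
                "label": s.label,
                "porosity": s.porosity,
                "dissolved_umol": dissolved,
                "avs_umol": avs,
                "dissolved_umol_2dp": round_half_away(dissolved, 2),
                "avs_umol_2dp": round_half_away(avs, 2),
                "avs_to_dissolved": avs / dissolved if dissolved > 0 else float("nan"),
                "avs_larger": avs > dissolved,
            }
        )
    return pd.DataFrame(rows)
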