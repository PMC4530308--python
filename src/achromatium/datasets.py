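"""In-study input values used by the reproduction pipeline.

These are the measured field and assembly inputs of the Warm Mineral
Springs *Achromatium* study — surface-water geochemistry of the spring
basin on the two sampling dates, the littoral sediment characterization,
and the per-cell draft-genome statistics — recorded here as code so every
downstream number in the reproduction report is recomputed from explicit
inputs rather than looked up.
"""

from __future__ import annotations

from .carbonate import WaterSample
from .energetics import CalciteInventory, EnergeticsParams
from .sediment import SedimentSample

__all__ = [
    "BASIN_JUNE_2012",
    "BASIN_OCT_2013",
    "BASIN_SEDIMENT_AVS_LOW",
    "BASIN_SEDIMENT_AVS_HIGH",
    "CELL_CALCITE",
    "DEFAULT_ENERGETICS",
    "GENOME_TABLE",
]

#: Approximate bicarbonate of the spring water, mol/L (~2 mM).
BICARBONATE_MOLAR = 2e-3

#: Basin surface water, June 2012 sampling: the default condition for the
#: dissolved-CO2 estimate (pH 7.03, 29.6 degC, conductivity 28.9 mS/cm
#: i.e. roughly half-seawater salinity, sulfide 33.1 uM).
BASIN_JUNE_2012 = WaterSample(
    label="basin-2012-06",
    temperature_c=29.6,
    ph=7.03,
    bicarbonate_molar=BICARBONATE_MOLAR,
    conductivity_ms_cm=28.9,
    calcium_molar=11.1e-3,  # measured on the 2013 trip; only basin value
    sulfide_um=33.1,
)

#: Basin surface water, 28 October 2013 sampling.
BASIN_OCT_2013 = WaterSample(
    label="basin-2013-10-28",
    temperature_c=31.7,
    ph=7.32,
    bicarbonate_molar=BICARBONATE_MOLAR,
    conductivity_ms_cm=32.6,
    calcium_molar=11.1e-3,
    sulfide_um=None,  # below detection at the surface that day
)

#: Littoral basin sediment: porosity 0.9, pore-water sulfide taken as
#: 30 uM (upper bound of the water-column range), AVS 0.3-0.6 umol/g.
BASIN_SEDIMENT_AVS_LOW = SedimentSample(
    label="basin-littoral-avs-low",
    porosity=0.9,
    dissolved_sulfide_um=30.0,
    avs_umol_per_g=0.3,
)

BASIN_SEDIMENT_AVS_HIGH = SedimentSample(
    label="basin-littoral-avs-high",
    porosity=0.9,
    dissolved_sulfide_um=30.0,
    avs_umol_per_g=0.6,
)

#: Average per-cell calcite inventory (0.05 nmol Ca/cell, all as calcite).
CELL_CALCITE = CalciteInventory(calcite_mol_per_cell=5e-11)

DEFAULT_ENERGETICS = EnergeticsParams()

#: Draft single-cell genome statistics per cell: assembly size (Mbp),
#: marker-based completeness fraction, reported N50 (bp), contig count,
#: GC percent.
GENOME_TABLE = {
    "WMS1": {
        "assembly_size_mbp": 1.3,
        "completeness": 0.40,
        "n50_bp": 2561,
        "n_contigs": 669,
        "gc_percent": 39,
        "longest_contig_bp": 12446,
    },
    "WMS2": {
        "assembly_size_mbp": 2.8,
        "completeness": 0.80,
        "n50_bp": 8360,
        "n_contigs": 777,
        "gc_percent": 43,
        "longest_contig_bp": 47002,
    },
    "WMS3": {
        "assembly_size_mbp": 3.8,
        "completeness": 0.80,
        "n50_bp": 6610,
        "n_contigs": 1113,
        "gc_percent": 38,
        "longest_contig_bp": 31024,
    },
}
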