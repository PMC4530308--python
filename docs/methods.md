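# Methods

This note documents the models behind each module, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
tests do and do not establish.

## Carbonate system

Speciation is anchored on the two quantities the field campaign
measured: NBS-scale pH and bicarbonate (~2 mM). With stoichiometric
constants K1, K2:

    CO2(aq) = [HCO3-] · [H+] / K1
    CO3--   = [HCO3-] · K2 / [H+]
    DIC     = CO2(aq) + [HCO3-] + [CO3--]
    Omega   = [Ca2+][CO3--] / Ksp(calcite)

Alkalinity- or DIC-anchored solving is deliberately out of scope: pH and
HCO3⁻ are what exist for this site, and the closed forms make the DIC
conservation invariant exact by construction.

**Constant formulations.** Two independently published fits are
implemented, selected by `formulation_id`:

* `millero06` (default): K1/K2 valid over S 0–50 and T 0–50 °C on the
  seawater (concentration, mol/kg) scale. Published check values pinned
  in the tests: pK1 = 6.35 / pK2 = 10.33 at 25 °C freshwater,
  pK1 = 5.840 / pK2 = 8.966 at 25 °C, S 35.
* `cai_wang98`: an estuarine fit valid S 0–49, expressed natively on the
  NBS (activity) scale, so field pH enters with no conversion.

Ksp(calcite) uses the Mucci fit (log₁₀Ksp = −8.48 freshwater, −6.37 at
S 35, 25 °C). Constants are mol/kg-solution; bicarbonate is supplied in
mol/L. The ~1% solution-density difference between the two bases at
brackish salinity is ignored — far below the "about" precision of every
quantity derived here.

**pH scale handling.** A meter calibrated against NBS buffers reports a
hydrogen-ion *activity*; concentration-based constants need [H⁺]. For
`millero06` the conversion divides by a single-ion activity coefficient
γH (default `activity_model="davies"`): the Davies equation evaluated at
the seawater-composition ionic strength I = 19.924·S/(1000−1.005·S),
with the Debye–Hückel slope fitted quadratically in temperature. Davies
has the correct freshwater limit (γ→1) and is well suited to this site
(S ≈ 17.5, I ≈ 0.35). For open-ocean salinities the empirical seawater
factor fH (`"fh_seawater"`, valid S ≳ 19) is available, and
`"none"`/`ph_scale="free"` reproduces the mixed-scale shortcut of using
the NBS pH as a concentration. At the basin condition the treatments
give CO2(aq) ≈ 199 μM (Davies), 220 μM (NBS-native cai_wang98), and
144 μM (mixed-scale) — all within the "about 200 μM" envelope, but the
activity-consistent defaults sit closest to it.

**Cross-validation in lieu of a reference program.** The test suite
cross-checks the two formulations on CO2(aq): they agree within 0.2% at
the freshwater limit (where both are scale-free), within 10% at S ≥ 19
under a common seawater-type pH conversion, and within 20% everywhere on
the brackish grid at default settings — the latter being genuine,
documented disagreement between published scale conventions, not
implementation error (the constants themselves are pinned to published
values at the grid corners).

**Saturation state.** At basin conditions both formulations give
Ω ≈ 0.7–0.8: the spring water is *undersaturated* with respect to
calcite. This is a result, not a defect — intracellular precipitation in
undersaturated waters is precisely what makes the inclusions remarkable
and requires active ion accumulation by the cell.

**Conductivity → salinity** uses a ratio-to-standard-seawater
approximation (linear 1.91%/°C compensation to 25 °C, scaled by
35/53.087). It is flagged approximate; at this site it lands within a
few percent of PSS-78 and turns the recorded 28.9–32.6 mS/cm into
S ≈ 17.5–19 ("half seawater").

## Calcite chemiosmosis

Calcite precipitation at circumneutral pH releases one proton per
formula unit (Ca²⁺ + HCO3⁻ → CaCO3 + H⁺). Parameters, all overridable:

| parameter | default | meaning |
|---|---|---|
| `h_per_calcite` | 1 | mol H⁺ per mol CaCO3 precipitated |
| `h_per_atp` | 3 | mol H⁺ per mol ATP, aerobic; anaerobic stoichiometry is not established, so this is a free parameter |
| `calcite_mol_per_cell` | 5e-11 | 0.05 nmol, the average per-cell calcium inventory, assumed fully calcite |
| `atp_per_division_pmol_low/high` | 0.1 / 0.2 | *E. coli*-scale ATP cost per new cell |
| `vacuole_volume_fraction` | 0.8 | nitrate-vacuole share of cell volume |
| `vacuole_nitrate_molar` | 0.25 | vacuolar nitrate, mol/L |
| `atp_per_nitrate` | 16 | mol ATP per mol NO3⁻ respired against sulfur |

**Division accounting.** The default is cumulative: n doubling cycles
from one founder create 2ⁿ−1 new cells, each charged the per-division
cost, so cycles = max n with (2ⁿ−1)·c ≤ budget. This is the accounting
under which a 16 pmol budget funds exactly 6 cycles (64 cells) at
0.2 pmol and 7 (128) at 0.1 pmol. A "simple" mode (new cells =
budget/cost, giving 80–160) is exposed for comparison but is not the
default, because it counts cells rather than complete doublings. The
reporting layer truncates the ATP budget to integer picomoles (16.67 →
16); full precision is kept internally.

**Nitrate comparison.** Cell volume is an explicit input — the volumes
behind the published 0.08–375 μmol ATP range were never stated — so the
module reports the ratio and its log10 for user-chosen volumes
(back-solving the endpoints gives 2.5×10⁻⁸ and 1.17×10⁻⁴ L). Note the
lower endpoint is 5000× the calcite budget, i.e. 3.7 orders of
magnitude by raw log10.

## Sediment sulfide budget

Per bulk cm³: dissolved = φ·[HS⁻]·10⁻³ μmol (30 μM pore-water sulfide,
porosity φ = 0.9); AVS = (1−φ)·ρ·a μmol with a = 0.3–0.6 μmol/g solid.
The grain density ρ = 1.67 g/cm³ was **back-calibrated**: no density was
reported with the field data, and 1.67 is the unique value that carries
the measured 0.3 and 0.6 μmol/g to the published 0.05 and 0.10 μmol/cm³
endpoints at φ = 0.9. It is configurable and plausibly low for pure
silicates precisely because the sediment is a peat/sand mixture. Display
rounding is two decimals, half away from zero (0.027 → 0.03).

## Genome QC

* Length filter: contigs strictly shorter than 500 bp are removed
  (boundary kept at exactly 500).
* N50: the largest length L such that contigs ≥ L sum to at least half
  the assembly (the common convention; alternatives differ on ties, so
  this is pinned against a brute-force oracle on random sets).
* GC unimodality: Gaussian kernel smoothing with fixed bandwidth 0.02 GC
  units on a 1001-point grid over [0,1]; modes are strict local maxima
  above 1% of the peak density (ripple suppression). Bandwidth 0.02
  resolves mixtures separated by ≳0.1 GC while not splitting a single
  component of sd ≈ 0.03, the scale seen in clean single-cell
  assemblies.
* Completeness: fraction of a user-supplied single-copy marker set
  detected; marker detection (homology search) is out of scope. The
  bundled marker list is a synthetic placeholder of familiar
  housekeeping gene names, not the published set.
* Genome size: assembly/completeness, rounded to one decimal **half away
  from zero** — required for 1.3/0.40 → 3.25 → 3.3 (banker's rounding
  would print 3.2).

## Phylotyping

Percent identity uses the pairwise-deletion denominator (columns where
both sequences are non-gap); `all_columns` is available. N matches
nothing; U→T on load. The helix-38/V6 region is an annotation input
(alignment-specific coordinates, 0-based half-open); a sequence is
called Cluster A when the gap fraction in the region is ≥ 0.5, else
Cluster B. The published 91–92% identities of the real sequences require
the deposited accessions and are not asserted; the generator reproduces
the *structure* of that comparison with exact, count-based divergence.

## Synthetic data

Generators are deterministic in (seed, parameters) and emit versioned
JSON truth sidecars. Substitutions are placed by exact count (not
Bernoulli), so identity targets are exact by construction up to a ±1
column parity adjustment when 3+ sequences share one target; deletions
are contiguous gap blocks at stated coordinates, with substitutions kept
outside the region so expected identities stay closed-form. "paper"
scenarios emit the recorded study values verbatim. The generators do
*not* emulate MDA amplification bias, read-level errors, chimeras, or
phylogenetically realistic substitution processes — passing tests show
the metrics are computed correctly on known structure, not that the
upstream assembly pipeline would behave well on real single-cell data.

## Problem sizes and numerics

The acceptance-scale property checks use 1000 random contig sets (≤ 400
contigs each), a ~700-point budget/cost grid for division accounting,
200 marker-survey replicates at 1000 markers, and 1500-column
alignments — sizes chosen to exercise the estimators well past the
study's own scale while keeping the whole suite in seconds. Degenerate
inputs (empty contig lists, zero budgets, zero comparable columns,
completeness 0) raise typed errors rather than returning sentinels;
ratios with zero denominators raise `UndefinedRatioError`.

## Known limitations

* No alkalinity titration model, borate/phosphate contributions, or
  pressure corrections; Ω uses stoichiometric (not activity-corrected)
  Ca²⁺ and CO3²⁻, consistent with the concentration-based Ksp fit.
* The Davies equation is stretched above I ≈ 0.7 (S ≳ 35); use
  `fh_seawater` there.
* The chemiosmotic budget ignores the cost of pumping Ca²⁺ into the
  vacuole, membrane-potential partitioning of the proton-motive force,
  and pump kinetics; it is a stoichiometric ceiling, not a rate model.
* Completeness extrapolation inherits the binomial noise of small marker
  sets and assumes unbiased marker recovery, which amplification bias
  violates in real single-cell genomes.
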