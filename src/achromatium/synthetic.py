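"""Seeded generators for every input class, with ground-truth sidecars.

Each generator emulates one class of study input — surface-water
chemistry tables, sediment samples, single-copy marker surveys, contig
sets, aligned 16S sequences — with the generating parameters recorded in
a machine-readable truth record, so every pipeline stage can be tested
against known answers without any external data.

Design choices that make the truths exact:

* substitutions in :func:`gen_alignment` are placed by exact count, not
  by per-column probability, so pairwise identities are exact by
  construction (within the +/-1 column forced by parity when more than
  two sequences share one target);
* deletions are implanted as contiguous gap blocks at stated coordinates;
* "paper" scenarios emit the recorded study values verbatim rather than
  jittered draws.

All generators are deterministic in (seed, parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .genome_qc import ContigRecord, MarkerSurvey, PLACEHOLDER_MARKERS
from .phylotype import AlignedSequence, RegionAnnotation

__all__ = [
    "GeneratorConfig",
    "gen_water_samples",
    "gen_sediment_samples",
    "gen_marker_survey",
    "gen_contig_set",
    "gen_alignment",
    "write_truth",
]

TRUTH_SCHEMA = "achromatium-synthetic-truth/1"

#: Recorded WMS basin surface-water values (June 2012 sampling) used by
#: the exact "paper-basin" scenario.
_BASIN_2012 = {
    "label": "basin-2012-06",
    "temperature_c": 29.6,
    "ph": 7.03,
    "conductivity_ms_cm": 28.9,
    "bicarbonate_mM": 2.0,
    "calcium_mM": 11.1,
    "sulfide_uM": 33.1,
}
_BASIN_2013 = {
    "label": "basin-2013-10-28",
    "temperature_c": 31.7,
    "ph": 7.32,
    "conductivity_ms_cm": 32.6,
    "bicarbonate_mM": 2.0,
    "calcium_mM": 11.1,
    "sulfide_uM": None,
}

_WATER_COLUMNS = [
    "label", "temperature_c", "ph", "conductivity_ms_cm",
    "bicarbonate_mM", "calcium_mM", "sulfide_uM",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Common generator knobs; scenario-specific parameters ride in params."""

    seed: int = 0
    n_samples: int = 10
    scenario: str = "jittered"
    params: dict = field(default_factory=dict)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def write_truth(truth: dict, path) -> None:
    """Serialize a truth sidecar as versioned JSON."""
    payload = {"schema": TRUTH_SCHEMA, **truth}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# water and sediment tables


def gen_water_samples(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Water-chemistry table.

    scenario "paper-basin": the two recorded basin columns, verbatim.
    scenario "jittered": ``n_samples`` draws around the basin means.
    """
    if config.scenario == "paper-basin":
        df = pd.DataFrame([_BASIN_2012, _BASIN_2013], columns=_WATER_COLUMNS)
        truth = {
            "kind": "water_samples",
            "scenario": config.scenario,
            "provenance": {
                "basin-2012-06": "WMS basin surface water, June 2012 sampling",
                "basin-2013-10-28": "WMS basin surface water, 28 Oct 2013 sampling",
            },
            "values": [_BASIN_2012, _BASIN_2013],
        }
        return df, truth
    if config.scenario != "jittered":
        raise InputError(f"unknown water scenario {config.scenario!r}")
    rng = config.rng()
    rows = []
    for i in range(config.n_samples):
        rows.append(
            {
                "label": f"synthetic-{i:03d}",
                "temperature_c": float(np.clip(rng.normal(29.6, 1.0), 0, 50)),
                "ph": float(np.clip(rng.normal(7.1, 0.1), 2, 12)),
                "conductivity_ms_cm": float(max(rng.normal(29.5, 1.5), 0.1)),
                "bicarbonate_mM": float(max(rng.normal(2.0, 0.2), 0.05)),
                "calcium_mM": float(max(rng.normal(11.1, 0.5), 0.1)),
                "sulfide_uM": float(max(rng.normal(30.0, 5.0), 0.0)),
            }
        )
    df = pd.DataFrame(rows, columns=_WATER_COLUMNS)
    truth = {
        "kind": "water_samples",
        "scenario": "jittered",
        "seed": config.seed,
        "n_samples": config.n_samples,
        "means": {"temperature_c": 29.6, "ph": 7.1, "conductivity_ms_cm": 29.5,
                  "bicarbonate_mM": 2.0, "calcium_mM": 11.1, "sulfide_uM": 30.0},
    }
    return df, truth


def gen_sediment_samples(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Sediment table; scenario "paper" gives porosity 0.9 with the AVS
    endpoints 0.3 and 0.6 umol/g, "jittered" draws around them."""
    if config.scenario == "paper":
        rows = [
            {"label": "basin-littoral-avs-low", "porosity": 0.9,
             "dissolved_sulfide_uM": 30.0, "avs_umol_per_g": 0.3},
            {"label": "basin-littoral-avs-high", "porosity": 0.9,
             "dissolved_sulfide_uM": 30.0, "avs_umol_per_g": 0.6},
        ]
        truth = {
            "kind": "sediment_samples",
            "scenario": "paper",
            "provenance": "WMS littoral basin sediment characterization "
                          "(porosity 0.9; AVS 0.3-0.6 umol/g; 30 uM pore-water sulfide)",
            "values": rows,
        }
        return pd.DataFrame(rows), truth
    if config.scenario != "jittered":
        raise InputError(f"unknown sediment scenario {config.scenario!r}")
    rng = config.rng()
    rows = []
    for i in range(config.n_samples):
        rows.append(
            {
                "label": f"synthetic-sed-{i:03d}",
                "porosity": float(np.clip(rng.normal(0.9, 0.03), 0.0, 1.0)),
                "dissolved_sulfide_uM": float(max(rng.normal(30.0, 5.0), 0.0)),
                "avs_umol_per_g": float(max(rng.normal(0.45, 0.1), 0.0)),
            }
        )
    truth = {
        "kind": "sediment_samples", "scenario": "jittered",
        "seed": config.seed, "n_samples": config.n_samples,
        "means": {"porosity": 0.9, "dissolved_sulfide_uM": 30.0,
                  "avs_umol_per_g": 0.45},
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# marker surveys and contig sets


def gen_marker_survey(
    true_completeness: float,
    n_markers: int = len(PLACEHOLDER_MARKERS),
    seed: int = 0,
) -> tuple[MarkerSurvey, dict]:
    """Survey with each marker present independently with the given
    probability (degenerate at 0 and 1)."""
    if not 0.0 <= true_completeness <= 1.0:
        raise InputError("true_completeness must be in [0, 1]")
    if n_markers < 1:
        raise InputError("n_markers must be >= 1")
    if n_markers <= len(PLACEHOLDER_MARKERS):
        ids = list(PLACEHOLDER_MARKERS[:n_markers])
    else:
        ids = [f"marker{i:04d}" for i in range(n_markers)]
    rng = np.random.default_rng(seed)
    present_mask = rng.random(n_markers) < true_completeness
    survey = MarkerSurvey(
        frozenset(ids), dict(zip(ids, (bool(b) for b in present_mask)))
    )
    truth = {
        "kind": "marker_survey",
        "seed": seed,
        "true_completeness": true_completeness,
        "n_markers": n_markers,
        "n_present": int(present_mask.sum()),
    }
    return survey, truth


def gen_contig_set(
    n: int,
    median_length_bp: float = 2500.0,
    length_sigma: float = 1.0,
    gc_modes: list[tuple[float, float, float]] = ((0.39, 0.03, 1.0),),
    seed: int = 0,
) -> tuple[list[ContigRecord], dict]:
    """Contigs with log-normal lengths and mixture-of-Gaussians GC.

    ``gc_modes`` is a list of (mean, sd, weight).  The truth records the
    N50 of the emitted lengths via an independent cumulative-sum pass.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        rng.lognormal(np.log(median_length_bp), length_sigma, size=n), 1.0
    ).astype(int)
    means, sds, weights = (np.array(x, dtype=float) for x in zip(*gc_modes))
    weights = weights / weights.sum()
    comp = rng.choice(len(means), size=n, p=weights)
    gc = np.clip(rng.normal(means[comp], sds[comp]), 0.0, 1.0)
    contigs = [
        ContigRecord(f"contig{i:05d}", int(lengths[i]), float(gc[i]))
        for i in range(n)
    ]
    # brute-force N50 for the truth record
    srt = np.sort(lengths)[::-1]
    csum = np.cumsum(srt)
    true_n50 = int(srt[np.searchsorted(csum, csum[-1] / 2.0)])
    truth = {
        "kind": "contig_set",
        "seed": seed,
        "n": n,
        "gc_modes": [list(m) for m in gc_modes],
        "true_n50_bp": true_n50,
        "total_bp": int(csum[-1]),
    }
    return contigs, truth


# ---------------------------------------------------------------------------
# alignments


def gen_alignment(
    n_seqs: int,
    length: int,
    target_identity: float = 91.0,
    deletion_spec: tuple[RegionAnnotation, float] | None = None,
    deletion_seqs: tuple[int, ...] | None = None,
    seed: int = 0,
) -> tuple[list[AlignedSequence], dict]:
    """Alignment with count-based pairwise divergence and optional implanted
    deletion.

    Each sequence receives a private set of substituted columns (disjoint
    across sequences, outside any deletion region) sized so that every
    pair differs by ``round((1 - target/100) * length)`` columns, up to
    the +/-1 parity adjustment when ``n_seqs`` > 2 and the count is odd.
    ``deletion_spec`` = (region, coverage) implants a contiguous gap block
    covering the given fraction of the region, by default in the last
    sequence only (the Cluster A archetype).
    """
    if n_seqs < 2:
        raise InputError("alignment generator needs n_seqs >= 2")
    if length < 10:
        raise InputError("length must be >= 10")
    if not 0.0 <= target_identity <= 100.0:
        raise InputError("target_identity must be a percentage in [0, 100]")
    k = round((1.0 - target_identity / 100.0) * length)

    region = None
    gap_cols: list[int] = []
    if deletion_spec is not None:
        region, coverage = deletion_spec
        if not 0.0 <= coverage <= 1.0:
            raise InputError("deletion coverage must be in [0, 1]")
        if region.end_col > length:
            raise InputError("deletion region exceeds alignment length")
        n_gap = round(coverage * len(region))
        gap_cols = list(range(region.start_col, region.start_col + n_gap))
    if deletion_seqs is None:
        deletion_seqs = (n_seqs - 1,) if deletion_spec is not None else ()

    # per-sequence private substitution counts: a_i + a_j == k for all pairs
    if n_seqs == 2:
        counts = [0, k]
    elif k % 2 == 0:
        counts = [k // 2] * n_seqs
    else:
        counts = [k // 2 + 1] + [k // 2] * (n_seqs - 1)

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    root = rng.choice(bases, size=length)
    forbidden = set(range(region.start_col, region.end_col)) if region else set()
    available = [i for i in range(length) if i not in forbidden]
    if sum(counts) > len(available):
        raise InputError(
            "alignment too short for the requested divergence outside the "
            "deletion region"
        )
    chosen = rng.choice(len(available), size=sum(counts), replace=False)
    pool = [available[i] for i in chosen]

    seqs = []
    offset = 0
    private_cols = []
    for i in range(n_seqs):
        cols = pool[offset:offset + counts[i]]
        offset += counts[i]
        private_cols.append(sorted(cols))
        row = root.copy()
        for c in cols:
            row[c] = rng.choice(bases[bases != row[c]])
        if i in deletion_seqs:
            row[gap_cols] = "-"
        seqs.append(AlignedSequence(f"seq{i}", "".join(row)))

    # expected pairwise identities by construction
    expected = {}
    g = len(gap_cols)
    for i in range(n_seqs):
        for j in range(i + 1, n_seqs):
            d = counts[i] + counts[j]
            pair_gaps = g if (i in deletion_seqs or j in deletion_seqs) else 0
            comparable = length - pair_gaps
            expected[f"seq{i}|seq{j}"] = 100.0 * (comparable - d) / comparable
    truth = {
        "kind": "alignment",
        "seed": seed,
        "n_seqs": n_seqs,
        "length": length,
        "target_identity": target_identity,
        "substitutions_per_seq": counts,
        "private_columns": private_cols,
        "expected_identity": expected,
        "deletion": None if region is None else {
            "region": [region.start_col, region.end_col],
            "name": region.name,
            "gap_columns": gap_cols,
            "sequences": list(deletion_seqs),
        },
        "has_deletion": {f"seq{i}": (i in deletion_seqs) for i in range(n_seqs)},
    }
    return seqs, truth


def write_alignment_fasta(seqs: list[AlignedSequence], path) -> None:
    """Write an alignment as FASTA (one line per sequence)."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.seq_id}\n{s.residues}\n")
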