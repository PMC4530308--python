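"""Quality metrics for single-amplified bacterial genomes.

Single-cell assemblies produced after multiple displacement amplification
are systematically incomplete and at risk of contamination.  This module
implements the desk-side metrics used to screen and summarize them:
contig length filtering, assembly size, N50, a GC-distribution
unimodality screen (a bimodal GC histogram is a red flag for a mixed
assembly), marker-gene completeness, and completeness-scaled genome-size
extrapolation.

Marker detection itself (homology search) is out of scope: a
:class:`MarkerSurvey` records presence/absence of a user-supplied
single-copy marker set, and completeness is the detected fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .util import round_half_away

__all__ = [
    "ContigRecord",
    "MarkerSurvey",
    "CompletenessReport",
    "filter_contigs",
    "n50",
    "assembly_size_bp",
    "gc_unimodality",
    "completeness",
    "estimate_genome_size",
    "contigs_from_fasta",
    "read_contig_csv",
    "read_marker_survey",
    "PLACEHOLDER_MARKERS",
]

#: Synthetic stand-in for a conserved single-copy housekeeping marker set
#: (the canonical published list is not redistributed here); any marker
#: list can be supplied instead.
PLACEHOLDER_MARKERS = tuple(
    f"{gene}" for gene in (
        "dnaA", "dnaE", "dnaN", "dnaQ", "gyrA", "gyrB", "polA", "ligA",
        "rpoA", "rpoB", "rpoC", "nusA", "nusG", "infA", "infB", "infC",
        "tsf", "tufA", "fusA", "frr", "pyrG", "ffh", "ftsY", "secA",
        "secY", "rplA", "rplB", "rplC", "rplD", "rplE", "rplF", "rplM",
        "rpsB", "rpsC", "rpsE", "rpsJ",
    )
)


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig: id, length, and GC fraction."""

    contig_id: str
    length_bp: int
    gc_fraction: float

    def __post_init__(self):
        if self.length_bp < 1:
            raise InputError(f"length_bp must be >= 1, got {self.length_bp}")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise InputError(
                f"gc_fraction must be in [0, 1], got {self.gc_fraction}"
            )


@dataclass(frozen=True)
class MarkerSurvey:
    """Presence/absence of each marker in a single-copy marker set."""

    marker_ids: frozenset
    present: Mapping[str, bool]

    def __post_init__(self):
        if not self.marker_ids:
            raise InputError("marker set must be non-empty")
        stray = set(self.present) - set(self.marker_ids)
        if stray:
            raise InputError(f"present keys not in marker set: {sorted(stray)}")

    @classmethod
    def from_found(cls, marker_ids: Iterable[str], found: Iterable[str]):
        ids = frozenset(marker_ids)
        found = set(found)
        return cls(ids, {m: (m in found) for m in ids})


@dataclass(frozen=True)
class CompletenessReport:
    """Marker tally plus assembly- and genome-size summary for one cell."""

    n_markers: int
    n_found: int
    completeness: float
    assembly_size_mbp: float
    estimated_genome_size_mbp: Optional[float]

    def __post_init__(self):
        if self.n_found > self.n_markers:
            raise InputError("n_found cannot exceed n_markers")


# ---------------------------------------------------------------------------
# operations


def filter_contigs(
    contigs: list[ContigRecord], min_len_bp: int = 500
) -> list[ContigRecord]:
    """Drop contigs shorter than ``min_len_bp`` (strictly less), keep order."""
    if min_len_bp < 1:
        raise InputError(f"min_len_bp must be >= 1, got {min_len_bp}")
    return [c for c in contigs if c.length_bp >= min_len_bp]


def assembly_size_bp(contigs: list[ContigRecord]) -> int:
    return sum(c.length_bp for c in contigs)


def n50(contigs: list[ContigRecord]) -> int:
    """N50: the largest contig length L such that contigs of length >= L
    together cover at least half of the assembly."""
    if not contigs:
        raise InputError("n50 of an empty contig list is undefined")
    lengths = sorted((c.length_bp for c in contigs), reverse=True)
    half = sum(lengths) / 2.0
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def gc_unimodality(
    gc_values: Iterable[float],
    bandwidth: float = 0.02,
    grid_points: int = 1001,
    rel_height: float = 0.01,
) -> dict:
    """Count modes of the kernel-smoothed GC distribution on [0, 1].

    A Gaussian kernel of fixed ``bandwidth`` (GC-fraction units) is
    evaluated on a fixed grid; modes are strict local maxima whose density
    exceeds ``rel_height`` of the global peak (suppresses numerical
    ripples).  A clean single-genome assembly is expected to be unimodal.
    """
    values = np.asarray(list(gc_values), dtype=float)
    if values.size < 10:
        raise InputError(
            f"need at least 10 GC values for a mode count, got {values.size}"
        )
    if bandwidth <= 0:
        raise InputError(f"bandwidth must be > 0, got {bandwidth}")
    if np.any((values < 0) | (values > 1)):
        raise InputError("GC fractions must lie in [0, 1]")
    grid = np.linspace(0.0, 1.0, grid_points)
    z = (grid[:, None] - values[None, :]) / bandwidth
    density = np.exp(-0.5 * z * z).sum(axis=1) / (
        values.size * bandwidth * np.sqrt(2.0 * np.pi)
    )
    interior = density[1:-1]
    is_peak = (interior > density[:-2]) & (interior > density[2:])
    significant = interior > rel_height * density.max()
    n_modes = int(np.count_nonzero(is_peak & significant))
    # A distribution concentrated at a grid edge has its maximum on the
    # boundary; count it so constant data still reports one mode.
    for edge, neighbour in ((0, 1), (-1, -2)):
        if density[edge] > density[neighbour] and density[edge] > rel_height * density.max():
            n_modes += 1
    return {"n_modes": n_modes, "unimodal": n_modes == 1}


def completeness(survey: MarkerSurvey) -> float:
    """Fraction of the marker set detected, in [0, 1]."""
    n = len(survey.marker_ids)
    found = sum(bool(survey.present.get(m, False)) for m in survey.marker_ids)
    return found / n


def estimate_genome_size(assembly_size_mbp: float, completeness_frac: float) -> float:
    """Extrapolate genome size as assembly / completeness, Mbp.

    Rounded to one decimal with ties away from zero, matching how such
    tables are conventionally reported (3.25 -> 3.3).
    """
    if not 0.0 < completeness_frac <= 1.0:
        raise InputError(
            "completeness must be in (0, 1] to scale an assembly size; "
            "estimate completeness from a marker survey first"
        )
    if assembly_size_mbp < 0:
        raise InputError("assembly size must be >= 0")
    return round_half_away(assembly_size_mbp / completeness_frac, 1)


def survey_report(
    survey: MarkerSurvey, assembly_size_mbp: float
) -> CompletenessReport:
    """Bundle a marker survey and assembly size into a CompletenessReport."""
    frac = completeness(survey)
    est = estimate_genome_size(assembly_size_mbp, frac) if frac > 0 else None
    return CompletenessReport(
        n_markers=len(survey.marker_ids),
        n_found=round(frac * len(survey.marker_ids)),
        completeness=frac,
        assembly_size_mbp=assembly_size_mbp,
        estimated_genome_size_mbp=est,
    )


# ---------------------------------------------------------------------------
# IO


def contigs_from_fasta(path) -> list[ContigRecord]:
    """Build contig records from a FASTA file.

    GC is computed over unambiguous bases only (A/C/G/T denominator);
    records with no unambiguous bases get gc_fraction 0.
    """
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise InputError(f"contig {rec.id!r} has empty sequence")
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        denom = gc + at
        records.append(
            ContigRecord(
                contig_id=rec.id,
                length_bp=len(seq),
                gc_fraction=gc / denom if denom else 0.0,
            )
        )
    return records


def read_contig_csv(path) -> list[ContigRecord]:
    """Read precomputed contig stats (contig_id, length_bp, gc_fraction)."""
    df = pd.read_csv(path)
    missing = {"contig_id", "length_bp", "gc_fraction"} - set(df.columns)
    if missing:
        raise InputError(f"contig CSV missing columns: {sorted(missing)}")
    return [
        ContigRecord(str(r.contig_id), int(r.length_bp), float(r.gc_fraction))
        for r in df.itertuples()
    ]


def read_marker_survey(path) -> MarkerSurvey:
    """Read a two-column marker survey CSV (marker_id, present as 0/1)."""
    df = pd.read_csv(path)
    missing = {"marker_id", "present"} - set(df.columns)
    if missing:
        raise InputError(f"marker survey CSV missing columns: {sorted(missing)}")
    present = {str(r.marker_id): bool(int(r.present)) for r in df.itertuples()}
    return MarkerSurvey(frozenset(present), present)
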