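"""16S rRNA phylotype comparison on a fixed multiple alignment.

Pairwise percent identity between aligned sequences (pairwise-deletion
convention: columns where either sequence is gapped are excluded from the
denominator, configurable), and phylotype cluster assignment from the
presence/absence of the characteristic deletion spanning helix 38 of the
V6 region: sequences carrying the deletion belong to Cluster A,
full-length helix 38 sequences to Cluster B.

Alignment coordinates for the helix-38 region are supplied as an
annotation (0-based, half-open); the module does not hard-code reference
numbering, since column positions are alignment-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, InputError, UndefinedRatioError

__all__ = [
    "AlignedSequence",
    "RegionAnnotation",
    "pairwise_identity",
    "identity_matrix",
    "detect_helix38_deletion",
    "assign_cluster",
    "read_alignment",
    "read_region_annotations",
]

GAP = "-"
_ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class AlignedSequence:
    """One row of a multiple alignment; U is normalized to T on load."""

    seq_id: str
    residues: str

    def __post_init__(self):
        bad = set(self.residues.upper()) - _ALPHABET - {"U"}
        if bad:
            raise InputError(
                f"sequence {self.seq_id!r} contains invalid symbols {sorted(bad)}"
            )
        object.__setattr__(
            self, "residues", self.residues.upper().replace("U", "T")
        )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RegionAnnotation:
    """Named alignment column range, 0-based half-open [start_col, end_col)."""

    name: str
    start_col: int
    end_col: int

    def __post_init__(self):
        if not 0 <= self.start_col < self.end_col:
            raise InputError(
                f"region {self.name!r}: require 0 <= start < end, "
                f"got [{self.start_col}, {self.end_col})"
            )

    def __len__(self) -> int:
        return self.end_col - self.start_col


def pairwise_identity(
    a: AlignedSequence, b: AlignedSequence, denominator: str = "both_nongap"
) -> float:
    """Percent identity between two rows of one alignment.

    ``both_nongap`` (default): matches / columns where both are non-gap.
    ``all_columns``: matches / alignment length.  N never matches.
    """
    if len(a) != len(b):
        raise AlignmentError(
            f"{a.seq_id!r} ({len(a)} cols) and {b.seq_id!r} ({len(b)} cols) "
            "are not from the same alignment"
        )
    ra, rb = a.residues, b.residues
    matches = 0
    comparable = 0
    for x, y in zip(ra, rb):
        both_nongap = x != GAP and y != GAP
        if both_nongap:
            comparable += 1
            if x == y and x != "N":
                matches += 1
    if denominator == "both_nongap":
        if comparable == 0:
            raise UndefinedRatioError(
                f"{a.seq_id!r} vs {b.seq_id!r}: no columns where both are non-gap"
            )
        return 100.0 * matches / comparable
    if denominator == "all_columns":
        return 100.0 * matches / len(a)
    raise InputError(f"unknown denominator convention {denominator!r}")


def identity_matrix(
    alignment: list[AlignedSequence], denominator: str = "both_nongap"
) -> pd.DataFrame:
    """Symmetric percent-identity matrix (100 on the diagonal)."""
    if len(alignment) < 2:
        raise InputError("identity matrix needs at least 2 sequences")
    ids = [s.seq_id for s in alignment]
    n = len(alignment)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_identity(
                alignment[i], alignment[j], denominator
            )
    return pd.DataFrame(m, index=ids, columns=ids)


def detect_helix38_deletion(
    seq: AlignedSequence,
    region: RegionAnnotation,
    gap_fraction_threshold: float = 0.5,
) -> bool:
    """True iff the gap fraction within the region is >= the threshold."""
    if region.end_col > len(seq):
        raise InputError(
            f"region {region.name!r} [{region.start_col}, {region.end_col}) "
            f"exceeds alignment length {len(seq)}"
        )
    if not 0.0 < gap_fraction_threshold <= 1.0:
        raise InputError("gap_fraction_threshold must be in (0, 1]")
    window = seq.residues[region.start_col:region.end_col]
    return window.count(GAP) / len(window) >= gap_fraction_threshold


def assign_cluster(has_deletion: bool) -> str:
    """Helix-38 deletion -> Cluster "A"; intact helix -> Cluster "B"."""
    return "A" if has_deletion else "B"


# ---------------------------------------------------------------------------
# IO


def read_alignment(path) -> list[AlignedSequence]:
    """Read an aligned FASTA; enforces equal column counts."""
    from Bio import SeqIO

    seqs = [
        AlignedSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise InputError(f"no sequences found in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(
            f"alignment {path} has unequal sequence lengths: {sorted(lengths)}"
        )
    return seqs


def read_region_annotations(path) -> list[RegionAnnotation]:
    """Read region annotations from CSV (name, start_col, end_col)."""
    df = pd.read_csv(path)
    missing = {"name", "start_col", "end_col"} - set(df.columns)
    if missing:
        raise InputError(f"region CSV missing columns: {sorted(missing)}")
    return [
        RegionAnnotation(str(r.name), int(r.start_col), int(r.end_col))
        for r in df.itertuples()
    ]
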