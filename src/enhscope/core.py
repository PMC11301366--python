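"""Core domain types shared by every pipeline stage.

All genomic coordinates are BED-convention: 0-based, half-open
``[start, end)``.  GTF input (1-based, closed) is converted on read and
never leaks into the rest of the system.  The single overlap predicate
used everywhere is >= 1 bp intersection of half-open intervals, i.e. the
default behaviour of ``bedtools intersect``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)`` with a strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 bp intersection, strand-agnostic."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """Full containment of *other* within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def expanded(self, margin: int) -> "GenomicInterval":
        """Interval widened by ``margin`` bp on each side, clamped at 0."""
        return GenomicInterval(
            self.chrom, max(0, self.start - margin), self.end + margin, self.strand
        )


@dataclass
class CtssRecord:
    """One CAGE TSS: a width-1 position with per-sample 5'-end tag counts."""

    interval: GenomicInterval
    counts: np.ndarray  # shape (n_samples,), non-negative integers

    def __post_init__(self) -> None:
        if self.interval.length != 1:
            raise ValueError("CTSS interval must have width 1")
        if self.interval.strand not in ("+", "-"):
            raise ValueError("CTSS strand must be + or -")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("CTSS counts must be non-negative")

    @property
    def pos(self) -> int:
        return self.interval.start


@dataclass
class CountMatrix:
    """Features x samples count matrix, raw tags or TPM."""

    feature_ids: list
    sample_ids: list
    values: np.ndarray
    scale: str = "raw"  # {"raw", "tpm"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicated feature_ids")
        if self.scale not in ("raw", "tpm"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if (self.values < 0).any():
            raise ValueError("counts must be non-negative")

    def validate_tpm(self, rtol: float = 1e-6) -> None:
        """Check the TPM conservation invariant: columns sum to 1e6.

        Columns that are entirely zero (zero raw total) are exempt.
        """
        if self.scale != "tpm":
            raise ValueError("matrix is not TPM-scaled")
        sums = self.values.sum(axis=0)
        nz = sums > 0
        if not np.allclose(sums[nz], 1e6, rtol=rtol):
            raise ValueError("TPM columns do not sum to 1e6")

    def row(self, feature_id) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]


@dataclass(frozen=True)
class InteractionPair:
    """A chromatin interaction (e.g. one PCHi-C contact): two anchors.

    Anchors are order-normalised by (chrom, start) on construction.
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    source_label: str = ""

    def __post_init__(self) -> None:
        a, b = self.anchor_a, self.anchor_b
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            object.__setattr__(self, "anchor_a", b)
            object.__setattr__(self, "anchor_b", a)


@dataclass(frozen=True)
class SnpRecord:
    """A GWAS variant: lead SNP or an LD proxy of a lead SNP."""

    rsid: str
    position: GenomicInterval  # width 1
    trait: str
    role: str  # {"lead", "ld"}
    lead_rsid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position.length != 1:
            raise ValueError("SNP position must have width 1")
        if self.role not in ("lead", "ld"):
            raise ValueError(f"invalid SNP role {self.role!r}")
        if self.role == "ld" and not self.lead_rsid:
            raise ValueError("LD SNP requires lead_rsid")


@dataclass(frozen=True)
class Tad:
    """A topologically associating domain (unstranded interval)."""

    interval: GenomicInterval


def validate_intervals(intervals: Iterable[GenomicInterval]) -> int:
    """Global sweep: assert the half-open invariant over any interval set.

    Returns the number of intervals checked; raises on the first violation.
    (Construction already enforces the invariant; this guards data that
    crossed a serialisation boundary.)
    """
    n = 0
    for iv in intervals:
        if not (0 <= iv.start < iv.end) or not iv.chrom or iv.strand not in STRANDS:
            raise ValueError(f"invalid interval {iv}")
        n += 1
    return n


def sort_intervals(intervals: Sequence[GenomicInterval]) -> list:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))
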