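"""Strand-resolved base-count pileups from aligned reads.

The heteroplasmy caller consumes per-position, per-strand counts of the four
bases after quality filtering.  Bases below the PHRED base-quality or mapping
quality thresholds (defaults 30/30) contribute nothing; N bases, deletions and
inserted bases are never counted and do not add to depth; both mates of an
overlapping read pair are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import CoordinateError
from .reference import GENOME_LENGTH, MitoGenome

BASES = "ACGT"
BASE_INDEX: Mapping[str, int] = {b: i for i, b in enumerate(BASES)}
FORWARD, REVERSE = "+", "-"
_STRAND_INDEX = {FORWARD: 0, REVERSE: 1}

DEFAULT_BASEQ_MIN = 30
DEFAULT_MAPQ_MIN = 30


def normalize_circular(position: int, length: int = GENOME_LENGTH) -> int:
    """Map a possibly-wrapped coordinate onto 1..length (circular genome).

    ``16570 -> 1``, ``0 -> 16569``, in-range positions unchanged.
    """
    return (int(position) - 1) % length + 1


@dataclass(frozen=True)
class ReadObservation:
    """One filtered base observation from an aligned read."""

    position: int
    base: str
    base_quality: int
    mapping_quality: int
    strand: str  # "+" (forward) or "-" (reverse)

    def __post_init__(self) -> None:
        if self.base_quality < 0 or self.mapping_quality < 0:
            raise ValueError("qualities must be non-negative")
        if self.strand not in _STRAND_INDEX:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class StrandBaseCounts:
    """Per-strand base counts at one position."""

    position: int
    ref_base: str
    counts_forward: dict[str, int] = field(default_factory=lambda: dict.fromkeys(BASES, 0))
    counts_reverse: dict[str, int] = field(default_factory=lambda: dict.fromkeys(BASES, 0))

    def __post_init__(self) -> None:
        for counts in (self.counts_forward, self.counts_reverse):
            for base in BASES:
                counts.setdefault(base, 0)
                if counts[base] < 0:
                    raise ValueError("base counts must be non-negative")

    @property
    def depth_forward(self) -> int:
        return sum(self.counts_forward.values())

    @property
    def depth_reverse(self) -> int:
        return sum(self.counts_reverse.values())

    @property
    def pooled(self) -> dict[str, int]:
        return {
            b: self.counts_forward[b] + self.counts_reverse[b] for b in BASES
        }

    def swapped_strands(self) -> "StrandBaseCounts":
        return StrandBaseCounts(
            position=self.position,
            ref_base=self.ref_base,
            counts_forward=dict(self.counts_reverse),
            counts_reverse=dict(self.counts_forward),
        )


class Pileup:
    """Whole-genome strand-resolved counts backed by a numpy array.

    ``counts`` has shape ``(L, 2, 4)`` indexed by (0-based position, strand
    {0: forward, 1: reverse}, base A/C/G/T).
    """

    def __init__(self, ref: str, counts: np.ndarray | None = None):
        self.ref = ref.upper()
        L = len(self.ref)
        if counts is None:
            counts = np.zeros((L, 2, 4), dtype=np.int64)
        if counts.shape != (L, 2, 4):
            raise ValueError(f"counts shape {counts.shape} != ({L}, 2, 4)")
        self.counts = counts

    def __len__(self) -> int:
        return len(self.ref)

    @property
    def length(self) -> int:
        return len(self.ref)

    def site(self, position: int) -> StrandBaseCounts:
        i = int(position) - 1
        if not 0 <= i < len(self.ref):
            raise CoordinateError(f"position {position} outside 1..{len(self.ref)}")
        fwd, rev = self.counts[i]
        return StrandBaseCounts(
            position=int(position),
            ref_base=self.ref[i],
            counts_forward={b: int(fwd[j]) for b, j in BASE_INDEX.items()},
            counts_reverse={b: int(rev[j]) for b, j in BASE_INDEX.items()},
        )

    def __iter__(self) -> Iterator[StrandBaseCounts]:
        for position in range(1, len(self.ref) + 1):
            yield self.site(position)

    def depth(self, strand: str | None = None) -> np.ndarray:
        if strand is None:
            return self.counts.sum(axis=(1, 2))
        return self.counts[:, _STRAND_INDEX[strand], :].sum(axis=1)

    def total_count(self) -> int:
        return int(self.counts.sum())

    def swapped_strands(self) -> "Pileup":
        return Pileup(self.ref, self.counts[:, ::-1, :].copy())

    # -- TSV interface ------------------------------------------------------
    # One row per position per strand: pos ref strand A C G T depth

    TSV_HEADER = "pos\tref\tstrand\tA\tC\tG\tT\tdepth"

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write(self.TSV_HEADER + "\n")
            for i in range(len(self.ref)):
                for strand, s in ((FORWARD, 0), (REVERSE, 1)):
                    row = self.counts[i, s]
                    out.write(
                        f"{i + 1}\t{self.ref[i]}\t{strand}\t"
                        f"{row[0]}\t{row[1]}\t{row[2]}\t{row[3]}\t{int(row.sum())}\n"
                    )

    @classmethod
    def from_tsv(cls, path) -> "Pileup":
        positions: list[int] = []
        refs: dict[int, str] = {}
        rows: dict[tuple[int, int], list[int]] = {}
        with open(path) as handle:
            header = handle.readline().rstrip("\n")
            if header != cls.TSV_HEADER:
                raise ValueError(f"unexpected pileup header {header!r}")
            for line in handle:
                pos_s, ref, strand, a, c, g, t, _depth = line.rstrip("\n").split("\t")
                pos = int(pos_s)
                refs[pos] = ref
                rows[(pos, _STRAND_INDEX[strand])] = [int(a), int(c), int(g), int(t)]
                positions.append(pos)
        L = max(positions)
        ref_seq = "".join(refs.get(p, "N") for p in range(1, L + 1))
        counts = np.zeros((L, 2, 4), dtype=np.int64)
        for (pos, s), vals in rows.items():
            counts[pos - 1, s] = vals
        return cls(ref_seq, counts)


def build_pileup(
    observations: Iterable[ReadObservation],
    ref: str | MitoGenome,
    baseq_min: int = DEFAULT_BASEQ_MIN,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> Pileup:
    """Tally filtered observations into a strand-resolved pileup.

    Observations failing either quality threshold are dropped; N bases are
    excluded from counts and depth.  Positions outside the genome are wrapped
    circularly before counting.
    """
    if baseq_min < 0 or mapq_min < 0:
        raise ValueError("quality thresholds must be non-negative")
    ref_seq = ref.sequence if isinstance(ref, MitoGenome) else str(ref).upper()
    pileup = Pileup(ref_seq)
    L = len(ref_seq)
    for obs in observations:
        if obs.base_quality < baseq_min or obs.mapping_quality < mapq_min:
            continue
        if obs.base not in BASE_INDEX:  # N or other: never counted
            continue
        pos = normalize_circular(obs.position, L)
        pileup.counts[pos - 1, _STRAND_INDEX[obs.strand], BASE_INDEX[obs.base]] += 1
    return pileup


def observations_from_sam(
    path,
    contig: str | None = None,
) -> Iterator[ReadObservation]:
    """Stream per-base observations from a SAM/BAM file (indels skipped).

    Both mates of overlapping pairs are emitted; duplicates are not removed.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        for read in af.fetch(contig=contig, until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            quals = read.query_qualities
            seq = read.query_sequence
            if seq is None or quals is None:
                continue
            strand = REVERSE if read.is_reverse else FORWARD
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                yield ReadObservation(
                    position=rpos + 1,
                    base=seq[qpos].upper(),
                    base_quality=quals[qpos],
                    mapping_quality=read.mapping_quality,
                    strand=strand,
                )


def pileup_from_sam(
    path,
    ref: str | MitoGenome,
    baseq_min: int = DEFAULT_BASEQ_MIN,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    baq: bool = False,
    contig: str | None = None,
) -> Pileup:
    """Pileup from a SAM/BAM file.

    With ``baq=False`` (default) raw base qualities are used.  With
    ``baq=True`` base-alignment-quality recalibration is delegated to the
    htslib pileup engine; artifact diagnostics are defined with BAQ off.
    """
    if not baq:
        return build_pileup(
            observations_from_sam(path, contig=contig), ref,
            baseq_min=baseq_min, mapq_min=mapq_min,
        )
    import pysam

    ref_seq = ref.sequence if isinstance(ref, MitoGenome) else str(ref).upper()
    pileup = Pileup(ref_seq)
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        for col in af.pileup(
            contig=contig,
            stepper="samtools",
            compute_baq=True,
            ignore_overlaps=False,
            min_base_quality=baseq_min,
            min_mapping_quality=mapq_min,
            max_depth=1_000_000,
        ):
            i = col.reference_pos
            if not 0 <= i < len(ref_seq):
                continue
            for pread in col.pileups:
                if pread.is_del or pread.is_refskip or pread.query_position is None:
                    continue
                read = pread.alignment
                base = read.query_sequence[pread.query_position].upper()
                if base not in BASE_INDEX:
                    continue
                s = 1 if read.is_reverse else 0
                pileup.counts[i, s, BASE_INDEX[base]] += 1
    return pileup
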