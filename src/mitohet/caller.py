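"""Dual-strand point-heteroplasmy calling from strand-resolved base counts.

A site is called heteroplasmic when the same minor allele reaches the calling
threshold (default 1% of reads) on the forward strand AND on the reverse strand
independently — the two strands must confirm each other.  Two level conventions
are carried on every call:

``level_pct``
    percentage of the rCRS-non-reference ("mutated") nucleotide in the pooled
    counts; may exceed 50 when the reference allele is the minor component.
``minor_pct``
    percentage of the minor component, ``min(level_pct, 100 - level_pct)``,
    always in (0, 50]; used for the low/high (<10%) classification.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientCoverageError
from .pileup import BASES, Pileup, StrandBaseCounts

LOW_LEVEL_BOUNDARY_PCT = 10.0


@dataclass(frozen=True)
class CallThreshold:
    """Minimum minor-allele fraction required on each strand separately."""

    minor_fraction_min: float = 0.01
    per_strand: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.minor_fraction_min <= 0.5:
            raise ValueError("minor_fraction_min must lie in (0, 0.5]")


@dataclass
class HeteroplasmyCall:
    """A detected point heteroplasmy at one position of one sample."""

    position: int
    ref_base: str
    major_allele: str
    minor_allele: str
    level_pct: float
    minor_pct: float
    minor_fwd_pct: float
    minor_rev_pct: float
    depth_fwd: int
    depth_rev: int
    sample: str = ""
    filter_flags: set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.filter_flags


@dataclass(frozen=True)
class NoCall:
    """An explicit no-call with a machine-readable reason."""

    position: int
    reason: str  # insufficient_coverage | no_minor_allele | below_threshold


def _strand_fractions(counts: StrandBaseCounts) -> tuple[np.ndarray, np.ndarray, int, int]:
    fwd = np.array([counts.counts_forward[b] for b in BASES], dtype=float)
    rev = np.array([counts.counts_reverse[b] for b in BASES], dtype=float)
    df, dr = int(fwd.sum()), int(rev.sum())
    return fwd, rev, df, dr


def call_site(
    counts: StrandBaseCounts,
    threshold: CallThreshold = CallThreshold(),
    sample: str = "",
) -> HeteroplasmyCall | NoCall:
    """Apply the dual-strand rule to one site.

    A call is emitted iff some allele other than the pooled major reaches the
    threshold fraction on both strands.  The reported minor allele is the most
    frequent pooled allele among those passing; ties break toward the higher
    minimum per-strand fraction, then alphabetically.
    """
    fwd, rev, df, dr = _strand_fractions(counts)
    if df == 0 or dr == 0:
        return NoCall(counts.position, "insufficient_coverage")
    pooled = fwd + rev
    major_i = int(np.argmax(pooled))  # ties: first in A<C<G<T order
    minstrand = np.minimum(fwd / df, rev / dr)
    candidates = [
        i for i in range(4)
        if i != major_i and pooled[i] > 0
    ]
    if not candidates:
        return NoCall(counts.position, "no_minor_allele")
    passing = [i for i in candidates if minstrand[i] >= threshold.minor_fraction_min]
    if not passing:
        return NoCall(counts.position, "below_threshold")
    minor_i = max(passing, key=lambda i: (pooled[i], minstrand[i], -i))
    level = variant_level(counts)
    minor_pct = min(level, 100.0 - level)
    return HeteroplasmyCall(
        position=counts.position,
        ref_base=counts.ref_base,
        major_allele=BASES[major_i],
        minor_allele=BASES[minor_i],
        level_pct=level,
        minor_pct=minor_pct,
        minor_fwd_pct=100.0 * fwd[minor_i] / df,
        minor_rev_pct=100.0 * rev[minor_i] / dr,
        depth_fwd=df,
        depth_rev=dr,
        sample=sample,
    )


def variant_level(counts: StrandBaseCounts, ref_base: str | None = None) -> float:
    """Pooled percentage of the most frequent non-reference allele."""
    ref = ref_base or counts.ref_base
    pooled = counts.pooled
    depth = sum(pooled.values())
    if depth == 0:
        raise InsufficientCoverageError(
            f"zero pooled depth at position {counts.position}"
        )
    top_alt = max((pooled[b] for b in BASES if b != ref), default=0)
    return 100.0 * top_alt / depth


def classify_level(call: HeteroplasmyCall, boundary: float = LOW_LEVEL_BOUNDARY_PCT) -> str:
    """'low' for minor components below the boundary (default 10%), else 'high'."""
    return "low" if call.minor_pct < boundary else "high"


def call_pileup(
    pileup: Pileup,
    threshold: CallThreshold = CallThreshold(),
    sample: str = "",
    positions: Iterable[int] | None = None,
) -> list[HeteroplasmyCall]:
    """All PASS-eligible heteroplasmy calls in a pileup.

    A vectorised prefilter reproduces the dual-strand decision exactly, so
    :func:`call_site` is only evaluated at candidate positions.
    """
    if positions is not None:
        out = []
        for pos in positions:
            result = call_site(pileup.site(pos), threshold, sample=sample)
            if isinstance(result, HeteroplasmyCall):
                out.append(result)
        return out
    counts = pileup.counts.astype(float)  # (L, 2, 4)
    depths = counts.sum(axis=2)  # (L, 2)
    ok = (depths > 0).all(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = counts / depths[:, :, None]
    minstrand = np.minimum(fracs[:, 0, :], fracs[:, 1, :])  # (L, 4)
    pooled = counts.sum(axis=1)  # (L, 4)
    major = pooled.argmax(axis=1)
    minstrand[np.arange(len(pooled)), major] = -1.0
    candidate = ok & (np.nan_to_num(minstrand).max(axis=1) >= threshold.minor_fraction_min)
    calls = []
    for i in np.flatnonzero(candidate):
        result = call_site(pileup.site(int(i) + 1), threshold, sample=sample)
        if isinstance(result, HeteroplasmyCall):
            calls.append(result)
    return calls


# ---------------------------------------------------------------------------
# Calls TSV interface
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "sample", "pos", "ref", "major", "minor", "level_pct", "minor_pct",
    "minor_fwd_pct", "minor_rev_pct", "depth_fwd", "depth_rev", "filters",
]


def write_calls(calls: Sequence[HeteroplasmyCall], path) -> None:
    """Write calls as TSV; percentages rounded to two decimals on output only."""
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(CALL_COLUMNS)
        for c in calls:
            writer.writerow([
                c.sample, c.position, c.ref_base, c.major_allele, c.minor_allele,
                f"{c.level_pct:.2f}", f"{c.minor_pct:.2f}",
                f"{c.minor_fwd_pct:.2f}", f"{c.minor_rev_pct:.2f}",
                c.depth_fwd, c.depth_rev,
                ";".join(sorted(c.filter_flags)) or "PASS",
            ])


def read_calls(path) -> list[HeteroplasmyCall]:
    calls = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            flags = set() if row["filters"] == "PASS" else set(row["filters"].split(";"))
            calls.append(HeteroplasmyCall(
                position=int(row["pos"]),
                ref_base=row["ref"],
                major_allele=row["major"],
                minor_allele=row["minor"],
                level_pct=float(row["level_pct"]),
                minor_pct=float(row["minor_pct"]),
                minor_fwd_pct=float(row["minor_fwd_pct"]),
                minor_rev_pct=float(row["minor_rev_pct"]),
                depth_fwd=int(row["depth_fwd"]),
                depth_rev=int(row["depth_rev"]),
                sample=row["sample"],
                filter_flags=flags,
            ))
    return calls
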