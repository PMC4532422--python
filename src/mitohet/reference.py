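"""Circular rCRS reference model: genome container, gene annotation, variant labels.

The human mitochondrial genome is a 16,569-bp circle; all public coordinates in this
package are 1-based inclusive rCRS positions.  The gene annotation ships as a
versioned fixture table (``data/regions.tsv``) whose partition rows cover every
position exactly once; hypervariable segments of the control region are carried as
sub-features of ``MT-CR``.

Variant nomenclature follows the compact mitochondrial style used in the forensic
and population-genetics literature: ``m.G14560R`` is a point heteroplasmy at
position 14560 with reference base G and an A/G mixture (IUPAC R), ``m.G15498A``
a plain substitution, ``m.309.1C`` a single-base insertion after position 309,
``m.A3107d`` a deletion and ``m.16189LH`` a length-heteroplasmy annotation.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterator, Sequence

from Bio.Data import CodonTable

from .errors import AnnotationError, CoordinateError, LabelParseError

GENOME_LENGTH = 16569

#: IUPAC two-base ambiguity codes used to write point heteroplasmies.
IUPAC_PAIRS = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
}
_PAIR_TO_IUPAC = {pair: code for code, pair in IUPAC_PAIRS.items()}

#: Vertebrate mitochondrial genetic code (NCBI translation table 2).
MITO_CODON_TABLE = CodonTable.unambiguous_dna_by_id[2]

REGION_CLASSES = ("protein", "tRNA", "rRNA", "control")


def iupac_code(base_a: str, base_b: str) -> str:
    """Two-base IUPAC ambiguity code for an unordered base pair."""
    try:
        return _PAIR_TO_IUPAC[frozenset((base_a, base_b))]
    except KeyError:  # identical or non-ACGT bases
        raise LabelParseError(f"no ambiguity code for pair {base_a}/{base_b}")


def check_position(position: int) -> int:
    """Validate a 1-based rCRS coordinate (no wrapping)."""
    if not 1 <= int(position) <= GENOME_LENGTH:
        raise CoordinateError(
            f"position {position} outside 1..{GENOME_LENGTH}"
        )
    return int(position)


@dataclass(frozen=True)
class MitoGenome:
    """A full-length circular mitochondrial genome sequence."""

    sequence: str
    name: str = "rCRS"
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != GENOME_LENGTH:
            raise ValueError(
                f"mitochondrial genome must be {GENOME_LENGTH} bp, "
                f"got {len(self.sequence)}"
            )
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("genome alphabet restricted to A/C/G/T/N")

    def base(self, position: int) -> str:
        """Base at a 1-based position (positions wrap circularly)."""
        return self.sequence[(int(position) - 1) % GENOME_LENGTH]

    def context(self, position: int, window: int = 9) -> str:
        """Circular sequence neighbourhood of odd length ``window`` centred on
        ``position``, written with the centre base bracketed (``GG[T]ATGCAC``)."""
        if window < 1 or window % 2 == 0:
            raise ValueError("context window must be a positive odd number")
        half = window // 2
        left = "".join(self.base(position + d) for d in range(-half, 0))
        right = "".join(self.base(position + d) for d in range(1, half + 1))
        return f"{left}[{self.base(position)}]{right}"

    @classmethod
    def from_fasta(cls, path, name: str | None = None) -> "MitoGenome":
        from Bio import SeqIO

        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(sequence=str(record.seq).upper(), name=name or record.id)


@dataclass(frozen=True)
class GeneRegion:
    """One annotated region of the mitochondrial genome.

    ``end`` may be numerically smaller than ``start`` for the single region that
    wraps across the origin (the control region).  ``frame`` preserves the true
    reading frame of protein genes whose annotated start was trimmed to keep the
    annotation a strict partition.
    """

    name: str
    start: int
    end: int
    region_class: str
    strand: str = "+"
    frame: int = 0
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        check_position(self.start)
        check_position(self.end)

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    @property
    def length(self) -> int:
        if self.wraps:
            return GENOME_LENGTH - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        position = check_position(position)
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end


class GeneAnnotation:
    """Gene-region lookup over a partition fixture table.

    The partition rows must jointly cover positions 1..16569 with no overlap;
    this is validated at load time.  Sub-features (hypervariable segments,
    C-stretches) are kept separately and never participate in :meth:`locate`.
    """

    def __init__(self, regions: Sequence[GeneRegion]):
        self.regions = [r for r in regions if r.parent is None]
        self.subfeatures = [r for r in regions if r.parent is not None]
        self._by_name = {r.name: r for r in regions}
        self._validate_partition()
        linear = sorted(
            (r for r in self.regions if not r.wraps), key=lambda r: r.start
        )
        self._starts = [r.start for r in linear]
        self._linear = linear
        wrapped = [r for r in self.regions if r.wraps]
        self._wrapped = wrapped[0] if wrapped else None

    def _validate_partition(self) -> None:
        covered = sum(r.length for r in self.regions)
        if covered != GENOME_LENGTH:
            raise AnnotationError(
                f"partition rows cover {covered} bp, expected {GENOME_LENGTH}"
            )
        seen = [False] * (GENOME_LENGTH + 1)
        for region in self.regions:
            positions: Iterator[int]
            if region.wraps:
                positions = iter(
                    list(range(region.start, GENOME_LENGTH + 1))
                    + list(range(1, region.end + 1))
                )
            else:
                positions = iter(range(region.start, region.end + 1))
            for p in positions:
                if seen[p]:
                    raise AnnotationError(f"position {p} covered twice")
                seen[p] = True

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, name: str) -> GeneRegion:
        try:
            return self._by_name[name]
        except KeyError:
            raise AnnotationError(f"unknown region name {name!r}")

    def locate(self, position: int) -> GeneRegion:
        """The unique partition region containing a 1-based position."""
        position = check_position(position)
        i = bisect_right(self._starts, position) - 1
        if i >= 0 and self._linear[i].contains(position):
            return self._linear[i]
        if self._wrapped is not None and self._wrapped.contains(position):
            return self._wrapped
        raise AnnotationError(f"position {position} not covered")  # pragma: no cover

    def hypervariable_segment(self, position: int) -> str | None:
        """HVS-I/II/III label for control-region positions, else None."""
        for sub in self.subfeatures:
            if sub.parent == "MT-CR" and sub.contains(position):
                return sub.name
        return None

    def relative_gene_length(self, region: str | GeneRegion) -> float:
        """Region length as a fraction of the whole mitochondrial genome."""
        if isinstance(region, str):
            region = self[region]
        return region.length / GENOME_LENGTH

    @classmethod
    def from_tsv(cls, path) -> "GeneAnnotation":
        regions = []
        with open(path) as handle:
            header: list[str] | None = None
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                if header is None:
                    header = line.split("\t")
                    continue
                row = dict(zip(header, line.split("\t")))
                regions.append(
                    GeneRegion(
                        name=row["name"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        region_class=row["region_class"],
                        strand=row["strand"],
                        frame=int(row["frame"]),
                        parent=None if row["parent"] == "." else row["parent"],
                    )
                )
        return cls(regions)

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "GeneAnnotation":
        """The packaged rCRS annotation fixture."""
        with resources.as_file(
            resources.files("mitohet.data").joinpath("regions.tsv")
        ) as path:
            return cls.from_tsv(path)


# ---------------------------------------------------------------------------
# Variant labels
# ---------------------------------------------------------------------------

VARIANT_KINDS = ("substitution", "insertion", "deletion", "length_heteroplasmy")

_SUBST_RE = re.compile(r"m\.([ACGT])(\d+)([ACGTRYKMSW])\Z")
_INS_RE = re.compile(r"m\.(\d+)\.(\d+)([ACGT]+)\Z")
_DEL_RE = re.compile(r"m\.([ACGT])(\d+)d\Z")
_LH_RE = re.compile(r"m\.(\d+)LH\Z")


@dataclass(frozen=True)
class VariantLabel:
    """A parsed variant label in ``m.`` nomenclature.

    ``observed`` holds the observed allele symbol: a plain base for homoplasmic
    substitutions, a two-base IUPAC code for point heteroplasmies, the inserted
    bases for insertions, and ``""`` for deletions / length heteroplasmies.
    """

    position: int
    ref_base: str | None
    observed: str
    kind: str = "substitution"
    insert_index: int = 1  # the ".1" in m.309.1C

    def __post_init__(self) -> None:
        check_position(self.position)
        if self.kind not in VARIANT_KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "substitution":
            if self.ref_base not in "ACGT":
                raise LabelParseError(
                    f"substitution needs an A/C/G/T reference, got {self.ref_base!r}"
                )
            if self.observed in IUPAC_PAIRS:
                if self.ref_base not in IUPAC_PAIRS[self.observed]:
                    raise LabelParseError(
                        f"reference {self.ref_base} is not encoded by "
                        f"IUPAC {self.observed}"
                    )
            elif self.observed in "ACGT":
                if self.observed == self.ref_base:
                    raise LabelParseError(
                        f"observed base equals reference at {self.position}"
                    )
            else:
                raise LabelParseError(f"invalid observed symbol {self.observed!r}")

    @property
    def is_heteroplasmic(self) -> bool:
        return self.kind == "substitution" and self.observed in IUPAC_PAIRS

    @property
    def alleles(self) -> frozenset[str]:
        """The set of bases encoded by the observed symbol."""
        if self.is_heteroplasmic:
            return IUPAC_PAIRS[self.observed]
        return frozenset(self.observed) if self.observed else frozenset()

    @property
    def alternate(self) -> str:
        """The non-reference base of a substitution or heteroplasmy."""
        if self.kind != "substitution":
            raise ValueError("alternate base defined for substitutions only")
        if self.is_heteroplasmic:
            (alt,) = IUPAC_PAIRS[self.observed] - {self.ref_base}
            return alt
        return self.observed

    def format(self) -> str:
        """Canonical string form; round-trips through :func:`parse_variant_label`."""
        if self.kind == "substitution":
            return f"m.{self.ref_base}{self.position}{self.observed}"
        if self.kind == "insertion":
            return f"m.{self.position}.{self.insert_index}{self.observed}"
        if self.kind == "deletion":
            return f"m.{self.ref_base}{self.position}d"
        return f"m.{self.position}LH"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


def parse_variant_label(text: str) -> VariantLabel:
    """Parse ``m.``-style variant nomenclature into a :class:`VariantLabel`.

    Supported forms: ``m.G14560R`` (point heteroplasmy), ``m.G15498A``
    (substitution), ``m.309.1C`` (insertion), ``m.A3107d`` (deletion),
    ``m.16189LH`` (length heteroplasmy).
    """
    text = text.strip()
    m = _SUBST_RE.match(text)
    if m:
        ref, pos, obs = m.group(1), int(m.group(2)), m.group(3)
        if not 1 <= pos <= GENOME_LENGTH:
            raise LabelParseError(f"position {pos} out of range in {text!r}")
        return VariantLabel(position=pos, ref_base=ref, observed=obs)
    m = _INS_RE.match(text)
    if m:
        pos, idx, bases = int(m.group(1)), int(m.group(2)), m.group(3)
        return VariantLabel(
            position=pos, ref_base=None, observed=bases,
            kind="insertion", insert_index=idx,
        )
    m = _DEL_RE.match(text)
    if m:
        return VariantLabel(
            position=int(m.group(2)), ref_base=m.group(1), observed="",
            kind="deletion",
        )
    m = _LH_RE.match(text)
    if m:
        return VariantLabel(
            position=int(m.group(1)), ref_base=None, observed="",
            kind="length_heteroplasmy",
        )
    # name the offending token for the error message
    token = text.removeprefix("m.") or text
    raise LabelParseError(f"cannot parse variant label {text!r} (token {token!r})")


# ---------------------------------------------------------------------------
# Coding-effect classification
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

EFFECT_CLASSES = (
    "synonymous", "nonsynonymous", "rRNA", "tRNA", "control", "frameshift",
)


def _codon_at(genome: MitoGenome, region: GeneRegion, position: int) -> tuple[str, int]:
    """The reference codon containing ``position`` and the in-codon offset.

    Codons truncated by the gene's 3' end (incomplete stop codons completed by
    polyadenylation in vivo) are padded with ``A``.
    """
    if region.strand == "+":
        phase = (position - region.start + region.frame) % 3
        bases = []
        for p in (position - phase, position - phase + 1, position - phase + 2):
            bases.append("A" if p > region.end else genome.base(p))
        return "".join(bases), phase
    # light strand: codons read 3'->5' along rCRS coordinates
    phase = (region.end - position + region.frame) % 3
    bases = []
    for p in (position + phase, position + phase - 1, position + phase - 2):
        bases.append("A" if p < region.start else genome.base(p).translate(_COMPLEMENT))
    return "".join(bases), phase


def _translate(codon: str) -> str:
    if codon in MITO_CODON_TABLE.stop_codons:
        return "*"
    return MITO_CODON_TABLE.forward_table[codon.replace("U", "T")]


def classify_coding_effect(
    label: VariantLabel,
    genome: MitoGenome,
    annotation: GeneAnnotation | None = None,
) -> str:
    """Functional class of a variant under the vertebrate mitochondrial code.

    Substitutions in protein genes are translated against the reference codon;
    single-base indels in protein genes are frameshifts; variants in other
    regions return the region class.
    """
    annotation = annotation or GeneAnnotation.default()
    region = annotation.locate(label.position)
    if region.region_class != "protein":
        return region.region_class
    if label.kind in ("insertion", "deletion", "length_heteroplasmy"):
        return "frameshift"
    ref = label.ref_base
    if genome.base(label.position) != ref:
        raise AnnotationError(
            f"label reference {ref} does not match genome base "
            f"{genome.base(label.position)} at {label.position}"
        )
    codon, phase = _codon_at(genome, region, label.position)
    alt = label.alternate
    if region.strand == "-":
        alt = alt.translate(_COMPLEMENT)
    alt_codon = codon[:phase] + alt + codon[phase + 1:]
    return "synonymous" if _translate(codon) == _translate(alt_codon) else "nonsynonymous"


def locate_gene(position: int, annotation: GeneAnnotation | None = None) -> GeneRegion:
    """Convenience wrapper: region containing ``position`` in the default annotation."""
    return (annotation or GeneAnnotation.default()).locate(position)
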