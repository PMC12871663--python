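"""Satellite-locus arrays: annotated repeat units, classification and copy counting.

A pericentromeric satellite locus is modeled as a linear, ordered series of
annotated units over a single contig: the tandem repeat monomers themselves
(organized here as left/right dimer halves of a higher-order repeat),
interspersed transposable-element (TE) islands, and the flanking blocks
(a simple-satellite flank on the proximal side, a TE block on the distal
side).  This module provides the in-memory representation of such an array,
readers for the two annotation dialects practitioners actually have on disk
(BED and RepeatMasker ``.out``), the length/identity/bitscore rules that
sort alignment hits into canonical, variant and truncated repeat classes,
per-class copy counting, and the two copy-number summary statistics used
downstream: percent change between a parent array and a derived allele, and
qPCR relative abundance by the delta-delta-Ct method.

Coordinates are 0-based half-open everywhere inside the package; the
RepeatMasker dialect (1-based inclusive) is converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO


class UnitClass(str, Enum):
    """Functional class of one annotated unit of a satellite locus."""

    REPEAT_LEFT = "repeat-left"
    REPEAT_RIGHT = "repeat-right"
    REPEAT_VARIANT = "repeat-variant"
    REPEAT_TRUNCATED = "repeat-truncated"
    TE_ISLAND = "te-island"
    FLANK_PROXIMAL = "flank-proximal"
    FLANK_DISTAL = "flank-distal"
    OTHER = "other"


#: Classes that count toward the repeat copy total.
REPEAT_CLASSES = (
    UnitClass.REPEAT_LEFT,
    UnitClass.REPEAT_RIGHT,
    UnitClass.REPEAT_VARIANT,
    UnitClass.REPEAT_TRUNCATED,
)


@dataclass(frozen=True)
class UnitAnnotation:
    """One annotated unit (repeat monomer, TE island or flank block).

    ``start``/``end`` are 0-based half-open positions on ``contig``.
    ``identity`` is the fraction of matching bases against the family
    consensus (in [0, 1]) and ``score`` an alignment bitscore; both are
    optional because BED input carries neither.
    """

    contig: str
    start: int
    end: int
    strand: str
    unit_class: UnitClass
    family: str = ""
    identity: float | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"unit {self.contig}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.identity is not None and not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity must lie in [0, 1], got {self.identity}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentHit:
    """One BLAST-style hit of a repeat consensus against the locus sequence.

    ``subject_start``/``subject_end`` are 0-based half-open on the subject;
    ``percent_identity`` is on the conventional 0-100 scale.
    """

    query_label: str
    subject_start: int
    subject_end: int
    percent_identity: float
    alignment_length: int
    bitscore: float
    strand: str = "+"
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must lie in [0, 100]")


@dataclass
class SatelliteArray:
    """Ordered, non-overlapping annotated units over one contig.

    ``sequence`` is optional; when present every unit must fit inside it.
    Units are sorted by start on construction.  Overlapping units are an
    input error: the model is a linear partition-like ordering of the locus,
    and silently merging overlaps would corrupt downstream unit counts.
    """

    contig: str
    units: list[UnitAnnotation] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.units = sorted(self.units, key=lambda u: (u.start, u.end))
        overlaps = [
            (a, b)
            for a, b in zip(self.units, self.units[1:])
            if b.start < a.end
        ]
        if overlaps:
            desc = "; ".join(
                f"{a.family or a.unit_class.value}@{a.start}-{a.end} overlaps "
                f"{b.family or b.unit_class.value}@{b.start}-{b.end}"
                for a, b in overlaps[:5]
            )
            raise ValueError(f"overlapping units on {self.contig}: {desc}")
        wrong_contig = [u for u in self.units if u.contig != self.contig]
        if wrong_contig:
            raise ValueError(
                f"units reference contig(s) other than {self.contig!r}: "
                f"{sorted({u.contig for u in wrong_contig})}"
            )
        if self.sequence is not None and self.units:
            last = self.units[-1]
            if last.end > len(self.sequence):
                raise ValueError(
                    f"unit end {last.end} exceeds sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.units)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SatelliteArray):
            return NotImplemented
        return self.contig == other.contig and self.units == other.units


@dataclass(frozen=True)
class CopySummary:
    """Per-class unit counts plus the repeat copy total.

    ``total_repeats`` sums the four ``repeat-*`` classes only; TE islands,
    flanks and ``other`` units never count as repeat copies.
    """

    counts: Mapping[UnitClass, int]

    @property
    def total_repeats(self) -> int:
        return sum(self.counts.get(c, 0) for c in REPEAT_CLASSES)

    def __getitem__(self, key: UnitClass) -> int:
        return self.counts.get(key, 0)


# ---------------------------------------------------------------------------
# Annotation parsing


def _parse_bed_line(line: str, lineno: int) -> tuple[str, int, int, str, str, float | None]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"line {lineno}: BED requires >= 3 tab-separated fields")
    try:
        contig = fields[0]
        start = int(fields[1])
        end = int(fields[2])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed BED coordinates: {exc}") from exc
    name = fields[3] if len(fields) > 3 else ""
    score: float | None = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed BED score: {exc}") from exc
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
    return contig, start, end, strand, name, score


def _parse_rmout_line(line: str, lineno: int) -> tuple[str, int, int, str, str, float | None]:
    # RepeatMasker .out: whitespace table, 1-based inclusive coordinates,
    # strand 'C' for the reverse complement.
    fields = line.split()
    if len(fields) < 11:
        raise ValueError(
            f"line {lineno}: RepeatMasker .out requires >= 11 whitespace fields"
        )
    try:
        score = float(fields[0])
        contig = fields[4]
        start = int(fields[5]) - 1  # to 0-based half-open
        end = int(fields[6])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed RepeatMasker record: {exc}") from exc
    strand = "-" if fields[8] in ("C", "-") else "+"
    family = fields[9]
    return contig, start, end, strand, family, score


_RM_HEADER_PREFIXES = ("SW", "score", "bit")


def parse_annotation(
    source: str | Path | TextIO | Iterable[str],
    dialect: str = "bed",
    class_map: Mapping[str, UnitClass | str] | None = None,
    sequence: str | None = None,
) -> SatelliteArray:
    """Parse repeat annotations into a :class:`SatelliteArray`.

    Parameters
    ----------
    source
        Path, open text handle, or iterable of lines.
    dialect
        ``"bed"`` (0-based half-open, tab-separated) or ``"repeatmasker-out"``
        (whitespace table, 1-based inclusive; converted on read).
    class_map
        Maps family labels (BED name column / RepeatMasker repeat name) to
        unit classes.  Labels absent from the map fall back to
        :attr:`UnitClass.OTHER`.
    sequence
        Optional contig sequence, attached to the returned array.

    All records must reference a single contig.  Units are sorted by start;
    overlapping units raise ``ValueError`` listing the offending pairs.
    """
    if dialect not in ("bed", "repeatmasker-out"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    parse_line = _parse_bed_line if dialect == "bed" else _parse_rmout_line

    if isinstance(source, (str, Path)):
        with open(source) as handle:
            lines = handle.readlines()
    else:
        lines = list(source)

    cmap: dict[str, UnitClass] = {}
    if class_map:
        cmap = {k: UnitClass(v) for k, v in class_map.items()}

    units: list[UnitAnnotation] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if dialect == "repeatmasker-out" and line.split()[0] in _RM_HEADER_PREFIXES:
            continue
        contig, start, end, strand, family, score = parse_line(raw, lineno)
        unit_class = cmap.get(family, UnitClass.OTHER)
        try:
            units.append(
                UnitAnnotation(
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    unit_class=unit_class,
                    family=family,
                    score=score,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc

    if not units:
        raise ValueError("no annotation records found")
    contigs = sorted({u.contig for u in units})
    if len(contigs) > 1:
        raise ValueError(f"records reference multiple contigs: {contigs}")
    return SatelliteArray(contig=contigs[0], units=units, sequence=sequence)


def write_bed(array: SatelliteArray, destination: str | Path | TextIO) -> None:
    """Write the array's units as 6-column BED (family label in the name field)."""

    def _emit(handle: TextIO) -> None:
        for u in array.units:
            score = "0" if u.score is None else f"{u.score:g}"
            handle.write(
                f"{u.contig}\t{u.start}\t{u.end}\t{u.family or u.unit_class.value}"
                f"\t{score}\t{u.strand}\n"
            )

    if isinstance(destination, (str, Path)):
        with open(destination, "w") as handle:
            _emit(handle)
    else:
        _emit(destination)


# ---------------------------------------------------------------------------
# Repeat-unit classification


def perfect_bitscore(consensus_length: int, lambda_: float = 1.28, k: float = 0.460) -> float:
    """Bitscore of an ungapped perfect self-alignment of a consensus.

    Karlin-Altschul bitscore for a full-length exact match under the default
    blastn scoring (match reward +1): ``(lambda * L - ln K) / ln 2``.  Used
    as the denominator when turning a hit's raw bitscore into a bitscore
    ratio; pass an empirically determined self-alignment bitscore instead
    whenever one is available.
    """
    if consensus_length <= 0:
        raise ValueError("consensus_length must be positive")
    return (lambda_ * consensus_length - math.log(k)) / math.log(2.0)


def classify_units(
    hits: Sequence[AlignmentHit],
    consensus_length: int,
    length_min: int = 90,
    identity_min: float = 90.0,
    bitscore_ratio_min: float = 0.7,
    self_bitscore: float | None = None,
    left_label: str = "L-Rsp",
    right_label: str = "R-Rsp",
) -> list[UnitAnnotation]:
    """Classify consensus-vs-locus alignment hits into repeat unit classes.

    The rules, applied in order of precedence to each hit:

    1. ``alignment_length < length_min``  ->  ``repeat-truncated``
       (truncation is a structural property: a short perfect match is still
       truncated, never "variant").
    2. ``percent_identity < identity_min`` or
       ``bitscore / self_bitscore < bitscore_ratio_min``  ->  ``repeat-variant``.
    3. otherwise ``repeat-left`` or ``repeat-right`` according to whether the
       query label matches ``left_label`` or ``right_label`` (any other
       query label maps to ``repeat-variant``).

    ``self_bitscore`` defaults to the analytic :func:`perfect_bitscore` of
    the consensus.  Hits longer than twice the consensus are accepted and
    classified by the same rules (they typically indicate tandem
    duplications the aligner merged); they are not discarded.
    """
    if consensus_length <= 0:
        raise ValueError("consensus_length must be positive")
    denom = self_bitscore if self_bitscore is not None else perfect_bitscore(consensus_length)
    if denom <= 0:
        raise ValueError("self_bitscore must be positive")

    out: list[UnitAnnotation] = []
    for hit in hits:
        if hit.alignment_length < length_min:
            unit_class = UnitClass.REPEAT_TRUNCATED
        elif (
            hit.percent_identity < identity_min
            or hit.bitscore / denom < bitscore_ratio_min
        ):
            unit_class = UnitClass.REPEAT_VARIANT
        elif hit.query_label == left_label:
            unit_class = UnitClass.REPEAT_LEFT
        elif hit.query_label == right_label:
            unit_class = UnitClass.REPEAT_RIGHT
        else:
            unit_class = UnitClass.REPEAT_VARIANT
        out.append(
            UnitAnnotation(
                contig=hit.subject_id or "locus",
                start=hit.subject_start,
                end=hit.subject_end,
                strand=hit.strand,
                unit_class=unit_class,
                family=hit.query_label,
                identity=hit.percent_identity / 100.0,
                score=hit.bitscore,
            )
        )
    return out


def count_copies(array: SatelliteArray) -> CopySummary:
    """Count units per class; the repeat total excludes TE islands and flanks."""
    counts: dict[UnitClass, int] = {c: 0 for c in UnitClass}
    for unit in array.units:
        counts[unit.unit_class] += 1
    return CopySummary(counts=counts)


def copy_summary_frame(summaries: Mapping[str, CopySummary]):
    """Tabulate named copy summaries as a pandas DataFrame (one row per array)."""
    import pandas as pd

    rows = {}
    for name, s in summaries.items():
        row = {c.value: s[c] for c in UnitClass}
        row["total-repeats"] = s.total_repeats
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Copy-number statistics


def percent_change(parent_total: int, subline_total: int) -> float:
    """Signed percent copy-number change of a derived allele vs its parent.

    ``100 * (subline - parent) / parent``; negative values are deletions,
    positive values expansions.
    """
    if parent_total <= 0:
        raise ValueError("parent_total must be positive")
    return 100.0 * (subline_total - parent_total) / parent_total


def relative_abundance(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
    efficiency: float = 2.0,
) -> float:
    """qPCR relative abundance of a target vs a single-copy reference.

    Delta-delta-Ct with an assumed per-cycle amplification ``efficiency``
    (default 2.0, i.e. perfect doubling):

        efficiency ** -((Ct_t,s - Ct_r,s) - (Ct_t,c - Ct_r,c))

    where the "sample" is the assayed line and the "control" the parent
    strain the fold-change is expressed against.
    """
    for ct in (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control):
        if not math.isfinite(ct):
            raise ValueError("all Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return efficiency ** (-ddct)
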