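"""Simulate post-CRISPR structures of a tandem array under multi-cut repair.

When a guide RNA targets dozens to hundreds of sites inside a satellite
array, simultaneous double-strand breaks followed by end-joining can delete
the whole segment between any pair of cuts.  This module models that
process at the unit level: each target site is cleaved independently with a
per-site probability; if at least two cuts occur, an end-joining rule
decides which inter-cut segments are lost before religation.  Because cuts
fall only where target sites sit, the achievable deletion sizes are set by
the spatial clustering of sites — which is why editing yields a small
number of discrete allele classes rather than a continuum, and why arrays
whose sites form two distant clusters can lose the entire span between
them.  An optional recombination pathway splices in the homologous allele's
inter-cut segment instead of deleting, producing expansions when the
homolog carries more repeats.

Repair rules (the true repair-pair choice is unknown; these are explicit
alternative hypotheses):

``adjacent-join``
    each segment between consecutive cuts is independently lost with
    probability 1/2, then the remaining ends are religated (default; with
    clustered sites this produces the observed discrete deletion classes).
``outermost-join``
    everything between the first and last cut is lost.
``random-pair-join``
    one cut pair is chosen uniformly among all pairs and the segment
    between is lost.

There is no sequence-level junction modeling: religation is perfect, so a
cleaved-then-religated site is restored intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .guide_target import GuideSpec, TargetSite
from .satarray import (
    REPEAT_CLASSES,
    SatelliteArray,
    UnitAnnotation,
    UnitClass,
    count_copies,
)

REPAIR_RULES = ("adjacent-join", "outermost-join", "random-pair-join")


@dataclass
class EditModel:
    """Parameters of the cleavage-and-repair process.

    ``cleavage_prob`` may be a scalar applied to every site or one value
    per site.  ``expansion_prob`` is the probability that a repair event
    resolves by recombination with ``homolog`` (spliced in between the
    chosen cut pair) instead of deletion.  ``lethality_midpoint``, when set,
    discards outcomes with probability ``1/(1+exp(-(cuts-midpoint)/scale))``
    — a logistic in the number of cuts, modeling the failure to recover
    progeny when cleavage load overwhelms repair; off by default.
    """

    cleavage_prob: float | Sequence[float] = 0.5
    repair_rule: str = "adjacent-join"
    expansion_prob: float = 0.0
    seed: int = 0
    homolog: SatelliteArray | None = None
    homolog_sites: Sequence[TargetSite] = field(default_factory=tuple)
    lethality_midpoint: float | None = None
    lethality_scale: float = 5.0

    def __post_init__(self) -> None:
        if self.repair_rule not in REPAIR_RULES:
            raise ValueError(
                f"repair_rule must be one of {REPAIR_RULES}, got {self.repair_rule!r}"
            )
        probs = np.atleast_1d(np.asarray(self.cleavage_prob, dtype=float))
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("cleavage probabilities must lie in [0, 1]")
        if not 0.0 <= self.expansion_prob <= 1.0:
            raise ValueError("expansion_prob must lie in [0, 1]")
        if self.expansion_prob > 0 and self.homolog is None:
            raise ValueError("expansion requires a homolog array")


@dataclass
class EditOutcome:
    """One simulated post-repair allele."""

    array: SatelliteArray
    copy_total: int
    surviving_sites: int
    cuts_made: int
    event_class: str  # {no-edit, deletion, expansion}
    viable: bool = True


def _site_spans(sites: Sequence[TargetSite], guide: GuideSpec | None) -> list[tuple[int, int]]:
    if guide is not None:
        return [s.full_span(guide) for s in sites]
    return [(s.position, s.position + 20) for s in sites]


def _splice_units(
    units: Sequence[UnitAnnotation],
    deletions: Sequence[tuple[int, int]],
    min_repeat_length: int = 90,
) -> list[UnitAnnotation]:
    """Remove ``deletions`` (sorted, disjoint, half-open) and close the gaps.

    Units fully inside a deleted interval vanish; units spanning a cut are
    clipped, and clipped repeat units shorter than ``min_repeat_length``
    are reclassified as truncated.
    """
    out: list[UnitAnnotation] = []
    for unit in units:
        pieces = _subtract(unit.start, unit.end, deletions)
        for s, e in pieces:
            shift = sum(dr - dl for dl, dr in deletions if dr <= s)
            cls = unit.unit_class
            if cls in REPEAT_CLASSES and (e - s) < min_repeat_length and (e - s) < unit.length:
                cls = UnitClass.REPEAT_TRUNCATED
            out.append(
                UnitAnnotation(
                    contig=unit.contig,
                    start=s - shift,
                    end=e - shift,
                    strand=unit.strand,
                    unit_class=cls,
                    family=unit.family,
                    identity=unit.identity,
                    score=unit.score,
                )
            )
    return out


def _subtract(start: int, end: int, deletions: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Subtract sorted disjoint intervals from [start, end)."""
    pieces: list[tuple[int, int]] = []
    cursor = start
    for dl, dr in deletions:
        if dr <= cursor or dl >= end:
            continue
        if dl > cursor:
            pieces.append((cursor, min(dl, end)))
        cursor = max(cursor, dr)
        if cursor >= end:
            break
    if cursor < end:
        pieces.append((cursor, end))
    return [(s, e) for s, e in pieces if e > s]


def _splice_sequence(sequence: str | None, deletions: Sequence[tuple[int, int]]) -> str | None:
    if sequence is None:
        return None
    kept: list[str] = []
    cursor = 0
    for dl, dr in deletions:
        kept.append(sequence[cursor:dl])
        cursor = dr
    kept.append(sequence[cursor:])
    return "".join(kept)


def _deletion_intervals(
    cuts: Sequence[int], rule: str, rng: np.random.Generator
) -> list[tuple[int, int]]:
    cuts = sorted(cuts)
    if rule == "outermost-join":
        return [(cuts[0], cuts[-1])] if cuts[0] < cuts[-1] else []
    if rule == "random-pair-join":
        k = len(cuts)
        i, j = sorted(rng.choice(k, size=2, replace=False).tolist())
        return [(cuts[i], cuts[j])] if cuts[i] < cuts[j] else []
    # adjacent-join: each inter-cut segment lost independently w.p. 1/2,
    # then merged into maximal disjoint intervals.
    intervals: list[tuple[int, int]] = []
    for left, right in zip(cuts, cuts[1:]):
        if left < right and rng.random() < 0.5:
            if intervals and intervals[-1][1] == left:
                intervals[-1] = (intervals[-1][0], right)
            else:
                intervals.append((left, right))
    return intervals


def simulate_editing(
    parent: SatelliteArray,
    sites: Sequence[TargetSite],
    model: EditModel,
    replicates: int = 1,
    guide: GuideSpec | None = None,
) -> list[EditOutcome]:
    """Simulate ``replicates`` independent editing outcomes of ``parent``.

    Per replicate: each site is cleaved independently with its cleavage
    probability; fewer than two cuts is a no-edit outcome; otherwise the
    repair rule determines the lost segment(s), or — with
    ``model.expansion_prob`` — the homolog's segment between its outermost
    cut positions replaces the span between the chosen cut pair.  Copy
    totals are recomputed from the surviving units; target-site survival is
    geometric (a site survives iff its protospacer+PAM footprint is
    untouched, religated cuts being perfect).

    Fully reproducible for a fixed ``model.seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    locus_end = parent.units[-1].end if parent.units else 0
    if parent.sequence is not None:
        locus_end = max(locus_end, len(parent.sequence))
    for s in sites:
        if not 0 <= s.cut_position <= locus_end:
            raise ValueError(
                f"site cut position {s.cut_position} outside array [0, {locus_end}]"
            )

    n = len(sites)
    probs = np.broadcast_to(
        np.atleast_1d(np.asarray(model.cleavage_prob, dtype=float)), (n,)
    ) if n else np.empty(0)
    rng = np.random.default_rng(model.seed)
    parent_total = count_copies(parent).total_repeats
    spans = _site_spans(sites, guide)

    hom_units: list[UnitAnnotation] = []
    hom_len = 0
    hom_site_spans: list[tuple[int, int]] = []
    if model.homolog is not None and model.homolog_sites is not None and len(model.homolog_sites) >= 2:
        hcuts = sorted(s.cut_position for s in model.homolog_sites)
        hl, hr = hcuts[0], hcuts[-1]
        hom_len = hr - hl
        for u in model.homolog.units:
            ps, pe = max(u.start, hl), min(u.end, hr)
            if ps < pe:
                hom_units.append(
                    UnitAnnotation(
                        contig=parent.contig,
                        start=ps - hl,
                        end=pe - hl,
                        strand=u.strand,
                        unit_class=u.unit_class,
                        family=u.family,
                        identity=u.identity,
                        score=u.score,
                    )
                )
        hom_site_spans = [
            sp for sp in _site_spans(model.homolog_sites, guide) if hl <= sp[0] and sp[1] <= hr
        ]

    outcomes: list[EditOutcome] = []
    for _ in range(replicates):
        cleaved = np.nonzero(rng.random(n) < probs)[0] if n else np.empty(0, dtype=int)
        cuts = sorted({sites[i].cut_position for i in cleaved.tolist()})
        if len(cuts) < 2:
            outcome = EditOutcome(
                array=parent,
                copy_total=parent_total,
                surviving_sites=n,
                cuts_made=len(cuts),
                event_class="no-edit",
            )
        else:
            expand = hom_len > 0 and rng.random() < model.expansion_prob
            deletions = _deletion_intervals(cuts, model.repair_rule, rng)
            if expand:
                # single interval between the chosen pair; for adjacent-join
                # recombination resolves at the outermost cuts
                if model.repair_rule == "adjacent-join" or not deletions:
                    deletions = [(cuts[0], cuts[-1])]
                deletions = deletions[:1]
            new_units = _splice_units(parent.units, deletions)
            new_seq = _splice_sequence(parent.sequence, deletions)
            survivors = sum(
                1
                for sp in spans
                if all(sp[1] <= dl or sp[0] >= dr for dl, dr in deletions)
            )
            if expand:
                ins_at = deletions[0][0]
                shift_before = sum(dr - dl for dl, dr in deletions if dr <= ins_at)
                ins_pos = ins_at - shift_before
                shifted = []
                for u in new_units:
                    if u.start >= ins_pos:
                        shifted.append(
                            UnitAnnotation(
                                contig=u.contig, start=u.start + hom_len, end=u.end + hom_len,
                                strand=u.strand, unit_class=u.unit_class, family=u.family,
                                identity=u.identity, score=u.score,
                            )
                        )
                    else:
                        shifted.append(u)
                inserted = [
                    UnitAnnotation(
                        contig=parent.contig, start=u.start + ins_pos, end=u.end + ins_pos,
                        strand=u.strand, unit_class=u.unit_class, family=u.family,
                        identity=u.identity, score=u.score,
                    )
                    for u in hom_units
                ]
                new_units = shifted + inserted
                new_seq = None  # homolog sequence splice not modeled at base level
                survivors += len(hom_site_spans)
                event = "expansion"
            else:
                event = "deletion" if deletions else "no-edit"
            array = SatelliteArray(contig=parent.contig, units=new_units, sequence=new_seq)
            outcome = EditOutcome(
                array=array,
                copy_total=count_copies(array).total_repeats,
                surviving_sites=survivors,
                cuts_made=len(cuts),
                event_class=event,
            )
        if model.lethality_midpoint is not None:
            p_dead = 1.0 / (
                1.0 + np.exp(-(outcome.cuts_made - model.lethality_midpoint) / model.lethality_scale)
            )
            outcome.viable = bool(rng.random() >= p_dead)
        outcomes.append(outcome)
    return outcomes


@dataclass(frozen=True)
class OutcomeHistogram:
    """Binned copy-total distribution over simulated outcomes."""

    bin_width: int
    counts: dict[int, int]  # bin start -> outcome count

    @property
    def n_classes(self) -> int:
        return len(self.counts)

    @property
    def modes(self) -> list[int]:
        peak = max(self.counts.values())
        return sorted(b for b, c in self.counts.items() if c == peak)


def outcome_classes(outcomes: Sequence[EditOutcome], bin_width: int = 1) -> OutcomeHistogram:
    """Histogram outcome copy totals into fixed-width bins.

    With clustered target sites the mass concentrates on a handful of bins
    — the discrete event classes seen in editing screens.
    """
    if not outcomes:
        raise ValueError("outcomes must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    counts: dict[int, int] = {}
    for o in outcomes:
        b = (o.copy_total // bin_width) * bin_width
        counts[b] = counts.get(b, 0) + 1
    return OutcomeHistogram(bin_width=bin_width, counts=dict(sorted(counts.items())))
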