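"""CRISPR guide target-site search, clustering, and survival across alleles.

Finds SpCas9-style target sites — a protospacer match followed immediately
by a PAM — on both strands of a sequence, with a configurable mismatch
tolerance in the protospacer and IUPAC-aware PAM matching.  Cut sites use
standard SpCas9 geometry: a blunt cut 3 bp 5' of the PAM, i.e. between
protospacer positions 17 and 18.  Sites can be clustered along the locus by
single-linkage with a gap threshold (the spatial clustering of target sites
is what determines which segment of a tandem array a multi-cut deletion can
remove), and counted before/after editing to measure target-site survival.

The scan is exact and exhaustive (vectorized over every placement), not a
seed-and-extend heuristic, so it doubles as its own ground truth on any
sequence small enough to check by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# IUPAC nucleotide codes -> set of concrete bases matched.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA query: protospacer, PAM pattern, and mismatch tolerance.

    The protospacer is matched against the genome; sequence ``N`` never
    counts as a match.  The PAM (default ``NGG``) must match exactly under
    IUPAC degeneracy — mismatches are only tolerated in the protospacer.
    """

    name: str
    protospacer: str
    pam: str = "NGG"
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        proto = self.protospacer.upper()
        object.__setattr__(self, "protospacer", proto)
        object.__setattr__(self, "pam", self.pam.upper())
        if not 17 <= len(proto) <= 24:
            raise ValueError(
                f"protospacer length must be 17-24 nt, got {len(proto)}"
            )
        bad = set(proto) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in protospacer: {sorted(bad)}")
        bad = set(self.pam) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in PAM: {sorted(bad)}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    @property
    def site_length(self) -> int:
        return len(self.protospacer) + len(self.pam)


@dataclass(frozen=True, order=True)
class TargetSite:
    """One strand-aware protospacer+PAM match.

    ``position`` is the 0-based start of the protospacer projected onto the
    + strand; ``cut_position`` the 0-based coordinate of the blunt cut (the
    cut falls immediately 5' of that coordinate on the + strand).
    """

    position: int
    strand: str
    mismatches: int
    cut_position: int
    guide: str = field(default="", compare=False)

    def full_span(self, guide: GuideSpec) -> tuple[int, int]:
        """Protospacer+PAM footprint on the + strand, half-open."""
        if self.strand == "+":
            return (self.position, self.position + guide.site_length)
        return (self.position - len(guide.pam), self.position + len(guide.protospacer))


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def _pattern_masks(pattern: str) -> np.ndarray:
    """(len(pattern), 5) boolean table: does pattern position i match base j?

    Column 4 is the sequence base ``N``, which matches nothing.
    """
    masks = np.zeros((len(pattern), 5), dtype=bool)
    for i, code in enumerate(pattern):
        for base in IUPAC[code]:
            masks[i, _BASE_CODE[base]] = True
    return masks


def _scan_strand(encoded: np.ndarray, guide: GuideSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (start positions, mismatch counts) of matches on one strand.

    ``encoded`` is the strand's 5'->3' sequence; positions are starts of the
    protospacer on that strand.
    """
    n = encoded.size
    m = len(guide.protospacer)
    p = len(guide.pam)
    total = m + p
    if n < total:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)

    n_starts = n - total + 1
    proto_masks = _pattern_masks(guide.protospacer)
    pam_masks = _pattern_masks(guide.pam)

    mismatches = np.zeros(n_starts, dtype=np.int64)
    for i in range(m):
        mismatches += ~proto_masks[i][encoded[i : i + n_starts]]
    pam_ok = np.ones(n_starts, dtype=bool)
    for i in range(p):
        pam_ok &= pam_masks[i][encoded[m + i : m + i + n_starts]]

    keep = pam_ok & (mismatches <= guide.max_mismatches)
    return np.nonzero(keep)[0], mismatches[keep]


# Blunt cut between protospacer positions 17 and 18 (3 bp 5' of the PAM).
CUT_OFFSET_FROM_PAM = 3


def find_target_sites(sequence: str, guide: GuideSpec) -> list[TargetSite]:
    """Find all target sites of ``guide`` on both strands of ``sequence``.

    A site is a protospacer placement with at most ``guide.max_mismatches``
    mismatches whose PAM matches immediately 3' of it (IUPAC-aware; an ``N``
    in the sequence never matches).  Sites are returned sorted by position,
    then strand.  Minus-strand coordinates are projected onto the + strand.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence alphabet must be ACGTN, found {sorted(bad)}")

    n = len(seq)
    m = len(guide.protospacer)
    fwd = _encode(seq)
    sites: list[TargetSite] = []

    starts, mms = _scan_strand(fwd, guide)
    cut_in_proto = m - CUT_OFFSET_FROM_PAM
    for pos, mm in zip(starts.tolist(), mms.tolist()):
        sites.append(
            TargetSite(
                position=pos,
                strand="+",
                mismatches=mm,
                cut_position=pos + cut_in_proto,
                guide=guide.name,
            )
        )

    rev = _encode(reverse_complement(seq))
    starts, mms = _scan_strand(rev, guide)
    for rpos, mm in zip(starts.tolist(), mms.tolist()):
        # protospacer occupies [rpos, rpos+m) on the - strand; mirrored to
        # the + strand it occupies [n - rpos - m, n - rpos).
        pos = n - rpos - m
        sites.append(
            TargetSite(
                position=pos,
                strand="-",
                mismatches=mm,
                cut_position=pos + CUT_OFFSET_FROM_PAM,
                guide=guide.name,
            )
        )

    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def site_survival(
    parent_sites: Sequence[TargetSite],
    edited_sequence: str,
    guide: GuideSpec,
) -> tuple[int, int, float | None]:
    """Count how many of a guide's target sites survive in an edited allele.

    Returns ``(remaining, parent, fraction)``; ``fraction`` is ``None`` when
    the parent had no sites.  This is the editing-efficiency readout: a
    handful of surviving sites out of dozens indicates near-complete
    cleavage of the targeted repeat subset.
    """
    parent = len(parent_sites)
    remaining = len(find_target_sites(edited_sequence, guide))
    fraction = remaining / parent if parent > 0 else None
    return remaining, parent, fraction


@dataclass(frozen=True)
class SiteCluster:
    """A maximal run of target sites whose consecutive cuts are within a gap."""

    sites: tuple[TargetSite, ...]
    gap_threshold: int

    @property
    def start(self) -> int:
        return self.sites[0].cut_position

    @property
    def end(self) -> int:
        return self.sites[-1].cut_position

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return len(self.sites)


def cluster_sites(sites: Sequence[TargetSite], gap_threshold: int) -> list[SiteCluster]:
    """Single-linkage clustering of sites by cut position.

    Consecutive sites whose cut positions differ by at most ``gap_threshold``
    join the same cluster; clusters are maximal and returned in positional
    order.
    """
    if gap_threshold <= 0:
        raise ValueError("gap_threshold must be positive")
    if not sites:
        return []
    ordered = sorted(sites, key=lambda s: s.cut_position)
    clusters: list[list[TargetSite]] = [[ordered[0]]]
    for site in ordered[1:]:
        if site.cut_position - clusters[-1][-1].cut_position <= gap_threshold:
            clusters[-1].append(site)
        else:
            clusters.append([site])
    return [SiteCluster(sites=tuple(c), gap_threshold=gap_threshold) for c in clusters]
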