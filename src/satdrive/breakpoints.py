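"""Recombination breakpoint inference from windowed allele-depth ratios.

Given biallelic variant calls of an edited line mapped against its parent
assembly, tracts of the chromosome that recombined with another haplotype
show up as runs of sites where the alternate allele dominates the read
depth, while un-recombined tracts stay reference-like.  The procedure:

1. filter variant records by call quality and by total read depth (keeping
   sites inside the inter-quartile depth band, which removes collapsed
   repeats and low-coverage artifacts);
2. compute the per-site alternate allele-depth ratio
   ``alt / (ref + alt)`` and classify each site as reference (<= 0.1),
   alternate (>= 0.9), heterozygous (0.3-0.7) or uncertain (the gaps);
3. summarize classified sites in fixed non-overlapping windows (50 kb by
   default) along the contig;
4. call a putative breakpoint wherever two sufficiently long runs of
   homogeneous, differing window states abut, and narrow the breakpoint
   interval using the outermost classified sites of the flanking windows.

VCF input is 1-based; everything downstream of parsing is 0-based
half-open, and breakpoint intervals are reported BED-style.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

State = Literal["reference", "heterozygous", "alternate", "uncertain"]

#: AD-ratio thresholds: (reference-max, het-min, het-max, alternate-min).
DEFAULT_THRESHOLDS = (0.1, 0.3, 0.7, 0.9)


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant call (VCF 1-based position convention)."""

    contig: str
    position: int
    qual: float
    ref_depth: int
    alt_depth: int
    total_depth: int
    genotype: str | None = None

    def __post_init__(self) -> None:
        if min(self.ref_depth, self.alt_depth, self.total_depth) < 0:
            raise ValueError("depths must be non-negative")


@dataclass(frozen=True)
class SiteState:
    record: VariantRecord
    ad_ratio: float | None
    state: State


@dataclass(frozen=True)
class WindowSummary:
    """Per-window site-state tallies over one tiling window [start, end)."""

    contig: str
    start: int
    end: int
    n_reference: int
    n_heterozygous: int
    n_alternate: int
    n_uncertain: int

    @property
    def n_classified(self) -> int:
        return self.n_reference + self.n_heterozygous + self.n_alternate

    @property
    def alternate_frequency(self) -> float | None:
        """Fraction of classified sites called alternate; None if empty."""
        n = self.n_classified
        return self.n_alternate / n if n else None

    @property
    def is_empty(self) -> bool:
        return self.n_classified == 0


@dataclass(frozen=True)
class Breakpoint:
    """A state transition bracketed by an interval (0-based half-open)."""

    contig: str
    start: int
    end: int
    left_state: str
    right_state: str

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


# ---------------------------------------------------------------------------
# Filtering and per-site classification


def filter_variants(
    records: Sequence[VariantRecord],
    qual_min: float = 30.0,
    depth_quantile_range: tuple[float, float] = (0.25, 0.75),
) -> list[VariantRecord]:
    """Keep records with qual strictly above ``qual_min`` and total depth
    inside the inclusive quantile band of the input set's depths.

    Quantiles use linear interpolation (numpy default, type 7).  Note the
    depth band is data-dependent: refiltering an already-filtered set
    recomputes quantiles on the survivors, so the operation is only
    idempotent if the quantile band is frozen by the caller.
    """
    if not records:
        warnings.warn("filter_variants: empty input", stacklevel=2)
        return []
    lo_q, hi_q = depth_quantile_range
    depths = np.array([r.total_depth for r in records], dtype=float)
    lo, hi = np.quantile(depths, [lo_q, hi_q])
    return [r for r in records if r.qual > qual_min and lo <= r.total_depth <= hi]


def ad_ratio(record: VariantRecord) -> float | None:
    """Alternate allele-depth ratio ``alt / (ref + alt)``; None if ref+alt=0."""
    denom = record.ref_depth + record.alt_depth
    if denom == 0:
        return None
    return record.alt_depth / denom


def classify_state(
    ratio: float | None,
    thresholds: tuple[float, float, float, float] = DEFAULT_THRESHOLDS,
) -> State:
    """Classify an AD ratio into reference / heterozygous / alternate.

    ``>= 0.9`` alternate, ``<= 0.1`` reference, ``[0.3, 0.7]`` heterozygous;
    the open gaps (0.1, 0.3) and (0.7, 0.9), and undefined ratios, are
    uncertain.
    """
    if ratio is None:
        return "uncertain"
    ref_max, het_min, het_max, alt_min = thresholds
    if ratio >= alt_min:
        return "alternate"
    if ratio <= ref_max:
        return "reference"
    if het_min <= ratio <= het_max:
        return "heterozygous"
    return "uncertain"


def site_states(
    records: Sequence[VariantRecord],
    thresholds: tuple[float, float, float, float] = DEFAULT_THRESHOLDS,
) -> list[SiteState]:
    out = []
    for r in records:
        ratio = ad_ratio(r)
        out.append(SiteState(record=r, ad_ratio=ratio, state=classify_state(ratio, thresholds)))
    return out


# ---------------------------------------------------------------------------
# Windowing


def window_states(
    states: Sequence[SiteState],
    window_size: int = 50_000,
    contig_length: int | None = None,
) -> list[WindowSummary]:
    """Tally site states in non-overlapping tiling windows [0,w), [w,2w), ...

    ``contig_length`` defaults to the last site's position; windows with no
    classified site are kept (flagged empty) so the tiling is gapless.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if not states:
        return []
    contig = states[0].record.contig
    last_pos = max(s.record.position for s in states)
    length = contig_length if contig_length is not None else last_pos
    n_windows = max(1, -(-length // window_size))

    tallies = np.zeros((n_windows, 4), dtype=int)  # ref, het, alt, unc
    col = {"reference": 0, "heterozygous": 1, "alternate": 2, "uncertain": 3}
    for s in states:
        w = min((s.record.position - 1) // window_size, n_windows - 1)  # 1-based pos
        tallies[w, col[s.state]] += 1

    return [
        WindowSummary(
            contig=contig,
            start=i * window_size,
            end=min((i + 1) * window_size, length) if contig_length else (i + 1) * window_size,
            n_reference=int(t[0]),
            n_heterozygous=int(t[1]),
            n_alternate=int(t[2]),
            n_uncertain=int(t[3]),
        )
        for i, t in enumerate(tallies)
    ]


def _window_label(
    w: WindowSummary, high: float, low: float, purity: float
) -> str:
    """Label a window by its dominant site state.

    A window is alternate-like when the alternate frequency among classified
    sites is >= ``high``, reference-like when <= ``low`` and reference sites
    dominate, heterozygous-like when heterozygous sites dominate (fraction
    >= ``purity``); anything else — including empty windows — is ambiguous.
    Heterozygous windows cannot be told from reference windows by alternate
    frequency alone (both are near zero), hence the dominant-state rule.
    """
    n = w.n_classified
    if n == 0:
        return "ambiguous"
    freq = w.n_alternate / n
    if freq >= high:
        return "alternate"
    if freq <= low and w.n_reference / n >= purity:
        return "reference"
    if w.n_heterozygous / n >= purity:
        return "heterozygous"
    return "ambiguous"


def call_breakpoints(
    windows: Sequence[WindowSummary],
    high: float = 0.9,
    low: float = 0.1,
    min_run: int = 2,
    purity: float = 0.9,
    states: Sequence[SiteState] | None = None,
) -> list[Breakpoint]:
    """Call putative recombination breakpoints between homogeneous window runs.

    Windows are labeled alternate- / reference- / heterozygous-like or
    ambiguous; maximal runs of at least ``min_run`` identically labeled
    windows are found (ambiguous windows and shorter runs act as gaps); a
    breakpoint is emitted between every pair of consecutive runs whose
    states differ.  The interval spans from the start of the left run's
    last window to the end of the right run's first window, narrowed to the
    gap between the outermost classified sites of those windows when
    ``states`` is supplied.
    """
    if len(windows) < 2 * min_run:
        warnings.warn("call_breakpoints: fewer than 2*min_run windows, no calls", stacklevel=2)
        return []

    labels = [_window_label(w, high, low, purity) for w in windows]

    runs: list[tuple[int, int, str]] = []  # (first idx, last idx, state)
    i = 0
    while i < len(labels):
        if labels[i] == "ambiguous":
            i += 1
            continue
        j = i
        while j + 1 < len(labels) and labels[j + 1] == labels[i]:
            j += 1
        if j - i + 1 >= min_run:
            runs.append((i, j, labels[i]))
        i = j + 1

    calls: list[Breakpoint] = []
    for (  _, left_last, left_state), (right_first, _, right_state) in zip(runs, runs[1:]):
        if left_state == right_state:
            continue
        lw, rw = windows[left_last], windows[right_first]
        start, end = lw.start, rw.end
        if states:
            # refine at site resolution: over the classified sites of the two
            # runs' facing windows and any gap between them, place the switch
            # point where (left-state sites before) + (right-state sites
            # after) is maximal; ties spread the interval
            positions = []
            labels = []
            for s in sorted(states, key=lambda s: s.record.position):
                if s.state not in (left_state, right_state):
                    continue
                if lw.start < s.record.position <= rw.end:
                    positions.append(s.record.position)
                    labels.append(s.state)
            n_sites = len(positions)
            if n_sites:
                left_prefix = np.cumsum([lab == left_state for lab in labels])
                right_prefix = np.cumsum([lab == right_state for lab in labels])
                total_right = int(right_prefix[-1])
                # score of cutting before site k, k = 0..n_sites
                scores = np.empty(n_sites + 1, dtype=int)
                scores[0] = total_right
                scores[1:] = left_prefix + (total_right - right_prefix)
                best = int(scores.max())
                ks = np.nonzero(scores == best)[0]
                k_lo, k_hi = int(ks[0]), int(ks[-1])
                start = positions[k_lo - 1] if k_lo > 0 else lw.start
                end = positions[k_hi] - 1 if k_hi < n_sites else rw.end
                if end <= start:
                    end = start + 1
        calls.append(
            Breakpoint(
                contig=lw.contig,
                start=start,
                end=end,
                left_state=left_state,
                right_state=right_state,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# I/O


def read_vcf(path: str | Path, contig: str | None = None) -> list[VariantRecord]:
    """Read a single-sample VCF (plain or bgzipped) with GT/AD/DP FORMAT fields.

    Only the first alternate allele's depth is used; additional alternates
    are ignored (their count is reported in a warning).
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    n_multiallelic = 0
    vcf = VCF(str(path))
    try:
        for v in vcf:
            if contig is not None and v.CHROM != contig:
                continue
            if len(v.ALT) > 1:
                n_multiallelic += 1
            ad = v.format("AD")
            if ad is None:
                ref_d, alt_d = 0, 0
            else:
                row = ad[0]
                ref_d = int(row[0]) if row[0] >= 0 else 0
                alt_d = int(row[1]) if len(row) > 1 and row[1] >= 0 else 0
            dp = v.format("DP")
            total = int(dp[0][0]) if dp is not None else ref_d + alt_d
            gt = None
            if v.genotypes:
                g = v.genotypes[0]
                gt = "/".join(str(a) for a in g[:-1])
            records.append(
                VariantRecord(
                    contig=v.CHROM,
                    position=v.POS,
                    qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                    ref_depth=ref_d,
                    alt_depth=alt_d,
                    total_depth=total,
                    genotype=gt,
                )
            )
    finally:
        vcf.close()
    if n_multiallelic:
        warnings.warn(f"{n_multiallelic} multiallelic record(s): only the first ALT used", stacklevel=2)
    return records


def read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    """Read variants from TSV with columns contig, pos, qual, ref_depth, alt_depth, total_depth."""
    df = pd.read_csv(path, sep="\t")
    return [
        VariantRecord(
            contig=str(r.contig),
            position=int(r.pos),
            qual=float(r.qual),
            ref_depth=int(r.ref_depth),
            alt_depth=int(r.alt_depth),
            total_depth=int(r.total_depth),
        )
        for r in df.itertuples(index=False)
    ]


def states_frame(states: Sequence[SiteState]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [s.record.contig for s in states],
            "pos": [s.record.position for s in states],
            "ad_ratio": [s.ad_ratio for s in states],
            "state": [s.state for s in states],
        }
    )


def windows_frame(windows: Sequence[WindowSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [w.contig for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_reference": [w.n_reference for w in windows],
            "n_heterozygous": [w.n_heterozygous for w in windows],
            "n_alternate": [w.n_alternate for w in windows],
            "n_uncertain": [w.n_uncertain for w in windows],
            "alternate_frequency": [w.alternate_frequency for w in windows],
        }
    )


def breakpoints_bed(calls: Sequence[Breakpoint]) -> str:
    """Render breakpoint calls as BED text (name = left>right states)."""
    lines = [
        f"{b.contig}\t{b.start}\t{b.end}\t{b.left_state}>{b.right_state}"
        for b in calls
    ]
    return "\n".join(lines) + ("\n" if lines else "")
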