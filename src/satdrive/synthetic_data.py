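"""Seeded generators of satellite-locus fixtures with known ground truth.

No public assembly of the modeled locus is available, so every other
module in this package is exercised on synthetic data built here: a
higher-order-repeat satellite array (tandem left/right ~120-bp repeat
dimers with variant and truncated units, interspersed TE islands, a simple
AAGAG-like proximal flank and a TE-block distal flank), single-sample
variant tables with recombinant homozygous/heterozygous tracts and
read-depth noise, and offspring-count tables from drive test crosses
binomially sampled under a chosen true drive strength and viability.

Every generator is a pure function of its spec plus a seed (one
``numpy.random.default_rng`` stream per call, no global state), and each
returns the truth objects needed to verify downstream inference: the
array's true per-class copy summary and planted guide-site positions, the
variant table's true tract breakpoints, the crosses' true k and viability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .breakpoints import VariantRecord
from .satarray import SatelliteArray, UnitAnnotation, UnitClass, count_copies, CopySummary

BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitute each base independently with probability ``rate``.

    Substitutions always change the base, so the returned mutation count is
    exactly the Hamming distance to the input.
    """
    if rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr), int(hit.sum())


def unit_identity(seq: str, consensus: str) -> float:
    """Alignment-free identity of an emitted unit vs its consensus.

    Position-wise match fraction over the unit's length (units are emitted
    colinear with the consensus, so a gap-free comparison is exact here).
    """
    n = min(len(seq), len(consensus))
    if n == 0:
        return 0.0
    matches = sum(a == b for a, b in zip(seq[:n], consensus[:n]))
    return matches / len(seq)


# ---------------------------------------------------------------------------
# Satellite arrays


@dataclass
class ArraySpec:
    """Recipe for a synthetic higher-order-repeat satellite array.

    Defaults emulate the modeled locus at reduced scale: ~120-bp left/right
    repeat dimers, occasional variant (mutated) and truncated units, two TE
    islands, an AAGAG simple-satellite proximal flank and a TE-like distal
    block.  ``te_islands`` maps dimer index -> island length (the island is
    inserted before that dimer).  ``plant_guide`` optionally embeds a
    protospacer+PAM at a fixed offset inside the left unit of the listed
    dimers, so guide-search results can be checked against planted truth.
    """

    n_dimers: int = 50
    unit_length: int = 120
    left_consensus: str | None = None
    right_consensus: str | None = None
    mutation_rate: float = 0.02
    variant_fraction: float = 0.1      # dimers mutated at variant_rate instead
    variant_rate: float = 0.15
    truncation_prob: float = 0.03
    truncation_min: int = 20
    truncation_max: int = 89
    te_islands: dict[int, int] = field(default_factory=lambda: {15: 2000, 35: 1500})
    proximal_motif: str = "AAGAG"
    proximal_length: int = 500
    distal_length: int = 1000
    plant_guide: str | None = None      # protospacer+PAM, e.g. 23 nt
    plant_in_dimers: Sequence[int] = ()
    plant_offset: int = 10
    seed: int = 0

    # classification thresholds used for truth labels (match classify_units)
    length_min: int = 90
    identity_min: float = 0.90


@dataclass
class ArrayTruth:
    """Ground truth accompanying a generated array."""

    summary: CopySummary
    planted_sites: list[int]          # 0-based protospacer starts, + strand
    unit_mutations: list[int]         # per emitted repeat unit


def gen_array(spec: ArraySpec) -> tuple[SatelliteArray, ArrayTruth]:
    """Generate a satellite array with sequence, annotations and truth.

    Deterministic for a fixed ``spec.seed``.  Truth unit classes are
    assigned by the same length/identity rules the classifier applies:
    emitted length < ``length_min`` -> truncated; identity vs consensus
    below ``identity_min`` -> variant; otherwise left/right.
    """
    rng = np.random.default_rng(spec.seed)
    left = spec.left_consensus or _random_seq(rng, spec.unit_length)
    right = spec.right_consensus or _random_seq(rng, spec.unit_length)
    if spec.left_consensus and len(spec.left_consensus) != spec.unit_length:
        raise ValueError("left consensus length must equal unit_length")
    if spec.right_consensus and len(spec.right_consensus) != spec.unit_length:
        raise ValueError("right consensus length must equal unit_length")

    chunks: list[str] = []
    units: list[UnitAnnotation] = []
    planted: list[int] = []
    unit_mutations: list[int] = []
    pos = 0
    contig = "synthetic_locus"

    def emit(seq_chunk: str, unit_class: UnitClass, family: str, identity: float | None = None) -> None:
        nonlocal pos
        chunks.append(seq_chunk)
        units.append(
            UnitAnnotation(
                contig=contig,
                start=pos,
                end=pos + len(seq_chunk),
                strand="+",
                unit_class=unit_class,
                family=family,
                identity=identity,
            )
        )
        pos += len(seq_chunk)

    # proximal simple-satellite flank
    if spec.proximal_length > 0:
        reps = -(-spec.proximal_length // len(spec.proximal_motif))
        emit((spec.proximal_motif * reps)[: spec.proximal_length],
             UnitClass.FLANK_PROXIMAL, spec.proximal_motif)

    plant_set = set(spec.plant_in_dimers)
    for d in range(spec.n_dimers):
        if d in spec.te_islands:
            emit(_random_seq(rng, spec.te_islands[d]), UnitClass.TE_ISLAND, "TE")
        for consensus, label, base_class in (
            (left, "L-Rsp", UnitClass.REPEAT_LEFT),
            (right, "R-Rsp", UnitClass.REPEAT_RIGHT),
        ):
            rate = (
                spec.variant_rate
                if rng.random() < spec.variant_fraction
                else spec.mutation_rate
            )
            seq, n_mut = _mutate(rng, consensus, rate)
            if rng.random() < spec.truncation_prob:
                keep = int(rng.integers(spec.truncation_min, spec.truncation_max + 1))
                seq = seq[:keep]
            if (
                spec.plant_guide
                and d in plant_set
                and base_class is UnitClass.REPEAT_LEFT
                and len(seq) >= spec.plant_offset + len(spec.plant_guide)
            ):
                g = spec.plant_guide.upper()
                seq = seq[: spec.plant_offset] + g + seq[spec.plant_offset + len(g):]
                planted.append(pos + spec.plant_offset)
            identity = unit_identity(seq, consensus)
            if len(seq) < spec.length_min:
                cls = UnitClass.REPEAT_TRUNCATED
            elif identity < spec.identity_min:
                cls = UnitClass.REPEAT_VARIANT
            else:
                cls = base_class
            unit_mutations.append(n_mut)
            emit(seq, cls, label, identity=identity)

    if spec.distal_length > 0:
        emit(_random_seq(rng, spec.distal_length), UnitClass.FLANK_DISTAL, "TE-block")

    array = SatelliteArray(contig=contig, units=units, sequence="".join(chunks))
    truth = ArrayTruth(
        summary=count_copies(array),
        planted_sites=planted,
        unit_mutations=unit_mutations,
    )
    return array, truth


# ---------------------------------------------------------------------------
# Variant tables with recombinant tracts


@dataclass
class TractSpec:
    """Recipe for a single-sample variant table over genotype-state tracts.

    ``tracts`` lists (end-position, state) with increasing ends, the last
    equal to ``contig_length`` — e.g. a reference tract then an alternate
    tract models one recombination breakpoint at the shared boundary.
    Depths follow a negative binomial (mean ``depth_mean``, dispersion
    ``depth_dispersion``; larger dispersion = tighter) so that the
    inter-quartile depth filter removes a realistic tail, and per-site
    states are mislabeled with probability ``noise`` to model mapping and
    calling errors.
    """

    contig_length: int = 2_000_000
    tracts: Sequence[tuple[int, str]] = (
        (900_000, "reference"),
        (2_000_000, "alternate"),
    )
    sites_per_kb: float = 2.0
    depth_mean: float = 40.0
    depth_dispersion: float = 10.0
    error_fraction: float = 0.02       # alt reads at a homozygous-ref site
    noise: float = 0.0                 # per-site state misassignment
    qual_mean: float = 45.0
    qual_sd: float = 6.0
    contig: str = "chr2_contig"
    seed: int = 0

    def __post_init__(self) -> None:
        ends = [e for e, _ in self.tracts]
        if ends != sorted(ends) or ends[-1] != self.contig_length:
            raise ValueError("tract ends must increase and finish at contig_length")
        for _, s in self.tracts:
            if s not in ("reference", "heterozygous", "alternate"):
                raise ValueError(f"unknown tract state {s!r}")


def gen_variant_table(spec: TractSpec) -> tuple[list[VariantRecord], list[int]]:
    """Generate variant records along tracts; returns (records, truth breakpoints).

    Site positions are a homogeneous Poisson process at ``sites_per_kb``;
    per-site alt depths are binomial with success probability set by the
    (possibly noise-flipped) tract state.  Truth breakpoints are the
    internal tract boundaries.
    """
    if spec.sites_per_kb <= 0:
        raise ValueError("sites_per_kb must be positive")
    rng = np.random.default_rng(spec.seed)
    n_sites = rng.poisson(spec.sites_per_kb * spec.contig_length / 1000.0)
    positions = np.sort(rng.integers(1, spec.contig_length + 1, size=n_sites))

    # negative binomial parameterized by mean and dispersion r:
    # p = r / (r + mean); variance = mean + mean^2 / r
    r = spec.depth_dispersion
    p_nb = r / (r + spec.depth_mean)
    depths = rng.negative_binomial(r, p_nb, size=n_sites) + 1

    tract_ends = np.array([e for e, _ in spec.tracts])
    tract_states = [s for _, s in spec.tracts]
    state_p = {
        "reference": spec.error_fraction,
        "heterozygous": 0.5,
        "alternate": 1.0 - spec.error_fraction,
    }
    all_states = ("reference", "heterozygous", "alternate")

    records: list[VariantRecord] = []
    for pos_, depth in zip(positions.tolist(), depths.tolist()):
        idx = int(np.searchsorted(tract_ends, pos_, side="left"))
        state = tract_states[min(idx, len(tract_states) - 1)]
        if spec.noise > 0 and rng.random() < spec.noise:
            others = [s for s in all_states if s != state]
            state = others[rng.integers(len(others))]
        alt = int(rng.binomial(depth, state_p[state]))
        qual = float(max(0.0, rng.normal(spec.qual_mean, spec.qual_sd)))
        records.append(
            VariantRecord(
                contig=spec.contig,
                position=int(pos_),
                qual=qual,
                ref_depth=depth - alt,
                alt_depth=alt,
                total_depth=depth,
            )
        )
    truth = [int(e) for e in tract_ends[:-1]]
    return records, truth


def write_vcf(records: Sequence[VariantRecord], path: str | Path, sample: str = "sample1") -> None:
    """Write records as a minimal single-sample VCF (FORMAT GT:AD:DP)."""
    records = sorted(records, key=lambda r: (r.contig, r.position))
    contigs = sorted({r.contig for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=satdrive-synthetic\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for rec in records:
            ratio = rec.alt_depth / max(1, rec.ref_depth + rec.alt_depth)
            gt = "1/1" if ratio >= 0.9 else ("0/0" if ratio <= 0.1 else "0/1")
            fh.write(
                f"{rec.contig}\t{rec.position}\t.\tA\tG\t{rec.qual:.1f}\t.\t.\t"
                f"GT:AD:DP\t{gt}:{rec.ref_depth},{rec.alt_depth}:{rec.total_depth}\n"
            )


def write_variant_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "contig": [r.contig for r in records],
            "pos": [r.position for r in records],
            "qual": [r.qual for r in records],
            "ref_depth": [r.ref_depth for r in records],
            "alt_depth": [r.alt_depth for r in records],
            "total_depth": [r.total_depth for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cross counts


def gen_cross_counts(
    true_k: float,
    viability: float = 1.0,
    n_offspring: int = 200,
    n_crosses: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate drive test crosses under a true drive strength and viability.

    In the male cross, an offspring is observed SD-bearing with probability
    ``k*v / (k*v + (1-k))`` — transmission at rate k thinned by relative
    viability v of SD-bearing offspring.  The reciprocal (female) cross
    transmits Mendelianly, so its SD probability is ``v / (1 + v)``.
    Returns one row per cross with columns line_id, male_sd, male_plus,
    reciprocal_sd, reciprocal_plus.
    """
    if not 0.0 <= true_k <= 1.0:
        raise ValueError("true_k must lie in [0, 1]")
    if viability <= 0:
        raise ValueError("viability must be positive")
    rng = np.random.default_rng(seed)
    p_male = true_k * viability / (true_k * viability + (1.0 - true_k))
    p_recip = viability / (1.0 + viability)
    male_sd = rng.binomial(n_offspring, p_male, size=n_crosses)
    recip_sd = rng.binomial(n_offspring, p_recip, size=n_crosses)
    return pd.DataFrame(
        {
            "line_id": [f"cross{i:04d}" for i in range(n_crosses)],
            "male_sd": male_sd,
            "male_plus": n_offspring - male_sd,
            "reciprocal_sd": recip_sd,
            "reciprocal_plus": n_offspring - recip_sd,
        }
    )


def write_fasta(array: SatelliteArray, path: str | Path) -> None:
    """Write the array sequence as FASTA (one record, 80-column wrap)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if array.sequence is None:
        raise ValueError("array has no sequence")
    rec = SeqRecord(Seq(array.sequence), id=array.contig, description="")
    SeqIO.write([rec], str(path), "fasta")
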