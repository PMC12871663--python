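"""Generators: determinism, truth consistency, round-trips, end-to-end recovery."""

import numpy as np
import pytest

from satdrive import (
    ArraySpec,
    EditModel,
    GuideSpec,
    TractSpec,
    UnitClass,
    classify_state,
    count_copies,
    find_target_sites,
    gen_array,
    gen_cross_counts,
    gen_variant_table,
    parse_annotation,
    simulate_editing,
    site_survival,
    write_bed,
)
from satdrive.breakpoints import read_variant_tsv
from satdrive.synthetic_data import unit_identity, write_fasta, write_variant_tsv, write_vcf

PROTO = "GACGTTACCGATTGCAAGTC"


class TestGenArray:
    def test_perfect_array_copy_count(self):
        spec = ArraySpec(
            n_dimers=30, mutation_rate=0.0, variant_fraction=0.0,
            truncation_prob=0.0, seed=1,
        )
        array, truth = gen_array(spec)
        assert truth.summary.total_repeats == 60
        assert count_copies(array).total_repeats == 60
        assert truth.summary[UnitClass.REPEAT_LEFT] == 30

    def test_seed_determinism(self):
        a1, t1 = gen_array(ArraySpec(seed=9))
        a2, t2 = gen_array(ArraySpec(seed=9))
        assert a1.sequence == a2.sequence
        assert a1.units == a2.units
        assert t1.summary.counts == t2.summary.counts
        a3, _ = gen_array(ArraySpec(seed=10))
        assert a3.sequence != a1.sequence

    def test_truth_labels_match_rule_application(self):
        """Reapplying the length/identity rules to emitted sequences must
        reproduce the generator's own class labels."""
        spec = ArraySpec(n_dimers=80, mutation_rate=0.02, variant_rate=0.15,
                         variant_fraction=0.3, truncation_prob=0.05, seed=23)
        array, _ = gen_array(spec)
        left = right = None
        for u in array.units:
            seq = array.sequence[u.start:u.end]
            if u.family == "L-Rsp" and left is None and u.length == spec.unit_length \
                    and u.identity == 1.0:
                left = seq
            if u.family == "R-Rsp" and right is None and u.length == spec.unit_length \
                    and u.identity == 1.0:
                right = seq
        assert left is not None and right is not None
        for u in array.units:
            if u.family not in ("L-Rsp", "R-Rsp"):
                continue
            consensus = left if u.family == "L-Rsp" else right
            seq = array.sequence[u.start:u.end]
            ident = unit_identity(seq, consensus)
            if len(seq) < spec.length_min:
                expected = UnitClass.REPEAT_TRUNCATED
            elif ident < spec.identity_min:
                expected = UnitClass.REPEAT_VARIANT
            else:
                expected = UnitClass.REPEAT_LEFT if u.family == "L-Rsp" else UnitClass.REPEAT_RIGHT
            assert u.unit_class is expected, (u.start, ident, u.unit_class)

    def test_structure_flanks_and_islands(self):
        array, _ = gen_array(ArraySpec(seed=3))
        classes = [u.unit_class for u in array.units]
        assert classes[0] is UnitClass.FLANK_PROXIMAL
        assert classes[-1] is UnitClass.FLANK_DISTAL
        assert classes.count(UnitClass.TE_ISLAND) == 2
        assert array.sequence[:10] == "AAGAGAAGAG"

    def test_bed_round_trip(self, tmp_path):
        array, _ = gen_array(ArraySpec(seed=4))
        path = tmp_path / "truth.bed"
        write_bed(array, path)
        rebuilt = parse_annotation(path, "bed")
        assert [(u.start, u.end) for u in rebuilt.units] == [
            (u.start, u.end) for u in array.units
        ]

    def test_fasta_round_trip(self, tmp_path):
        from Bio import SeqIO

        array, _ = gen_array(ArraySpec(seed=4))
        path = tmp_path / "locus.fa"
        write_fasta(array, path)
        rec = next(SeqIO.parse(str(path), "fasta"))
        assert str(rec.seq) == array.sequence


class TestPlantedGuides:
    def _spec(self, dimers):
        return ArraySpec(
            n_dimers=40, seed=6, mutation_rate=0.01, truncation_prob=0.0,
            plant_guide=PROTO + "AGG", plant_in_dimers=dimers,
        )

    def test_planted_sites_recovered_exactly(self):
        array, truth = gen_array(self._spec((3, 9, 21, 33)))
        guide = GuideSpec("g1", PROTO)
        sites = find_target_sites(array.sequence, guide)
        assert [s.position for s in sites if s.strand == "+"] == truth.planted_sites
        assert len(sites) == len(truth.planted_sites)

    def test_full_cluster_deletion_removes_sites(self):
        array, truth = gen_array(self._spec(tuple(range(5, 25))))
        guide = GuideSpec("g1", PROTO)
        sites = find_target_sites(array.sequence, guide)
        assert len(sites) == 20
        model = EditModel(cleavage_prob=1.0, repair_rule="outermost-join", seed=2)
        (outcome,) = simulate_editing(array, sites, model, 1, guide=guide)
        remaining, parent, frac = site_survival(sites, outcome.array.sequence, guide)
        assert parent == 20
        # only the outermost pair's flanking half-sites can survive
        assert remaining <= 2
        assert outcome.copy_total < count_copies(array).total_repeats


class TestGenVariantTable:
    def test_no_noise_states_match_tracts(self):
        spec = TractSpec(
            contig_length=400_000,
            tracts=((200_000, "heterozygous"), (400_000, "alternate")),
            noise=0.0, error_fraction=0.0, depth_mean=60.0, seed=2,
        )
        records, truth = gen_variant_table(spec)
        assert truth == [200_000]
        for r in records:
            ratio = r.alt_depth / (r.ref_depth + r.alt_depth)
            want = "heterozygous" if r.position <= 200_000 else "alternate"
            got = classify_state(ratio)
            if got != "uncertain":  # binomial het sampling can stray from 0.3-0.7
                assert got == want
        frac_uncertain = np.mean([
            classify_state(r.alt_depth / r.total_depth) == "uncertain" for r in records
        ])
        assert frac_uncertain < 0.05

    def test_single_tract_no_breakpoints(self):
        spec = TractSpec(contig_length=200_000, tracts=((200_000, "reference"),), seed=3)
        _, truth = gen_variant_table(spec)
        assert truth == []

    def test_determinism(self):
        r1, _ = gen_variant_table(TractSpec(seed=8, contig_length=100_000,
                                            tracts=((100_000, "reference"),)))
        r2, _ = gen_variant_table(TractSpec(seed=8, contig_length=100_000,
                                            tracts=((100_000, "reference"),)))
        assert r1 == r2

    def test_bad_tracts_rejected(self):
        with pytest.raises(ValueError):
            TractSpec(contig_length=100, tracts=((50, "reference"),))
        with pytest.raises(ValueError):
            TractSpec(contig_length=100, tracts=((100, "bogus"),))

    def test_tsv_round_trip(self, tmp_path):
        records, _ = gen_variant_table(
            TractSpec(seed=1, contig_length=50_000, tracts=((50_000, "heterozygous"),))
        )
        path = tmp_path / "variants.tsv"
        write_variant_tsv(records, path)
        rebuilt = read_variant_tsv(path)
        assert [(r.position, r.ref_depth, r.alt_depth) for r in rebuilt] == [
            (r.position, r.ref_depth, r.alt_depth) for r in records
        ]

    def test_vcf_round_trip(self, tmp_path):
        from satdrive.breakpoints import read_vcf

        records, _ = gen_variant_table(
            TractSpec(seed=1, contig_length=50_000, tracts=((50_000, "heterozygous"),))
        )
        path = tmp_path / "variants.vcf"
        write_vcf(records, path)
        rebuilt = read_vcf(path)
        assert [(r.contig, r.position, r.ref_depth, r.alt_depth, r.total_depth) for r in rebuilt] == [
            (r.contig, r.position, r.ref_depth, r.alt_depth, r.total_depth) for r in records
        ]
        assert [round(r.qual, 1) for r in rebuilt] == [round(r.qual, 1) for r in records]


class TestGenCrossCounts:
    def test_mendelian_null_mean(self):
        df = gen_cross_counts(0.5, 1.0, n_offspring=200, n_crosses=400, seed=1)
        frac = df["male_sd"].sum() / (200 * 400)
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_perfect_drive_boundary(self):
        df = gen_cross_counts(1.0, 0.7, n_offspring=100, n_crosses=50, seed=2)
        assert (df["male_sd"] == 100).all()

    def test_determinism(self):
        df1 = gen_cross_counts(0.8, 0.9, n_crosses=10, seed=5)
        df2 = gen_cross_counts(0.8, 0.9, n_crosses=10, seed=5)
        assert df1.equals(df2)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            gen_cross_counts(1.2)
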