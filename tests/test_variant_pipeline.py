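"""Variant pipeline: parsing, normalization, filters, consensus, annotation."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionmut import synthetic_data as sd
from ionmut import variant_pipeline as vp
from ionmut.annotation import REGION_PRECEDENCE, annotate, representative_position
from ionmut.variant_pipeline import (
    MutationRecord,
    VariantCall,
    apply_quality_filter,
    classify_sbs,
    consensus_mutations,
    exclude_background,
    indel_spectrum,
    intersect_callers,
    normalize_variant,
    read_caller_vcf,
    summarize_sample,
    titv_ratio,
    window_density,
)


def _call(chrom="chr1", pos=100, ref="A", alt="T", **kw):
    kw.setdefault("depth", 50)
    kw.setdefault("af", 0.5)
    return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


def _sbs_record(ref, alt, pos=1, chrom="chr1"):
    return MutationRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, mut_class="SBS")


class TestVcfReading:
    def test_multiallelic_records_split_per_alt(self, tmp_path):
        vcf = tmp_path / "s1.gatk.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AF,Number=A,Type=Float,Description="a">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t10\t.\tC\tA,T\t.\tPASS\t.\tGT:DP:AF\t0/1:40:0.3,0.2\n"
            "chr1\t30\t.\tG\tA\t.\tPASS\t.\tGT:DP:AF\t1/1:55:0.98\n"
        )
        calls, log = read_caller_vcf(vcf)
        assert [(c.pos, c.alt) for c in calls] == [(10, "A"), (10, "T"), (30, "A")]
        assert calls[0].af == pytest.approx(0.3) and calls[1].af == pytest.approx(0.2)
        assert calls[2].zygosity == "hom"
        assert log["caller"] == "gatk" and log["parsed"] == 3

    def test_record_without_depth_or_af_is_excluded_and_logged(self, tmp_path):
        vcf = tmp_path / "s1.varscan.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t10\t.\tC\tA\t.\tPASS\t.\tGT\t0/1\n"
        )
        calls, log = read_caller_vcf(vcf)
        assert calls == []
        assert log["excluded_no_dp_af"] == 1

    def test_af_derived_from_ad_when_af_missing(self, tmp_path):
        vcf = tmp_path / "s1.samtools.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t10\t.\tC\tA\t.\tPASS\t.\tGT:DP:AD\t0/1:40:30,10\n"
        )
        calls, _ = read_caller_vcf(vcf)
        assert len(calls) == 1
        assert calls[0].af == pytest.approx(0.25)

    def test_round_trip_of_generated_vcfs(self, toy_genome, cohort_truth, zero_error_profiles, tmp_path):
        genome, _ = toy_genome
        t = cohort_truth[2]
        paths = sd.generate_caller_vcfs(t, zero_error_profiles, genome, tmp_path, seed=12)
        for p in paths:
            calls, _ = read_caller_vcf(p)
            assert {c.key for c in calls} == {v.key for v in t.all_variants}


class TestNormalization:
    GENOME = {"chr1": "GGGG" + "CATTTTTTG" + "ACGTACGT" * 5}  # homopolymer context

    def test_sbs_passes_through(self):
        c = _call(pos=5, ref="C", alt="A")
        assert normalize_variant(c, self.GENOME) == c

    def test_trims_to_minimal_representation(self):
        genome = {"chr1": "G" * 98 + "CATGG" + "G" * 50}
        c = _call(chrom="chr1", pos=100, ref="AT", alt="AACT", depth=1, af=1.0)
        n = normalize_variant(c, genome)
        assert (n.pos, n.ref, n.alt) == (100, "A", "AAC")

    def test_deletion_left_aligned_in_homopolymer(self):
        # delete one T from the T6 run (positions 7-12): the leftmost
        # representation anchors on the A at position 6
        seq = self.GENOME["chr1"]
        pos = 9  # "TT" inside the run
        c = _call(pos=pos, ref=seq[pos - 1 : pos + 1], alt=seq[pos - 1])
        n = normalize_variant(c, self.GENOME)
        assert (n.pos, n.ref, n.alt) == (6, "AT", "A")

    def test_ref_mismatch_raises(self):
        with pytest.raises(vp.NormalizationError):
            normalize_variant(_call(pos=5, ref="T", alt="G"), self.GENOME)

    @pytest.mark.skipif(shutil.which("bcftools") is None, reason="bcftools not on PATH")
    @pytest.mark.parametrize(
        "pos,ref,alt",
        [
            (8, "TT", "T"),       # deletion inside homopolymer
            (9, "T", "TT"),       # insertion inside homopolymer
            (6, "ATT", "ATTT"),   # padded insertion
            (5, "CATT", "CA"),    # padded deletion
        ],
    )
    def test_agrees_with_bcftools_norm(self, tmp_path, pos, ref, alt):
        """Independent oracle: bcftools norm left-aligns to the same key."""
        fa = tmp_path / "ref.fa"
        fa.write_text(">chr1\n" + self.GENOME["chr1"] + "\n")
        subprocess.run(["samtools", "faidx", str(fa)], check=True, capture_output=True)
        vcf = tmp_path / "in.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length={}>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t{}\t.\t{}\t{}\t.\t.\t.\n".format(len(self.GENOME["chr1"]), pos, ref, alt)
        )
        out = subprocess.run(
            ["bcftools", "norm", "-f", str(fa), str(vcf)],
            check=True, capture_output=True, text=True,
        ).stdout
        data = [l.split("\t") for l in out.splitlines() if l and not l.startswith("#")]
        assert len(data) == 1
        mine = normalize_variant(_call(pos=pos, ref=ref, alt=alt), self.GENOME)
        assert (mine.pos, mine.ref, mine.alt) == (int(data[0][1]), data[0][3], data[0][4])

    @given(
        pos=st.integers(2, 40),
        ref_len=st.integers(1, 4),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=4),
    )
    @settings(deadline=None, max_examples=300)
    def test_normalization_is_idempotent(self, pos, ref_len, alt):
        seq = self.GENOME["chr1"]
        ref = seq[pos - 1 : pos - 1 + ref_len]
        if ref == alt:
            return
        c = _call(pos=pos, ref=ref, alt=alt)
        once = normalize_variant(c, self.GENOME)
        twice = normalize_variant(once, self.GENOME)
        assert once == twice


class TestBackgroundExclusion:
    def test_shared_variant_removed_from_all_carriers(self):
        shared = _call(pos=10)
        a_only = _call(pos=20)
        sets = {"A": [shared, a_only], "B": [shared], "C": [_call(pos=30)]}
        filtered, log = exclude_background(sets)
        assert filtered["A"] == [a_only]
        assert filtered["B"] == []
        assert len(filtered["C"]) == 1
        assert log[0]["carriers"] == ["A", "B"]

    def test_exclusion_is_symmetric_across_samples(self):
        shared = _call(pos=10)
        sets = {"A": [shared], "B": [shared], "C": [shared]}
        filtered, _ = exclude_background(sets)
        assert all(v == [] for v in filtered.values())

    def test_planted_background_fully_recovered(self, toy_genome, cohort_truth):
        genome, _ = toy_genome
        sets = {
            t.sample_id: [normalize_variant(v, genome) for v in t.all_variants]
            for t in cohort_truth
        }
        filtered, log = exclude_background(sets)
        assert len(log) == 50
        for t in cohort_truth:
            assert {c.key for c in filtered[t.sample_id]} == {
                normalize_variant(v, genome).key for v in t.mutations
            }

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            exclude_background({"A": []})


class TestQualityFilter:
    @pytest.mark.parametrize(
        "dp,af,kept",
        [
            (10, 0.25, True),   # both boundaries inclusive
            (100, 0.25, True),
            (9, 0.9, False),
            (101, 0.9, False),
            (50, 0.24, False),
            (50, 0.2499, False),
            (55, 0.8, True),
        ],
    )
    def test_boundaries_inclusive(self, dp, af, kept):
        calls = apply_quality_filter([_call(depth=dp, af=af)])
        assert (len(calls) == 1) is kept


class TestIntersection:
    def test_three_way_consensus_rules(self):
        v1, v2, v3 = _call(pos=10), _call(pos=20), _call(pos=30)
        recs = intersect_callers([v1, v2], [v1, v3], [v1, v2, v3])
        assert [r.key for r in recs] == [v1.key]  # v2 in 2 callers, v3 in 2

    def test_consensus_depth_from_first_caller(self):
        a = _call(pos=10, depth=40, af=0.4, caller="gatk")
        b = _call(pos=10, depth=90, af=0.9, caller="samtools")
        rec = intersect_callers([a], [b], [b])[0]
        assert rec.depth == 40 and rec.af == pytest.approx(0.4)

    def test_matches_brute_force_set_intersection(self):
        rng = np.random.default_rng(77)
        pools = []
        for _ in range(3):
            pools.append(
                [_call(pos=int(p)) for p in rng.choice(np.arange(1, 200), size=80, replace=False)]
            )
        recs = intersect_callers(*pools)
        brute = {
            c1.key
            for c1 in pools[0]
            for c2 in pools[1]
            for c3 in pools[2]
            if c1.key == c2.key == c3.key
        }
        assert {r.key for r in recs} == brute


class TestClassification:
    def test_canonical_transition_examples(self):
        assert classify_sbs("C", "T") == ("C:G>T:A", "Ti")
        assert classify_sbs("G", "A") == ("C:G>T:A", "Ti")  # strand collapse
        assert classify_sbs("T", "C") == ("T:A>C:G", "Ti")

    def test_all_twelve_substitutions_partition_into_6_classes(self):
        from collections import Counter

        got = Counter()
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                sub, label = classify_sbs(ref, alt)
                got[(sub, label)] += 1
        assert len(got) == 6
        assert all(n == 2 for n in got.values())  # each class from 2 ordered pairs
        assert sum(n for (s, l), n in got.items() if l == "Ti") == 4
        assert sum(n for (s, l), n in got.items() if l == "Tv") == 8

    def test_strand_symmetry(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref != alt:
                    assert classify_sbs(ref, alt) == classify_sbs(comp[ref], comp[alt])

    def test_non_sbs_rejected(self):
        with pytest.raises(ValueError):
            classify_sbs("AT", "A")
        with pytest.raises(ValueError):
            classify_sbs("C", "C")

    def test_titv_ratio_on_published_count_profile(self):
        """Record sets shaped like the two extreme mutant plants give the
        published ratios 2.78 and 1.31 at two decimals."""
        ar100 = [_sbs_record("C", "T")] * 297 + [_sbs_record("C", "A")] * 107
        ne50 = [_sbs_record("T", "C")] * 156 + [_sbs_record("T", "G")] * 119
        assert round(titv_ratio(ar100), 2) == 2.78
        assert round(titv_ratio(ne50), 2) == 1.31
        assert titv_ratio([_sbs_record("C", "T"), _sbs_record("C", "A")]) == 1.0

    def test_titv_undefined_without_transversions(self):
        with pytest.raises(ValueError, match="undefined"):
            titv_ratio([_sbs_record("C", "T")])


class TestIndelSpectrum:
    def test_sizes_from_allele_lengths(self):
        ins = MutationRecord("chr1", 5, "A", "AT", mut_class="insertion", size=1)
        dele = MutationRecord("chr1", 9, "ACGT", "A", mut_class="deletion", size=3)
        df = indel_spectrum([ins, dele])
        assert df.loc[df["size"] == 1, "insertions"].iloc[0] == 1
        assert df.loc[df["size"] == 3, "deletions"].iloc[0] == 1
        assert df.insertions.sum() + df.deletions.sum() == 2

    def test_totals_conserved_on_synthetic_truth(self, toy_genome):
        genome, _ = toy_genome
        truth = sd.generate_truth(genome, 1, n_induced=500, sbs_fraction=0.0, seed=8)[0]
        recs = [
            vp._mutation_record_from_call(normalize_variant(v, genome)) for v in truth.mutations
        ]
        df = indel_spectrum(recs)
        assert df.insertions.sum() + df.deletions.sum() == 500
        true_sizes = np.array(sorted(abs(len(v.ref) - len(v.alt)) for v in truth.mutations))
        got_sizes = np.array(
            sorted(
                s
                for col in ("insertions", "deletions")
                for s, n in zip(df["size"], df[col])
                for _ in range(n)
            )
        )
        assert (true_sizes == got_sizes).all()


class TestWindows:
    def test_boundary_positions(self):
        r1 = _sbs_record("A", "T", pos=1)
        r2 = _sbs_record("A", "T", pos=500_000)
        r3 = _sbs_record("A", "T", pos=500_001)
        df = window_density([r1, r2, r3], {"chr1": 1_200_000})
        assert df.loc[0, "sbs_count"] == 2  # pos 1 and 500,000 in window 1
        assert df.loc[1, "sbs_count"] == 1  # 500,001 starts window 2
        assert df.loc[0, ["window_start", "window_end"]].tolist() == [1, 500_000]
        assert df.loc[2, "window_end"] == 1_200_000  # short last window

    def test_counts_conserve_total(self, toy_genome):
        genome, _ = toy_genome
        rng = np.random.default_rng(3)
        recs = [
            _sbs_record("A", "T", pos=int(p), chrom=rng.choice(["chr1", "chr2"]))
            for p in rng.integers(1, 300_000, size=400)
        ]
        df = window_density(recs, {c: len(s) for c, s in genome.items()}, window=50_000)
        assert df.sbs_count.sum() == 400


class TestAnnotation:
    def test_region_calls_match_brute_force_painting_oracle(self, toy_genome):
        """1,000 fuzzed placements vs an oracle that paints every base of the
        chromosome with its region label by precedence."""
        genome, genes = toy_genome
        chrom = "chr1"
        labels = _paint_regions(len(genome[chrom]), [g for g in genes if g.chrom == chrom])
        rng = np.random.default_rng(99)
        for pos in rng.integers(1, len(genome[chrom]) + 1, size=1_000):
            pos = int(pos)
            ref = genome[chrom][pos - 1]
            alt = "A" if ref != "A" else "G"
            rec = MutationRecord(chrom, pos, ref, alt, mut_class="SBS")
            ann = annotate(rec, genes, genome)
            assert ann.region == labels[pos - 1], (pos, ann.region, labels[pos - 1])

    def test_synonymous_and_nonsynonymous_sbs(self, toy_genome):
        genome, genes = toy_genome
        from Bio.Seq import Seq

        from ionmut.genome import revcomp

        checked = {"synonymous": 0, "nonsynonymous": 0}
        for gene in genes:
            cds = gene.coding_sequence(genome)
            # walk codon positions until both effect kinds have been exercised
            for idx in range(3, len(cds) - 3):
                codon_start = 3 * (idx // 3)
                codon = cds[codon_start : codon_start + 3]
                for sub in "ACGT":
                    if sub == cds[idx]:
                        continue
                    mutated = codon[: idx % 3] + sub + codon[idx % 3 + 1 :]
                    aa0, aa1 = str(Seq(codon).translate()), str(Seq(mutated).translate())
                    if aa0 == "*" or aa1 == "*":
                        continue
                    expected = "synonymous" if aa0 == aa1 else "nonsynonymous"
                    if checked[expected] >= 5:
                        continue
                    pos = _genomic_pos_of_cds_index(gene, idx)
                    alt = sub if gene.strand == "+" else revcomp(sub)
                    rec = MutationRecord(gene.chrom, pos, genome[gene.chrom][pos - 1], alt, mut_class="SBS")
                    ann = annotate(rec, genes, genome)
                    assert ann.region == "exonic"
                    assert ann.effect == expected, (gene.gene_id, idx, expected, ann.effect)
                    checked[expected] += 1
        assert all(n >= 5 for n in checked.values())

    def test_stopgain_detected(self, toy_genome):
        genome, genes = toy_genome
        from Bio.Seq import Seq

        from ionmut.genome import revcomp

        for gene in genes:
            cds = gene.coding_sequence(genome)
            for idx in range(3, len(cds) - 3):
                codon_start = 3 * (idx // 3)
                codon = cds[codon_start : codon_start + 3]
                for sub in "ACGT":
                    mutated = codon[: idx % 3] + sub + codon[idx % 3 + 1 :]
                    if sub != cds[idx] and str(Seq(mutated).translate()) == "*":
                        pos = _genomic_pos_of_cds_index(gene, idx)
                        alt = sub if gene.strand == "+" else revcomp(sub)
                        rec = MutationRecord(
                            gene.chrom, pos, genome[gene.chrom][pos - 1], alt, mut_class="SBS"
                        )
                        assert annotate(rec, genes, genome).effect == "stopgain"
                        return
        pytest.fail("no stopgain-able site found in toy genome")

    def test_coding_indel_frame_classes(self, toy_genome):
        genome, genes = toy_genome
        gene = next(g for g in genes if g.strand == "+" and len(g.cds) == 1)
        s, e = gene.cds[0]
        pos = s + 4
        seq = genome[gene.chrom]
        del2 = MutationRecord(
            gene.chrom, pos, seq[pos - 1 : pos + 2], seq[pos - 1], mut_class="deletion", size=2
        )
        assert annotate(del2, genes, genome).effect == "frameshift"
        del3 = MutationRecord(
            gene.chrom, pos, seq[pos - 1 : pos + 3], seq[pos - 1], mut_class="deletion", size=3
        )
        ann3 = annotate(del3, genes, genome)
        assert ann3.region == "exonic"
        assert ann3.effect in ("nonframeshift", "stopgain")  # in-frame, never frameshift

    def test_unknown_chromosome_is_coordinate_error(self, toy_genome):
        genome, genes = toy_genome
        rec = _sbs_record("A", "T", pos=10, chrom="chrZ")
        with pytest.raises(ValueError, match="absent"):
            annotate(rec, genes, genome)


def _genomic_pos_of_cds_index(gene, idx):
    segs = sorted(gene.cds)
    order = segs if gene.strand == "+" else list(reversed(segs))
    off = 0
    for s, e in order:
        n = e - s + 1
        if idx < off + n:
            return s + (idx - off) if gene.strand == "+" else e - (idx - off)
        off += n
    raise AssertionError("index outside CDS")


def _paint_regions(length, genes):
    """Label every base by precedence, independently of the query logic."""
    rank = {r: i for i, r in enumerate(REGION_PRECEDENCE)}
    labels = ["intergenic"] * length

    def paint(a, b, region):
        for p in range(max(1, a), min(length, b) + 1):
            if rank[region] < rank[labels[p - 1]]:
                labels[p - 1] = region

    for g in genes:
        if g.strand == "+":
            paint(g.start - 1000, g.start - 1, "upstream")
            paint(g.end + 1, g.end + 1000, "downstream")
        else:
            paint(g.end + 1, g.end + 1000, "upstream")
            paint(g.start - 1000, g.start - 1, "downstream")
        for a, b in g.introns:
            paint(a, b, "intronic")
            paint(a, a + 1, "splicing")
            paint(b - 1, b, "splicing")
        for a, b in g.utr5:
            paint(a, b, "UTR5")
        for a, b in g.utr3:
            paint(a, b, "UTR3")
        for a, b in g.cds:
            paint(a, b, "exonic")
    return labels


class TestSummarize:
    def test_published_shape_consistency(self):
        """205 SBS + 31 InDel records sum to the published 236 total."""
        recs = (
            [_sbs_record("C", "T", pos=i + 1) for i in range(141)]
            + [_sbs_record("C", "A", pos=i + 1000) for i in range(64)]
            + [
                MutationRecord("chr1", 5000 + i, "AT", "A", mut_class="deletion", size=1)
                for i in range(31)
            ]
        )
        s = summarize_sample(recs)
        assert s["total"] == 236
        assert s["sbs_subtotal"] == 205
        assert (s["sbs_ti"], s["sbs_tv"]) == (141, 64)
        assert s["indel_subtotal"] == 31
        assert s["total"] == s["sbs_subtotal"] + s["indel_subtotal"]

    def test_empty_set_is_all_zero(self):
        s = summarize_sample([])
        assert all(v == 0 for v in s.values())


class TestEndToEnd:
    def test_zero_error_run_recovers_induced_truth_exactly(
        self, toy_genome, cohort_truth, zero_error_callsets
    ):
        genome, genes = toy_genome
        records, log = consensus_mutations(zero_error_callsets, genome, genes=genes)
        assert log["background_excluded_keys"] == 50
        for t in cohort_truth:
            got = {r.key for r in records[t.sample_id]}
            want = {normalize_variant(v, genome).key for v in t.mutations}
            assert got == want  # precision = recall = 1
        # every stage only removes records
        for slog in log["samples"].values():
            assert slog["input"] >= slog["after_background"] >= slog["after_quality"]
            assert slog["consensus"] <= slog["after_quality"] // 3 + 1

    def test_caller_disjoint_false_positives_never_reach_consensus(
        self, toy_genome, cohort_truth
    ):
        genome, _ = toy_genome
        profs = [
            sd.CallerProfile(c, fp_rate_per_mb=40.0, depth_mean=55, depth_dispersion=400, af_noise_sd=0.02)
            for c in ("gatk", "samtools", "varscan")
        ]
        callsets = {
            t.sample_id: sd.simulate_caller_calls(t, profs, genome, seed=300 + i)
            for i, t in enumerate(cohort_truth)
        }
        records, _ = consensus_mutations(callsets, genome)
        for t in cohort_truth:
            got = {r.key for r in records[t.sample_id]}
            want = {normalize_variant(v, genome).key for v in t.mutations}
            assert got == want  # zero FPs survive, full recall retained

    def test_consensus_subset_of_each_filtered_caller_set(self, toy_genome, zero_error_callsets):
        genome, _ = toy_genome
        records, _ = consensus_mutations(zero_error_callsets, genome)
        for sample, recs in records.items():
            keys = {r.key for r in recs}
            for caller_calls in zero_error_callsets[sample].values():
                caller_keys = {normalize_variant(c, genome).key for c in caller_calls}
                assert keys <= caller_keys
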