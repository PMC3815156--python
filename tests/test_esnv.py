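import io
from collections import defaultdict

import numpy as np
import pytest

from txlandscape import esnv
from txlandscape.esnv import (
    AlleleObservation,
    CohortVariantDB,
    MpileupError,
    SiteSummary,
    VariantCall,
    annotate_variant,
    candidate_filter,
    consensus_calls,
    end_bias_filter,
    filter_known,
    parse_mpileup,
    strand_bias_filter,
    summarize_alleles,
)
from conftest import run_esnv_cohort


def _site(ref_depth, alt_depth, alt_plus=None, alt_minus=None, ref="C", alt="T"):
    if alt_plus is None:
        alt_plus = (alt_depth + 1) // 2
        alt_minus = alt_depth - alt_plus
    return SiteSummary(
        chrom="chr1",
        pos=100,
        ref_allele=ref,
        ref_depth=ref_depth,
        alt_allele=alt,
        alt_depth=alt_depth,
        total_depth=ref_depth + alt_depth,
        strand_counts={alt: (alt_plus, alt_minus)},
    )


class TestParser:
    def test_hand_constructed_line(self):
        line = "chr1\t50\tG\t4\t.,aA\tIIII\n"
        (obs,) = list(parse_mpileup(io.StringIO(line)))
        counts = defaultdict(int)
        for o in obs:
            counts[(o.base, o.strand)] += 1
        assert counts == {("G", "+"): 1, ("G", "-"): 1, ("A", "-"): 1, ("A", "+"): 1}

    def test_depth_zero_line_gives_no_observations(self):
        (obs,) = list(parse_mpileup(io.StringIO("chr1\t5\tA\t0\t\t\n")))
        assert obs == []

    def test_markers_and_indels_skipped(self):
        # ^X consumes its quality char, $ is dropped, +2TT insertion skipped
        line = "chr1\t7\tC\t4\t^~..+2TT,$T\tIIII\n"
        (obs,) = list(parse_mpileup(io.StringIO(line)))
        assert [o.base for o in obs] == ["C", "C", "C", "T"]

    @pytest.mark.parametrize(
        "line",
        ["chr1\t5\tA\t3\t..\tII\n", "chr1\tx\tA\t1\t.\tI\n", "chr1\t5\tA\t1\t?\tI\n"],
    )
    def test_malformed_line_reports_line_number(self, line):
        with pytest.raises(MpileupError, match="line 1"):
            list(parse_mpileup(io.StringIO(line)))

    def test_offset_column_round_trip(self):
        line = "chr1\t9\tT\t3\t.,G\tIII\t4,25,1\n"
        (obs,) = list(parse_mpileup(io.StringIO(line)))
        assert [o.read_offset for o in obs] == [4, 25, 1]


class TestSummarize:
    def test_mpg_style_site(self):
        # 11 reference (G) reads and 14 alternate (A) reads -> ratio 14/25
        obs = [AlleleObservation("chr16", 133064, "G", "+", None, "bwa")] * 11 + [
            AlleleObservation("chr16", 133064, "A", "+", None, "bwa")
        ] * 14
        s = summarize_alleles(obs, "G")
        assert (s.alt_allele, s.alt_depth, s.ref_depth) == ("A", 14, 11)
        assert s.alt_ratio == pytest.approx(14 / 25)

    def test_mrpl3_style_site(self):
        obs = [AlleleObservation("chr3", 131220447, "C", "+", None, "bwa")] * 53 + [
            AlleleObservation("chr3", 131220447, "G", "-", None, "bwa")
        ] * 79
        s = summarize_alleles(obs, "C")
        assert (s.ref_allele, s.alt_allele) == ("C", "G")
        assert (s.ref_depth, s.alt_depth) == (53, 79)

    def test_all_reference_site_omitted(self):
        obs = [AlleleObservation("chr1", 1, "T", "+", None, "bwa")] * 10
        assert summarize_alleles(obs, "T") is None

    def test_lexicographic_tie_break(self):
        obs = [AlleleObservation("chr1", 1, b, "+", None, "bwa") for b in "GGTTCC"]
        s = summarize_alleles(obs, "G")
        assert s.alt_allele == "C"


class TestCandidateFilter:
    def test_foxa1_style_high(self):
        # 4 reference + 6 alternate reads: depth 10, ratio 0.6
        assert candidate_filter(_site(4, 6)) == "high"

    def test_low_ratio_rejected(self):
        assert candidate_filter(_site(95, 5)) == "reject"

    def test_low_confidence_band(self):
        assert candidate_filter(_site(18, 2)) == "low"

    def test_depth_boundary(self):
        assert candidate_filter(_site(1, 2)) == "reject"  # depth 3 < 4
        assert candidate_filter(_site(2, 2)) == "low"  # depth exactly 4


class TestStrandBias:
    @pytest.mark.parametrize(
        "plus,minus,expected",
        [(5, 4, True), (9, 0, False), (0, 9, False), (20, 1, False), (10, 2, True)],
    )
    def test_rule(self, plus, minus, expected):
        site = _site(10, plus + minus, alt_plus=plus, alt_minus=minus)
        assert strand_bias_filter(site) is expected


class TestConsensus:
    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(0)
        def random_sites(seed):
            r = np.random.default_rng(seed)
            out = {}
            for _ in range(30):
                pos = int(r.integers(1, 50))
                alt = "ACGT"[r.integers(4)]
                out[("chr1", pos)] = _site(10, 5, ref="G", alt=alt)
                out[("chr1", pos)].pos = pos
            return out

        a, b = random_sites(1), random_sites(2)
        result = consensus_calls(a, b)
        oracle = {
            ("chr1", p, a[k].alt_allele)
            for k, p in ((k, k[1]) for k in a)
            if k in b and b[k].alt_allele == a[k].alt_allele
        }
        assert result == oracle


class TestAnnotation:
    @pytest.fixture()
    def toy_model(self):
        # single gene, + strand, CDS = ATG GAC CAA TAA at positions 10..22
        seq = "N" * 10 + "ATGGACCAATAA" + "N" * 10
        genome = {"chrT": seq.replace("N", "A")}
        tx = esnv.Transcript(
            gene="TOY", name="TOY.T1", chrom="chrT", strand="+",
            tx_start=10, tx_end=22, cds_start=10, cds_end=22,
            exon_starts=[10], exon_ends=[22],
        )
        return [tx], genome

    def test_missense(self, toy_model):
        txs, genome = toy_model
        # GAC (D) -> CAC (H), first base of codon 2 (genomic pos0 13 -> 1-based 14)
        csq, gene = annotate_variant("chrT", 14, "G", "C", txs, genome)
        assert (csq, gene) == ("missense", "TOY")

    def test_stopgain(self, toy_model):
        txs, genome = toy_model
        # CAA (Q) -> TAA (stop), 1-based 17
        csq, _ = annotate_variant("chrT", 17, "C", "T", txs, genome)
        assert csq == "stopgain"

    def test_synonymous(self, toy_model):
        txs, genome = toy_model
        # GAC -> GAT, both Asp (third base of codon 2, 1-based 16)
        csq, _ = annotate_variant("chrT", 16, "C", "T", txs, genome)
        assert csq == "synonymous"

    def test_intergenic(self, toy_model):
        txs, genome = toy_model
        assert annotate_variant("chrT", 3, "A", "G", txs, genome) == ("non-exonic", "")

    def test_minus_strand(self):
        # - strand gene: genomic TTATTGGTCCAT revcomp = ATGGACCAATAA
        genomic = "TTATTGGTCCAT"
        genome = {"chrT": "C" * 10 + genomic + "C" * 10}
        tx = esnv.Transcript(
            gene="TOYM", name="TOYM.T1", chrom="chrT", strand="-",
            tx_start=10, tx_end=22, cds_start=10, cds_end=22,
            exon_starts=[10], exon_ends=[22],
        )
        # genomic G at pos0 16 is codon2 middle base on - strand (GAC).
        # G->T genomic = C->A transcript: GAC (D) -> AAC... compute: codon GAC
        # with first base mutated? assert a concrete nonsynonymous call
        csq, gene = annotate_variant("chrT", 17, "G", "T", [tx], genome)
        assert gene == "TOYM"
        assert csq in {"missense", "stopgain"}

    def test_frame_violation_skipped(self, toy_model):
        txs, genome = toy_model
        txs[0].cds_end = 21  # length 11, not divisible by 3
        with pytest.warns(UserWarning, match="not divisible"):
            csq, _ = annotate_variant("chrT", 14, "G", "C", txs, genome)
        assert csq == "non-exonic"


class TestKnownFilter:
    def test_allele_aware_set_difference(self):
        known = {("chr1", 10, "A"), ("chr1", 20, "C")}
        cands = [("chr1", 10, "A"), ("chr1", 10, "G"), ("chr1", 30, "T")]
        kept = filter_known(cands, known)
        assert kept == {("chr1", 10, "G"), ("chr1", 30, "T")}

    def test_position_only_mode(self):
        known = {("chr1", 10, "A")}
        kept = filter_known([("chr1", 10, "G")], known, allele_aware=False)
        assert kept == set()


class TestEndBias:
    def test_all_near_end_fails(self):
        ok, known = end_bias_filter([0, 1, 2])
        assert not ok and known

    def test_interior_evidence_passes(self):
        ok, _ = end_bias_filter([1, 20, 24])
        assert ok

    def test_unknown_offsets_pass_with_flag(self):
        ok, known = end_bias_filter([None, None])
        assert ok and not known


class TestCohortDB:
    def _db(self):
        return CohortVariantDB({"h1": "HER2", "h2": "HER2", "e1": "ER+"})

    def _call(self, sample, pos=100, alt_depth=9, failed=()):
        return VariantCall(
            sample=sample, chrom="chr1", pos=pos, ref="A", alt="G",
            alt_depth=alt_depth, total_depth=30,
            confidence="high" if alt_depth >= 4 else "low",
            consequence="missense", gene="X",
            filters_failed=frozenset(failed),
        )

    def test_exclusive_kept_and_vetoed(self):
        db = self._db()
        db.add_calls([self._call("h1"), self._call("h2", pos=200), self._call("e1", pos=200)])
        excl = db.cohort_exclusive("HER2")
        assert {k[1] for k in excl} == {100}

    def test_two_sample_support_counted_once(self):
        db = self._db()
        db.add_calls([self._call("h1"), self._call("h2")])
        excl = db.cohort_exclusive("HER2")
        assert len(excl) == 1
        assert len(excl[("chr1", 100, "A", "G")]) == 2

    def test_passing_only_mode(self):
        db = self._db()
        db.add_calls([self._call("h1"), self._call("e1", failed=["strand"])])
        assert len(db.cohort_exclusive("HER2", passing_only=True)) == 1
        assert len(db.cohort_exclusive("HER2", passing_only=False)) == 0

    def test_recurrence_nucb2_style(self):
        # alternate depths 9, 8, 2 across three tumors -> 2 high + 1 low
        db = self._db()
        db.add_calls([
            self._call("h1", alt_depth=9),
            self._call("h2", alt_depth=8),
            self._call("e1", alt_depth=2),
        ])
        (rec,) = db.recurrence_report()
        assert (rec["n_high"], rec["n_low"], rec["recurrent"]) == (2, 1, True)

    def test_singleton_not_recurrent(self):
        db = self._db()
        db.add_calls([self._call("h1")])
        (rec,) = db.recurrence_report()
        assert not rec["recurrent"]


class TestVcfRoundTrip:
    def test_write_then_read_preserves_calls(self, tmp_path):
        calls = [
            VariantCall("s1", "chr1", 10, "A", "G", 6, 20, "high", "missense", "GENEX"),
            VariantCall(
                "s2", "chr1", 30, "C", "T", 2, 10, "low", "stopgain", "GENEY",
                filters_failed=frozenset({"alt_depth"}),
            ),
        ]
        path = tmp_path / "out.vcf"
        esnv.write_vcf(calls, path)
        back = esnv.read_vcf(path)
        for orig, rt in zip(calls, back):
            for f in ("sample", "chrom", "pos", "ref", "alt", "alt_depth",
                      "total_depth", "confidence", "consequence", "gene",
                      "filters_failed"):
                assert getattr(orig, f) == getattr(rt, f)


class TestFullChain:
    def test_precision_recall_and_filter_attribution(self, pileup_dir):
        cfg, d, truth = pileup_dir
        db = run_esnv_cohort(cfg, d, truth)
        excl = db.cohort_exclusive("HER2")
        called = {
            (k[0], k[1], k[3])
            for k, v in excl.items()
            if any(c.confidence == "high" for c in v)
        }
        true_keys = {(v.chrom, v.pos, v.alt) for v in truth.variants if v.klass == "true_somatic"}
        assert called == true_keys  # precision = recall = 1.0

        # each planted artifact class fails exactly its designated filter(s)
        designated = {
            "true_somatic": set(),
            "strand_artifact": {"strand"},
            "end_artifact": {"end_bias"},
            "low_depth": {"depth", "alt_depth"},  # depth < 4 forces alt < 4
            "germline": {"known"},
            "non_exonic": {"consequence"},
            "shared": set(),  # removed by cohort exclusivity, not a filter
        }
        tmap = {(v.chrom, v.pos, v.alt, v.sample): v.klass for v in truth.variants}
        seen = defaultdict(set)
        for key in db.variants():
            for c in db.calls_for(key).values():
                klass = tmap[(c.chrom, c.pos, c.alt, c.sample)]
                seen[klass] |= set(c.filters_failed)
        for klass, expected in designated.items():
            if klass in seen:
                assert seen[klass] == expected, klass
        # shared variants are vetoed by exclusivity instead
        shared_keys = {
            (v.chrom, v.pos, v.ref, v.alt) for v in truth.variants if v.klass == "shared"
        }
        assert not shared_keys & set(excl)
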