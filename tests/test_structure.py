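"""UTR/intron inference from HSP chains, GC and coverage diagnostics."""

import math

import pytest

from lstclust.evaluate import n50
from lstclust.seqio import HitRecord, ReferenceProtein, Transcript
from lstclust.structure import (
    CoverageProfile,
    StructureAnnotation,
    aggregate_coverage_fold,
    coverage_fold,
    gc_stats,
    infer_structure,
    n50_excluding_introns,
)
from oracles import welch_t_closed_form


def hsp(q_start, q_end, s_start, s_end, bitscore=200.0, frame=1, subject="P1"):
    """1-based inclusive coordinates, as hits arrive from the parser."""
    return HitRecord(
        query_id="t1",
        subject_id=subject,
        subject_species="sp1",
        percent_identity=95.0,
        aln_length=s_end - s_start + 1,
        mismatches=0,
        gap_opens=0,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=1e-40,
        bitscore=bitscore,
        frame=frame,
    )


def protein(length, pid="P1"):
    return ReferenceProtein(pid, "sp1", "M" + "A" * (length - 1))


class TestInferStructure:
    def test_exact_full_length_cds(self):
        # transcript = exact coding match of a 100-aa protein (300 nt)
        t = Transcript("t1", "L1", "A" * 300)
        ann = infer_structure(t, protein(100), [hsp(1, 300, 1, 100)])
        assert ann.utr5 == (0, 0)
        assert ann.utr3 == (300, 300)
        assert ann.cds_spans == ((0, 300),)
        assert ann.intron_spans == ()
        assert ann.expected_cds_len == 300
        assert ann.confident

    def test_utr_spans_from_terminal_hsp(self):
        # 100 nt 5' UTR + full 300-nt CDS + 50 nt 3' UTR
        t = Transcript("t1", "L1", "A" * 450)
        ann = infer_structure(t, protein(100), [hsp(101, 400, 1, 100)])
        assert ann.utr5 == (0, 100)
        assert ann.utr3 == (400, 450)
        assert ann.cds_spans == ((100, 400),)

    def test_unaligned_termini_shrink_utrs(self):
        # HSP misses 2 N-terminal and 3 C-terminal residues: 6 and 9 nt of
        # the flanks are treated as coding, not UTR
        t = Transcript("t1", "L1", "A" * 450)
        ann = infer_structure(t, protein(100), [hsp(107, 391, 3, 97)])
        assert ann.utr5 == (0, 100)
        assert ann.utr3 == (400, 450)

    def test_adjacent_hsps_yield_intron_of_excess_length(self):
        # two HSPs adjacent in protein coordinates, 200 nt apart on the
        # transcript: one 200-nt intron span
        t = Transcript("t1", "L1", "A" * 500)
        chain = [hsp(1, 150, 1, 50), hsp(351, 500, 51, 100)]
        ann = infer_structure(t, protein(100), chain)
        assert ann.intron_spans == ((150, 350),)
        assert ann.cds_spans == ((0, 150), (350, 500))
        assert ann.confident

    def test_subject_gap_allotted_before_intron(self):
        # 10 unaligned subject residues (30 nt) sit between the HSPs along
        # with 230 nt of transcript: excess 200 nt becomes the intron
        t = Transcript("t1", "L1", "A" * 530)
        chain = [hsp(1, 150, 1, 50), hsp(381, 530, 61, 100)]
        ann = infer_structure(t, protein(100), chain)
        assert ann.intron_spans == ((180, 380),)

    def test_excess_below_min_intron_not_called(self):
        t = Transcript("t1", "L1", "A" * 320)
        chain = [hsp(1, 150, 1, 50), hsp(171, 320, 51, 100)]
        ann = infer_structure(t, protein(100), chain)
        assert ann.intron_spans == ()

    def test_confidence_threshold_is_strict_three_quarters(self):
        t = Transcript("t1", "L1", "A" * 300)
        ann = infer_structure(t, protein(100), [hsp(1, 225, 1, 75)])
        assert not ann.confident  # exactly 75% is not "> 75%"
        ann = infer_structure(t, protein(100), [hsp(1, 228, 1, 76)])
        assert ann.confident

    def test_no_relevant_hsps_gives_empty_annotation(self):
        t = Transcript("t1", "L1", "A" * 300)
        ann = infer_structure(t, protein(100), [hsp(1, 300, 1, 100, subject="OTHER")])
        assert not ann.confident
        assert ann.cds_spans == ()

    def test_minus_strand_hits_flip_orientation(self):
        t = Transcript("t1", "L1", "A" * 300)
        # blast convention: minus-strand query has q_start > q_end
        ann = infer_structure(t, protein(100), [hsp(300, 1, 1, 100, frame=-1)])
        assert ann.sense_strand == "-"
        assert ann.cds_spans == ((0, 300),)

    def test_span_accounting_sums_to_length(self):
        t = Transcript("t1", "L1", "A" * 500)
        chain = [hsp(51, 200, 1, 50), hsp(351, 500, 51, 100)]
        ann = infer_structure(t, protein(100), chain)
        total = (
            (ann.utr5[1] - ann.utr5[0])
            + sum(e - s for s, e in ann.cds_spans)
            + ann.intron_total
            + (ann.utr3[1] - ann.utr3[0])
        )
        assert total == t.length


class TestGcStats:
    def test_simple_fractions(self):
        out = gc_stats({"cds": ["ATGC"], "intron": ["AATT"]})
        assert out["mean_gc_cds"] == pytest.approx(0.5)
        assert out["mean_gc_intron"] == pytest.approx(0.0)

    def test_class_means(self):
        out = gc_stats({"cds": ["GGCC", "GGAA"], "intron": ["AATT", "GTAT"]})
        assert out["mean_gc_cds"] == pytest.approx(0.75)
        assert out["mean_gc_intron"] == pytest.approx(0.125)

    def test_ambiguous_bases_excluded_from_denominator(self):
        out = gc_stats({"cds": ["GCNN"], "intron": ["ATNN"]})
        assert out["mean_gc_cds"] == pytest.approx(1.0)

    def test_welch_p_matches_closed_form(self):
        cds = ["GCGC", "GCGA", "GGCC", "GCAT", "GGGC"]
        intron = ["ATAT", "ATGC", "AATT", "ATTA"]
        out = gc_stats({"cds": cds, "intron": intron})
        x = [3 / 4, 2 / 4 + 1 / 4, 4 / 4, 2 / 4, 4 / 4]  # per-seq GC, spelled out
        x = [sum(c in "GC" for c in s) / 4 for s in cds]
        y = [sum(c in "GC" for c in s) / 4 for s in intron]
        _, _, p = welch_t_closed_form(x, y)
        assert out["p_value"] == pytest.approx(p, rel=1e-10)

    def test_empty_class_warns_nan(self):
        with pytest.warns(UserWarning):
            out = gc_stats({"cds": ["ATGC"], "intron": []})
        assert math.isnan(out["mean_gc_intron"])
        assert math.isnan(out["p_value"])


def annotation(tid, length, cds_spans, introns):
    return StructureAnnotation(
        transcript_id=tid,
        length=length,
        utr5=(0, 0),
        utr3=(length, length),
        cds_spans=tuple(cds_spans),
        intron_spans=tuple(introns),
        expected_cds_len=sum(e - s for s, e in cds_spans),
        confident=True,
    )


class TestCoverageFold:
    def test_uniform_depth_fold_one(self):
        ann = annotation("t1", 100, [(0, 40), (60, 100)], [(40, 60)])
        prof = CoverageProfile("t1", (5.0,) * 100)
        assert coverage_fold(prof, ann) == pytest.approx(1.0)

    def test_five_fold(self):
        ann = annotation("t1", 100, [(0, 40), (60, 100)], [(40, 60)])
        depth = tuple([10.0] * 40 + [2.0] * 20 + [10.0] * 40)
        assert coverage_fold(CoverageProfile("t1", depth), ann) == pytest.approx(5.0)

    def test_zero_intron_depth_is_nan_and_excluded(self):
        ann = annotation("t1", 100, [(0, 40), (60, 100)], [(40, 60)])
        depth = tuple([10.0] * 40 + [0.0] * 20 + [10.0] * 40)
        assert math.isnan(coverage_fold(CoverageProfile("t1", depth), ann))
        agg = aggregate_coverage_fold([CoverageProfile("t1", depth)], [ann])
        assert math.isnan(agg["mean_of_ratios"])

    def test_no_introns_is_nan(self):
        ann = annotation("t1", 100, [(0, 100)], [])
        assert math.isnan(coverage_fold(CoverageProfile("t1", (1.0,) * 100), ann))

    def test_aggregate_conventions_differ_as_expected(self):
        a1 = annotation("t1", 100, [(0, 50)], [(50, 100)])
        a2 = annotation("t2", 100, [(0, 50)], [(50, 100)])
        p1 = CoverageProfile("t1", tuple([10.0] * 50 + [1.0] * 50))  # fold 10
        p2 = CoverageProfile("t2", tuple([2.0] * 50 + [2.0] * 50))  # fold 1
        agg = aggregate_coverage_fold([p1, p2], [a1, a2])
        assert agg["mean_of_ratios"] == pytest.approx(5.5)
        assert agg["ratio_of_means"] == pytest.approx((12.0 / 2) / (3.0 / 2))


class TestN50ExcludingIntrons:
    def test_no_introns_equals_plain_n50(self):
        anns = [annotation(f"t{i}", L, [(0, L)], []) for i, L in enumerate([500, 800, 1200])]
        assert n50_excluding_introns(anns) == n50([500, 800, 1200])

    def test_single_transcript_with_intron(self):
        ann = annotation("t1", 1000, [(0, 400), (600, 1000)], [(400, 600)])
        assert n50_excluding_introns([ann]) == 800


class TestPlantedRecovery:
    """Round-trip: plant introns/UTRs with the generator, recover them from
    internal translated-search HSP chains against the cognate ortholog."""

    def _recover(self, div, seeds):
        from lstclust.synthetic import SimConfig, generate
        from lstclust.translated import TranslatedSearch

        exact = total = 0
        inter = union = 0
        for seed in seeds:
            cfg = SimConfig(
                seed=seed, n_families=6, intron_retention_prob=0.6,
                ortholog_divergence=div, isoform_divergence=div, fragment_prob=0.0,
            )
            sim = generate(cfg)
            search = TranslatedSearch(sim.proteins)
            by_pid = {p.id: p for p in sim.proteins["sp1"]}
            for t in sim.transcripts:
                gene = sim.truth.transcript_to_gene[t.id]
                pid = sim.truth.gene_to_ortholog[gene]["sp1"]
                ann = infer_structure(t, by_pid[pid], search.hsps_vs(t, pid))
                spans = sim.truth.spans[t.id]
                truth_introns = [tuple(x) for x in spans["introns"]]
                total += 1
                exact += (
                    list(ann.intron_spans) == truth_introns
                    and ann.utr5 == tuple(spans["utr5"])
                    and ann.utr3 == tuple(spans["utr3"])
                )
                tset, gset = set(), set()
                for s, e in truth_introns:
                    tset |= set(range(s, e))
                for s, e in ann.intron_spans:
                    gset |= set(range(s, e))
                inter += len(tset & gset)
                union += len(tset | gset)
        return exact, total, (inter / union if union else 1.0)

    def test_exact_span_equality_at_zero_divergence(self):
        exact, total, jaccard = self._recover(0.0, range(1, 5))
        assert exact == total
        assert jaccard == 1.0

    def test_ninety_percent_base_jaccard_at_five_percent_divergence(self):
        _, _, jaccard = self._recover(0.05, range(1, 5))
        assert jaccard >= 0.90

    def test_n50_excluding_introns_matches_intron_free_source(self):
        # with fragments off, removing the planted introns restores the
        # mature isoform lengths exactly
        from lstclust.synthetic import SimConfig, generate
        from lstclust.translated import TranslatedSearch

        cfg = SimConfig(seed=3, n_families=5, intron_retention_prob=0.6,
                        ortholog_divergence=0.0, isoform_divergence=0.0,
                        fragment_prob=0.0)
        sim = generate(cfg)
        search = TranslatedSearch(sim.proteins)
        by_pid = {p.id: p for p in sim.proteins["sp1"]}
        anns = []
        mature_lengths = []
        for t in sim.transcripts:
            gene = sim.truth.transcript_to_gene[t.id]
            pid = sim.truth.gene_to_ortholog[gene]["sp1"]
            anns.append(infer_structure(t, by_pid[pid], search.hsps_vs(t, pid)))
            intron_total = sum(e - s for s, e in sim.truth.spans[t.id]["introns"])
            mature_lengths.append(t.length - intron_total)
        assert n50_excluding_introns(anns) == n50(mature_lengths)
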