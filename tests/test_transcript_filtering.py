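import numpy as np
import pytest

import lncflux as lx
from lncflux.transcript_filtering import _longest_orf_codons

# ---------------------------------------------------------------------------
# independent brute-force class-code oracle: exonic base sets + literal
# intron membership, no interval arithmetic shared with the implementation
# ---------------------------------------------------------------------------


def _bases(t):
    out = set()
    for s, e in t.exons:
        out |= set(range(s, e))
    return out


def _introns(t):
    return [(t.exons[i][1], t.exons[i + 1][0]) for i in range(len(t.exons) - 1)]


def oracle_class_code(cand, refs):
    same_overlap = opp_overlap = False
    eq = contained = False
    for r in refs:
        if r.chromosome != cand.chromosome:
            continue
        shared = _bases(cand) & _bases(r)
        if not shared:
            continue
        if r.strand == cand.strand:
            same_overlap = True
            if _introns(cand) == _introns(r):
                eq = True
            elif _bases(cand) <= _bases(r) and all(
                i in _introns(r) for i in _introns(cand)
            ):
                contained = True
        else:
            opp_overlap = True
    if eq:
        return "="
    if contained:
        return "c"
    if same_overlap:
        return "o"
    if opp_overlap:
        return "x"
    return "u"


def random_transcript(rng, tid, chrom="chr1", strand=None, max_pos=2500):
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, max_pos))
    exons = []
    for i in range(n_exons):
        length = int(rng.integers(20, 200))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(20, 150))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    return lx.TranscriptModel(tid, tid, chrom, strand, tuple(exons))


def make_tx(tid, exons, strand="+", chrom="chr1", seq=None, gid=None):
    t = lx.TranscriptModel(tid, gid or tid, chrom, strand, tuple(exons))
    return t.with_sequence(seq) if seq else t


class TestAssignClassCode:
    def test_identical_intron_chain_is_equal(self):
        ref = make_tx("r1", [(0, 100), (200, 300), (400, 500)])
        cand = make_tx("c1", [(20, 100), (200, 300), (400, 450)])
        assert lx.assign_class_code(cand, lx.AnnotationSet([ref])).code == "="

    def test_monoexonic_candidate_inside_reference_exon_is_contained(self):
        ref = make_tx("r1", [(0, 300), (400, 500)])
        cand = make_tx("c1", [(50, 250)])
        code = lx.assign_class_code(cand, lx.AnnotationSet([ref]))
        assert (code.code, code.matched_reference_id) == ("c", "r1")

    def test_spliced_subchain_is_contained(self):
        ref = make_tx("r1", [(0, 100), (200, 300), (400, 500), (600, 700)])
        cand = make_tx("c1", [(250, 300), (400, 500), (600, 650)])
        assert lx.assign_class_code(cand, lx.AnnotationSet([ref])).code == "c"

    def test_unknown_chromosome_is_unclassified(self):
        ref = make_tx("r1", [(0, 100)])
        cand = make_tx("c1", [(0, 100)], chrom="chr9")
        assert lx.assign_class_code(cand, lx.AnnotationSet([ref])).code == "u"

    def test_opposite_strand_overlap_is_x(self):
        ref = make_tx("r1", [(0, 300)])
        cand = make_tx("c1", [(100, 200)], strand="-")
        assert lx.assign_class_code(cand, lx.AnnotationSet([ref])).code == "x"

    def test_partial_same_strand_overlap_is_o(self):
        ref = make_tx("r1", [(0, 300), (500, 800)])
        cand = make_tx("c1", [(200, 400)])
        assert lx.assign_class_code(cand, lx.AnnotationSet([ref])).code == "o"

    def test_agrees_with_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        n_mismatch = 0
        for i in range(1000):
            refs = [
                random_transcript(rng, f"r{i}_{j}") for j in range(int(rng.integers(1, 4)))
            ]
            cand = random_transcript(rng, f"c{i}")
            got = lx.assign_class_code(cand, lx.AnnotationSet(refs)).code
            n_mismatch += got != oracle_class_code(cand, refs)
        assert n_mismatch == 0


class TestBuiltinCodingScore:
    def test_150_codon_orf_scores_1_5(self):
        rng = np.random.default_rng(1)
        safe = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in {"TAA", "TAG", "TGA", "ATG"}
        ]
        seq = "CC" + "ATG" + "".join(rng.choice(safe, 149)) + "TAA" + "CC"
        # independent brute-force ORF scan
        assert _longest_orf_codons(seq) == 150
        t = make_tx("t1", [(0, len(seq))], seq=seq)
        assert lx.builtin_coding_score(t).score == pytest.approx(1.5)

    def test_stop_codon_repeat_has_no_orf(self):
        t = make_tx("t1", [(0, 300)], seq="TAA" * 100)
        assert lx.builtin_coding_score(t).score == 0.0

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="200"):
            lx.builtin_coding_score(make_tx("t1", [(0, 150)], seq="A" * 150))

    def test_missing_sequence_points_to_external_scores(self):
        with pytest.raises(ValueError, match="external"):
            lx.builtin_coding_score(make_tx("t1", [(0, 300)]))


class TestExternalScores:
    def test_basic_rows_parse(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("tx1\t2.3\ntx2\t0.4\n")
        scores = {s.transcript_id: s for s in lx.load_external_scores(p)}
        assert scores["tx1"].score == 2.3
        assert scores["tx1"].source == "external"

    def test_duplicate_id_last_wins_with_warning(self, tmp_path, caplog):
        p = tmp_path / "s.tsv"
        p.write_text("tx1\t2.3\ntx1\t0.1\n")
        with caplog.at_level("WARNING", logger="lncflux"):
            scores = lx.load_external_scores(p)
        assert len(scores) == 1 and scores[0].score == 0.1
        assert "duplicate" in caplog.text

    def test_non_numeric_score_reports_line(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("tx1\t2.3\ntx2\thigh\n")
        with pytest.raises(ValueError, match="line 2"):
            lx.load_external_scores(p)


def hand_fixture():
    """Six candidates engineered so exactly one fails each cascade stage and
    two survive (one of them antisense to the reference)."""
    ref = make_tx("ref1", [(1000, 1300), (1500, 1800)])
    noncoding = "TTAACC" * 200  # 1200 nt, no ATG at all
    coding_seq = "CCC" + "ATG" + "GCT" * 149 + "TAA" + "CC"  # 455 nt, 150-codon ORF
    cands = [
        # identical intron chain -> removed at stage 1 as '='
        make_tx("c_equal", [(1050, 1300), (1500, 1700)], seq=noncoding[:450]),
        # 160 bp spliced length -> stage 2
        make_tx("c_short", [(5000, 5080), (5200, 5280)], seq=noncoding[:160]),
        # 150-codon ORF, score 1.5 -> stage 3
        make_tx(
            "c_coding",
            [(7000, 7230), (7400, 7400 + len(coding_seq) - 230)],
            seq=coding_seq,
        ),
        # single exon -> stage 4
        make_tx("c_mono", [(9000, 9400)], seq=noncoding[:400]),
        # antisense overlap with the reference ('x') but passes everything
        make_tx("c_anti", [(1100, 1350), (1600, 1850)], strand="-", seq=noncoding[:500]),
        # clean intergenic survivor
        make_tx("c_clean", [(20000, 20200), (20400, 20600)], seq=noncoding[:400]),
    ]
    return cands, lx.AnnotationSet([ref])


class TestFilterCandidates:
    def test_hand_fixture_accounting(self):
        cands, ref = hand_fixture()
        survivors, report = lx.filter_candidates(cands, ref)
        assert report.removed_by == {
            "class": 1,
            "length": 1,
            "coding": 1,
            "monoexonic": 1,
        }
        assert sorted(report.surviving_ids) == ["c_anti", "c_clean"]
        assert report.class_codes["c_equal"] == "="
        assert report.class_codes["c_anti"] == "x"
        assert report.input_count == 6

    def test_empty_candidate_list(self):
        _, ref = hand_fixture()
        survivors, report = lx.filter_candidates([], ref)
        assert len(survivors) == 0
        assert report.input_count == 0
        assert sum(report.removed_by.values()) == 0

    def test_all_reference_copies_removed_at_stage_one(self):
        cands, ref = hand_fixture()
        copies = [
            make_tx(f"copy{i}", [(1000, 1300), (1500, 1800)], seq="TTAACC" * 100)
            for i in range(3)
        ]
        _, report = lx.filter_candidates(copies, ref)
        assert report.removed_by["class"] == 3
        assert report.surviving_ids == []

    def test_unstranded_candidates_counted_separately(self):
        _, ref = hand_fixture()
        t = make_tx("c_dot", [(30000, 30400)], seq=("TTAACC" * 100)[:400])
        t = lx.TranscriptModel(
            t.transcript_id, t.gene_id, t.chromosome, ".", t.exons, t.sequence
        )
        _, report = lx.filter_candidates([t], ref)
        assert report.removed_by["unstranded"] == 1

    def test_candidate_without_sequence_or_score_is_named(self):
        _, ref = hand_fixture()
        bare = make_tx("c_bare", [(40000, 40300), (40500, 40800)])
        with pytest.raises(ValueError, match="c_bare"):
            lx.filter_candidates([bare], ref)

    def test_external_score_overrides_builtin(self):
        cands, ref = hand_fixture()
        scores = [lx.CodingScore("c_clean", 5.0, source="external")]
        _, report = lx.filter_candidates(cands, ref, scores=scores)
        assert "c_clean" not in report.surviving_ids
        assert report.removed_by["coding"] == 2

    def test_survivors_satisfy_all_constraints(self, sim_config, annotation_truth):
        annotation, truth = annotation_truth
        reference, _ = lx.split_annotation(annotation)
        cands, truth = lx.generate_candidates(sim_config, annotation, truth)
        survivors, report = lx.filter_candidates(cands, reference)
        assert report.input_count == sum(report.removed_by.values()) + len(
            report.surviving_ids
        )
        for t in survivors:
            assert report.class_codes[t.transcript_id] not in {"=", "c"}
            assert t.spliced_length >= 200
            assert t.n_exons >= 2
            assert lx.builtin_coding_score(t).score <= 1
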