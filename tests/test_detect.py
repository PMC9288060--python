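"""Detection core: evidence, candidates, dedup, support, annotation."""

from __future__ import annotations

import random

import pytest

from lctseq.align import AlignParams, SequenceDB
from lctseq.detect import (
    LCTCandidate,
    LCTEvent,
    annotate_event,
    apply_min_support,
    build_candidate,
    count_support,
    dedup_candidates,
    detect_chimeric_reads,
    run_detection,
)
from lctseq.models import GeneModel, GenomicInterval


def _rand(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="module")
def toy():
    """One transcript, one L1, and a chimera joining them at (400, 50)."""
    rng = random.Random(33)
    tx = _rand(rng, 800)
    l1 = _rand(rng, 600)
    txj, l1j = 400, 50
    while l1[l1j] == tx[txj]:  # keep the junction unambiguous
        l1j += 1
    chimera = tx[:txj] + l1[l1j : l1j + 250]
    return {
        "tx": tx,
        "l1": l1,
        "txj": txj,
        "l1j": l1j,
        "chimera": chimera,
        "tx_db": SequenceDB({"TX": tx}),
        "l1_db": SequenceDB({"L1A": l1}),
    }


class TestDetectChimericReads:
    def test_error_free_junction_read_yields_exact_evidence(self, toy):
        j = toy["txj"]
        read = toy["chimera"][j - 50 : j + 50]
        evs, stats = detect_chimeric_reads(
            [("r1", read)], toy["l1_db"], toy["tx_db"],
            transcripts_unmasked={"TX": toy["tx"]},
        )
        assert len(evs) == 1
        ev = evs[0]
        assert ev.junction_read_pos == 50
        assert ev.tx_junction_coord == toy["txj"]
        assert ev.l1_junction_coord == toy["l1j"]
        assert ev.orientation == "right"

    def test_pure_l1_read_gives_no_evidence(self, toy):
        read = toy["l1"][100:200]
        evs, stats = detect_chimeric_reads([("r1", read)], toy["l1_db"], toy["tx_db"])
        assert evs == [] and stats["no_tx_anchor"] == 1

    def test_short_l1_overhang_below_anchor_floor_is_dropped(self, toy):
        j = toy["txj"]
        read = toy["chimera"][j - 88 : j + 12]  # 12 bp L1 fragment < 18 bp floor
        evs, stats = detect_chimeric_reads([("r1", read)], toy["l1_db"], toy["tx_db"])
        assert evs == []

    def test_reverse_complement_read_gives_same_evidence(self, toy):
        from lctseq.models import reverse_complement

        j = toy["txj"]
        read = reverse_complement(toy["chimera"][j - 50 : j + 50])
        evs, _ = detect_chimeric_reads(
            [("r1", read)], toy["l1_db"], toy["tx_db"],
            transcripts_unmasked={"TX": toy["tx"]},
        )
        assert len(evs) == 1
        assert evs[0].tx_junction_coord == toy["txj"]
        assert evs[0].l1_junction_coord == toy["l1j"]


class TestBuildCandidate:
    def _evidence(self, toy, read_len=100):
        j = toy["txj"]
        read = toy["chimera"][j - read_len // 2 : j + read_len // 2]
        evs, _ = detect_chimeric_reads(
            [("r1", read)], toy["l1_db"], toy["tx_db"],
            transcripts_unmasked={"TX": toy["tx"]},
        )
        return evs[0]

    def test_interior_junction_full_extension(self, toy):
        ev = self._evidence(toy)
        cand = build_candidate(ev, {"L1A": toy["l1"]}, {"TX": toy["tx"]}, 100)
        assert len(cand.sequence) == 198  # (read_length - 1) each side
        assert cand.tx_flank == cand.l1_flank == 99
        assert cand.sequence == toy["tx"][toy["txj"] - 99 : toy["txj"]] + toy["l1"][
            toy["l1j"] : toy["l1j"] + 99
        ]
        assert not cand.truncated

    def test_flank_truncated_at_reference_edge(self, toy):
        ev = self._evidence(toy)
        ev.tx_junction_coord = 3  # junction 3 bp from the transcript 5' end
        cand = build_candidate(ev, {"L1A": toy["l1"]}, {"TX": toy["tx"]}, 100)
        assert cand.tx_flank == 3 and cand.truncated

    def test_tiny_read_length_arithmetic(self, toy):
        ev = self._evidence(toy)
        ev.tx_junction_coord, ev.l1_junction_coord = 10, 5
        cand = build_candidate(ev, {"L1A": toy["l1"]}, {"TX": toy["tx"]}, 6)
        assert cand.sequence == toy["tx"][5:10] + toy["l1"][5:10]
        assert len(cand.sequence) == 10

    def test_junction_outside_reference_errors(self, toy):
        ev = self._evidence(toy)
        ev.l1_junction_coord = 10_000
        with pytest.raises(ValueError, match="outside"):
            build_candidate(ev, {"L1A": toy["l1"]}, {"TX": toy["tx"]}, 100)


def _cand(cid, seq, read_ids=("r",)):
    half = len(seq) // 2
    return LCTCandidate(
        candidate_id=cid, sequence=seq, l1_id="L1A", l1_junction_coord=0,
        l1_strand="+", transcript_id="TX", tx_junction_coord=0,
        read_length_used=half + 1, tx_flank=half, l1_flank=len(seq) - half,
        orientation="right", read_ids=list(read_ids),
    )


class TestDedup:
    def test_exact_duplicates_collapse(self):
        out = dedup_candidates(
            [_cand("a", "ACGTACGTAA", ["r1"]), _cand("b", "ACGTACGTAA", ["r2"]),
             _cand("c", "TTGGCCAATT", ["r3"])]
        )
        assert len(out) == 2
        merged = next(c for c in out if c.sequence == "ACGTACGTAA")
        assert merged.read_ids == ["r1", "r2"]

    def test_substring_merges_into_longer(self):
        rng = random.Random(3)
        long = _rand(rng, 60)
        cands = [_cand("long", long, ["r1"]), _cand("short", long[5:41], ["r2"])]
        out = dedup_candidates(cands)
        assert len(out) == 1 and out[0].read_ids == ["r1", "r2"]

    def test_substring_containment_matches_all_pairs_oracle(self):
        rng = random.Random(4)
        seqs = [_rand(rng, 40) for _ in range(6)]
        seqs += [seqs[0][4:30], seqs[1][0:22], seqs[2]]
        cands = [_cand(f"c{i}", s, [f"r{i}"]) for i, s in enumerate(seqs)]
        out = dedup_candidates(cands)
        # oracle: survivors = sequences not strictly contained in another
        uniq = set(seqs)
        expected = {
            s for s in uniq if not any(s != t and s in t for t in uniq)
        }
        assert {c.sequence for c in out} == expected

    def test_single_candidate_unchanged(self):
        c = _cand("a", "ACGTACGTACGT")
        out = dedup_candidates([c])
        assert len(out) == 1 and out[0].sequence == c.sequence


class TestCountSupport:
    def test_originating_and_short_overhang_reads_support(self, toy):
        j = toy["txj"]
        cand = _full_candidate(toy)
        reads = [
            ("origin", toy["chimera"][j - 50 : j + 50]),
            ("short12", toy["chimera"][j - 88 : j + 12]),  # 12 >= j_min 10
            ("flank_only", toy["tx"][j - 120 : j - 20]),  # never crosses
            ("nine_bp", toy["chimera"][j - 91 : j + 9]),  # 9 < j_min
        ]
        counts, supporters = count_support([cand], reads, params=AlignParams())
        assert counts[cand.candidate_id] == 2
        assert set(supporters[cand.candidate_id]) == {"origin", "short12"}

    def test_support_monotone_in_reads(self, toy):
        j = toy["txj"]
        cand = _full_candidate(toy)
        base = [("r%d" % i, toy["chimera"][j - 60 + i : j + 40 + i]) for i in range(4)]
        extra = base + [("extra", toy["chimera"][j - 45 : j + 55])]
        c1, _ = count_support([cand], base, params=AlignParams())
        c2, _ = count_support([cand], extra, params=AlignParams())
        assert c2[cand.candidate_id] >= c1[cand.candidate_id]

    def test_read_credited_to_single_best_candidate(self, toy):
        j = toy["txj"]
        cand = _full_candidate(toy)
        # a decoy candidate sharing the transcript flank but a different L1 side
        rng = random.Random(9)
        decoy = _cand("decoy", toy["tx"][j - 99 : j] + _rand(rng, 99))
        reads = [("origin", toy["chimera"][j - 50 : j + 50])]
        counts, _ = count_support([cand, decoy], reads, params=AlignParams())
        assert counts[cand.candidate_id] == 1 and counts["decoy"] == 0


def _full_candidate(toy):
    return LCTCandidate(
        candidate_id="true", sequence=toy["tx"][toy["txj"] - 99 : toy["txj"]]
        + toy["l1"][toy["l1j"] : toy["l1j"] + 99],
        l1_id="L1A", l1_junction_coord=toy["l1j"], l1_strand="+",
        transcript_id="TX", tx_junction_coord=toy["txj"], read_length_used=100,
        tx_flank=99, l1_flank=99, orientation="right",
    )


class TestMinSupport:
    def _events(self, counts):
        return [
            LCTEvent(candidate=_cand(f"c{i}", "ACGTACGTAC"), sample_id="s", support_count=n)
            for i, n in enumerate(counts)
        ]

    def test_threshold_keeps_five_drops_four(self):
        kept = apply_min_support(self._events([4, 5, 6]), 5)
        assert [e.support_count for e in kept] == [5, 6]

    def test_empty_list_passes_through(self):
        assert apply_min_support([], 5) == []

    def test_min_support_below_one_rejected(self):
        with pytest.raises(ValueError):
            apply_min_support([], 0)


class TestAnnotate:
    @pytest.fixture()
    def model(self):
        # transcript of 300 bp: exons [0,100)+[100,200)+[200,300) on a toy
        # genome layout, CDS spanning transcript coords [80, 250)
        exons = [
            GenomicInterval("c", 0, 100),
            GenomicInterval("c", 150, 250),
            GenomicInterval("c", 300, 400),
        ]
        gm = GeneModel("G", "T", GenomicInterval("c", 0, 400), exons)
        gm.cds = GenomicInterval("c", 80, 350)
        return {"T": gm}

    def _event(self, txj):
        c = _cand("x", "ACGTACGTAC")
        c.transcript_id = "T"
        c.tx_junction_coord = txj
        return LCTEvent(candidate=c, sample_id="s", support_count=5)

    @pytest.mark.parametrize(
        "txj,region", [(50, "utr5"), (150, "coding"), (280, "utr3")]
    )
    def test_region_classes(self, model, txj, region):
        ev = annotate_event(self._event(txj), model)
        assert ev.region_class == region

    def test_noncoding_transcript(self, model):
        model["T"].cds = None
        ev = annotate_event(self._event(150), model)
        assert ev.region_class == "noncoding"

    @pytest.mark.parametrize("txj,flag", [(98, True), (102, True), (100, True), (97, False), (103, False)])
    def test_splice_junction_strictly_within_3bp(self, model, txj, flag):
        """Exon boundaries sit at transcript coords 100 and 200; the flag
        requires distance < 3 bp."""
        ev = annotate_event(self._event(txj), model)
        assert ev.splice_junction is flag

    def test_unknown_transcript_errors(self, model):
        ev = self._event(10)
        ev.candidate.transcript_id = "NOPE"
        with pytest.raises(KeyError):
            annotate_event(ev, model)


class TestRunDetection:
    def test_scene_recovered_exactly(self, small_scene, small_detection):
        df, stats = small_detection
        man = small_scene.manifest
        truth = {
            (c.transcript_id, c.tx_junction_coord, c.l1_id, c.l1_junction_coord)
            for c in man.chimeras
        }
        found = set(
            zip(df.transcript_id, df.tx_junction_coord, df.l1_id, df.l1_junction_coord)
        )
        assert found == truth
        flags = {c.transcript_id: c.at_exon_boundary for c in man.chimeras}
        assert all(bool(r.splice_junction) == flags[r.transcript_id] for r in df.itertuples())

    def test_no_events_from_decoys_or_background(self, small_scene, small_detection):
        df, _ = small_detection
        assert len(df) == len(small_scene.manifest.chimeras)

    def test_empty_input_gives_empty_table(self, small_scene, small_masked):
        df, _ = run_detection(
            [], small_scene.refs.l1_library, small_masked,
            small_scene.refs.gene_models, read_length=100,
        )
        assert len(df) == 0
        assert list(df.columns)[0] == "candidate_id"

    def test_detection_is_deterministic(self, small_scene, small_masked):
        kwargs = dict(
            l1_library=small_scene.refs.l1_library,
            masked_transcriptome=small_masked,
            gene_models=small_scene.refs.gene_models,
            repeat_library=small_scene.refs.repeat_library,
            read_length=small_scene.read_length,
        )
        reads = [(r, s) for r, s, _ in small_scene.reads]
        df1, _ = run_detection(reads, **kwargs)
        df2, _ = run_detection(reads, **kwargs)
        assert df1.to_csv(sep="\t") == df2.to_csv(sep="\t")
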