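import numpy as np
import pytest

from nesprintx.errors import InputError, ParameterError
from nesprintx.est_screen import (
    build_index,
    call_utr_candidates,
    classify_events,
    evaluate_recovery,
    map_est,
    screen_ests,
)
from nesprintx.gene_model import Exon, GeneModel
from nesprintx.synthetic import SimConfig, make_gene, simulate_ests
from nesprintx.variants import UTRSite, build_transcript, make_variant


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestMapping:
    def test_exact_substring_oracle(self, sim3):
        """For exact contiguous substrings the aligner must agree with
        brute-force string search: one block at the find() position."""
        _, model, *_ = sim3
        genome = model.locus_seq
        rng = np.random.default_rng(7)
        index = build_index(model)
        for _ in range(50):
            L = int(rng.integers(60, 300))
            g0 = int(rng.integers(0, len(genome) - L))
            read = genome[g0:g0 + L]
            expect = genome.find(read)  # leftmost occurrence
            aln = map_est(model, "r", read, index=index)
            assert not aln.empty
            assert len(aln.blocks) == 1
            r0, r1, gs, ge = aln.blocks[0]
            assert (r0, r1) == (0, L)
            assert gs == expect and ge == expect + L
            assert aln.identity == 1.0

    def test_errors_tolerated(self, sim3):
        _, model, *_ = sim3
        genome = model.locus_seq
        rng = np.random.default_rng(8)
        index = build_index(model)
        for _ in range(30):
            L = 250
            g0 = int(rng.integers(0, len(genome) - L))
            read = list(genome[g0:g0 + L])
            for pos in rng.choice(L - 60, size=3, replace=False) + 30:
                cur = read[pos]
                read[pos] = "ACGT"[("ACGT".index(cur) + 1) % 4]
            aln = map_est(model, "r", "".join(read), index=index)
            assert not aln.empty
            assert aln.blocks[0][2] == g0
            assert aln.identity >= (L - 3) / L - 1e-9

    def test_spliced_read_two_blocks(self, sim3):
        _, model, truth, *_ = sim3
        exons = model.exons
        read = model.exon_seq(exons[1].label)[-80:] + model.exon_seq(
            exons[2].label
        )[:80]
        aln = map_est(model, "r", read)
        assert not aln.empty and len(aln.blocks) == 2
        assert aln.blocks[0][3] == exons[1].end
        assert aln.blocks[1][2] == exons[2].start

    def test_polya_trim(self, sim3):
        _, model, *_ = sim3
        read = model.locus_seq[100:300] + "A" * 15
        aln = map_est(model, "r", read)
        assert aln.polya_tail and aln.tail_len >= 15

    def test_unmappable_returns_empty_alignment(self, sim3):
        """An unmapped read is a value (empty alignment), not an error,
        but classifying an empty alignment violates a precondition."""
        _, model, *_ = sim3
        rng = np.random.default_rng(9)
        aln = map_est(model, "r", _rand_seq(rng, 200))
        assert aln.empty and aln.blocks == () and aln.coverage == 0.0
        with pytest.raises(InputError):
            aln.g_start
        with pytest.raises(InputError):
            classify_events(model, aln)
        short = map_est(model, "r", "ACGTACGTAC")  # shorter than the seed
        assert short.empty

    def test_gapless_dp_oracle_equivalence(self):
        """On a small locus the aligner's best gapless block reaches the
        score of an exhaustive dynamic-programming oracle (best-scoring
        segment over every diagonal, +1 match / -2 mismatch), and
        error-free spliced reads align with every base matched (the
        splice-aware DP optimum)."""
        cfg = SimConfig(
            seed=5, n_exons=4, n_alt_starts=1, n_alt_ends=1, n_cassettes=0
        )
        model, truth, *_ = make_gene(cfg)
        genome = model.locus_seq
        assert len(genome) <= 2000

        def oracle(read: str) -> int:
            best = 0
            for d in range(-len(read) + 1, len(genome)):
                run = 0
                lo = max(0, -d)
                hi = min(len(read), len(genome) - d)
                for i in range(lo, hi):
                    run = max(0, run + (1 if read[i] == genome[i + d] else -2))
                    best = max(best, run)
            return best

        def block_score(aln, read) -> int:
            best = 0
            for r0, r1, g0, _ in aln.blocks:
                m = sum(read[r0 + i] == genome[g0 + i] for i in range(r1 - r0))
                best = max(best, m - 2 * ((r1 - r0) - m))
            return best

        rng = np.random.default_rng(6)
        index = build_index(model)
        for _ in range(25):
            L = int(rng.integers(80, 200))
            g0 = int(rng.integers(0, len(genome) - L))
            read = list(genome[g0 : g0 + L])
            for pos in rng.choice(L, size=3, replace=False):
                read[pos] = "ACGT"[("ACGT".index(read[pos]) + 1) % 4]
            read = "".join(read)
            aln = map_est(model, "r", read, index=index)
            assert not aln.empty
            assert block_score(aln, read) == oracle(read)

        for spec in truth.variants:
            mrna = build_transcript(model, truth.make_variant(model, spec.name)).mrna
            read = mrna[: min(200, len(mrna))]
            aln = map_est(model, "r", read, index=index)
            matched = sum(
                read[r0 + i] == genome[g0 + i]
                for r0, r1, g0, _ in aln.blocks
                for i in range(r1 - r0)
            )
            assert matched == len(read)

    def test_bad_inputs(self, sim3):
        _, model, *_ = sim3
        with pytest.raises(InputError):
            map_est(model, "r", "ACGU" * 30)
        with pytest.raises(ParameterError):
            map_est(model, "r", "ACGT" * 30, min_identity=0)
        with pytest.raises(ParameterError):
            build_index(model, k=4)


def _tiny_model():
    """Hand-built three-exon model with known sequence content."""
    rng = np.random.default_rng(42)
    e1 = "GCCACC" + "ATG" + "GCTGACGAAGCTGACGAAGCTGACGAAGCTGACGAAGCT"
    i1 = _rand_seq(rng, 80)
    e2 = "GACGAAGCTGACGAAGCTGACGAAGCTGACGAAGCTGACGAAGCT"
    i2 = _rand_seq(rng, 40) + "AATAAA" + _rand_seq(rng, 34)
    e3 = "GACGAAGCTGACGAAGCTGACTGA" + _rand_seq(rng, 20) + "AATAAA" + _rand_seq(rng, 10)
    flank = _rand_seq(rng, 30)
    locus = flank + e1 + i1 + e2 + i2 + e3 + flank
    o = len(flank)
    exons = [
        Exon("1", o, o + len(e1)),
        Exon("2", o + len(e1) + len(i1), o + len(e1) + len(i1) + len(e2)),
    ]
    s3 = exons[1].end + len(i2)
    exons.append(Exon("3", s3, s3 + len(e3)))
    return GeneModel("tiny", "c", "+", exons, locus)


class TestClassification:
    def test_canonical_3p_read_no_novel_events(self, sim3):
        cfg, model, truth, *_ = sim3
        v = truth.make_variant(model, "canonical")
        mrna = build_transcript(model, v).mrna
        aln = map_est(model, "r", mrna[-300:] + "A" * 15)
        kinds = {e.kind for e in classify_events(model, aln)}
        assert "novel_3p_end" not in kinds
        assert "novel_5p_start" not in kinds

    def test_planted_5p_read(self, sim3):
        cfg, model, truth, *_ = sim3
        p = next(p for p in truth.sites
                 if p.site.side == "5'" and p.site.site_class == "intron_retained")
        spec = next(s for s in truth.variants if s.start_name == p.site.name)
        mrna = build_transcript(model, truth.make_variant(model, spec.name)).mrna
        aln = map_est(model, "r", mrna[:250])
        evs = [e for e in classify_events(model, aln) if e.kind == "novel_5p_start"]
        assert len(evs) == 1
        prev = model.exons[model.exon_index(p.site.anchor_exon) - 1]
        assert evs[0].anchor == f"{prev.label}/{p.site.anchor_exon}"

    def test_planted_3p_read(self, sim3):
        cfg, model, truth, *_ = sim3
        p = next(p for p in truth.sites
                 if p.site.side == "3'" and p.site.site_class == "intron_retained")
        spec = next(s for s in truth.variants if s.end_name == p.site.name)
        mrna = build_transcript(model, truth.make_variant(model, spec.name)).mrna
        aln = map_est(model, "r", mrna[-250:] + "A" * 15)
        evs = [e for e in classify_events(model, aln) if e.kind == "novel_3p_end"]
        assert len(evs) == 1
        assert evs[0].anchor == p.site.anchor_exon
        assert "polya_tail" in evs[0].evidence
        assert "polya_signal" in evs[0].evidence

    def test_cassette_skip_and_include(self, sim3):
        cfg, model, truth, *_ = sim3
        cassette = truth.cassettes[0]
        spec = next(s for s in truth.variants if s.name == f"cassette_{cassette.label}")
        toggled = build_transcript(model, truth.make_variant(model, spec.name)).mrna
        default = build_transcript(
            model, truth.make_variant(model, "canonical")
        ).mrna
        skip_mrna, incl_mrna = (
            (toggled, default) if cassette.default_include else (default, toggled)
        )
        # skip evidence
        aln = map_est(model, "r", skip_mrna)
        skips = [e for e in classify_events(model, aln) if e.kind == "cassette_skip"]
        assert any(cassette.label in e.labels for e in skips)
        # include evidence
        aln = map_est(model, "r", incl_mrna)
        incl = [e for e in classify_events(model, aln) if e.kind == "cassette_include"]
        assert any(cassette.label in e.labels for e in incl)

    def test_retained_intron_event(self):
        model = _tiny_model()
        e1, e2 = model.exons[0], model.exons[1]
        read = model.locus_seq[e1.start : e2.end]  # retains intron 1/2
        aln = map_est(model, "r", read)
        assert len(aln.blocks) == 1
        evs = classify_events(model, aln)
        assert any(e.kind == "retained_intron" and e.anchor == "1/2" for e in evs)

    def test_internal_priming_rejected(self):
        model = _tiny_model()
        # append a genomic A-run right after exon 2 inside the intron
        locus = model.locus_seq
        i2s = model.exons[1].end
        doctored = locus[: i2s + 20] + "A" * 18 + locus[i2s + 38 :]
        model2 = GeneModel("tiny2", "c", "+", list(model.exons), doctored)
        e1, e2 = model2.exons[0], model2.exons[1]
        # read runs 20 nt into the intron then "gains" a tail by priming
        read = model2.locus_seq[e1.start : e2.end + 20] + "A" * 15
        aln = map_est(model2, "r", read)
        evs = [e for e in classify_events(model2, aln) if e.kind == "novel_3p_end"]
        assert evs == []  # tail rejected, and no hexamer in first 20 nt


class TestCandidatesAndRecovery:
    def test_end_to_end_seeded(self, sim3):
        cfg, model, truth, *_ = sim3
        reads, _ = simulate_ests(model, truth, 300, cfg)
        alns = screen_ests(model, reads)
        assert len(alns) / len(reads) > 0.95
        events = [e for a in alns for e in classify_events(model, a)]
        cands = call_utr_candidates(model, events, truth.gene_short)
        rec = evaluate_recovery(truth, cands)
        assert rec["precision"] == 1.0 and rec["recall"] == 1.0

    def test_min_support(self, sim3):
        cfg, model, truth, *_ = sim3
        reads, _ = simulate_ests(model, truth, 300, cfg)
        alns = screen_ests(model, reads)
        events = [e for a in alns for e in classify_events(model, a)]
        few = call_utr_candidates(model, events, "S1", min_support=10**6)
        assert few == []

    def test_candidate_names_follow_convention(self, sim3):
        cfg, model, truth, *_ = sim3
        reads, _ = simulate_ests(model, truth, 300, cfg)
        alns = screen_ests(model, reads)
        events = [e for a in alns for e in classify_events(model, a)]
        for c in call_utr_candidates(model, events, "S1"):
            assert c.site.name.startswith("S1-")
            assert ("5′I" in c.site.name) or ("3′E" in c.site.name)

    def test_recovery_counts_spurious_and_missed(self, sim3):
        _, model, truth, *_ = sim3
        from nesprintx.est_screen import UTRCandidate

        bogus = UTRCandidate(
            UTRSite("S1-3′E2", "3'", "2", "intron_retained", validated=True),
            support=5,
            read_ids=("a",),
        )
        rec = evaluate_recovery(truth, [bogus])
        assert rec["recall"] == 0.0
        assert rec["spurious"] == ["S1-3′E2"]
        assert len(rec["missed"]) == rec["n_planted"]
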