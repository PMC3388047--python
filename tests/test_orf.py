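import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nesprintx.errors import InputError, MassError, ParameterError
from nesprintx.orf import (
    CANONICAL_POLYA,
    NONCANONICAL_POLYA,
    RESIDUE_MASS,
    WATER_MASS,
    back_translate,
    disambiguate_names,
    domain_composition,
    frameshift_tail,
    kozak_assess,
    molecular_weight,
    name_variant,
    readthrough_translate,
    scan_polya,
    translate_cds,
    validate_utr,
    ProteinProduct,
)
from nesprintx.synthetic import (
    TAIL_DELTA_KASH_NESP1,
    TAIL_KASH_NESP1,
)
from nesprintx.variants import UTRSite

AA20 = "".join(sorted(RESIDUE_MASS))
peptides = st.text(alphabet=AA20, min_size=1, max_size=60)
dna = st.text(alphabet="ACGT", min_size=0, max_size=300)


class TestTranslate:
    def test_basic(self):
        assert translate_cds("ATGGCCTAA") == "MA"

    def test_stops_at_first_stop(self):
        assert translate_cds("ATGTGAATG") == "M"

    def test_n_codon_is_x(self):
        assert translate_cds("ATGANGGCC") == "MXA"

    def test_partial_codon_ignored(self):
        assert translate_cds("ATGGC") == "M"

    def test_too_short(self):
        with pytest.raises(InputError):
            translate_cds("AT")

    @given(peptides)
    @settings(max_examples=100, deadline=None)
    def test_back_translate_round_trip(self, pep):
        assert translate_cds(back_translate(pep) + "TAA") == pep

    def test_back_translate_unknown_residue(self):
        with pytest.raises(InputError):
            back_translate("AXB")


class TestMass:
    def test_glycine(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    @given(peptides, peptides)
    @settings(max_examples=100, deadline=None)
    def test_additivity(self, a, b):
        joined = molecular_weight(a + b)
        parts = molecular_weight(a) + molecular_weight(b) - WATER_MASS
        assert joined == pytest.approx(parts, abs=1e-6)

    def test_empty(self):
        with pytest.raises(MassError):
            molecular_weight("")

    def test_unknown_residue(self):
        with pytest.raises(MassError):
            molecular_weight("MAX")


def kozak_oracle(seq, off):
    """Independent re-scoring of the documented rule."""
    left = seq[max(0, off - 6) : off]
    ctx = "N" * (6 - len(left)) + left + seq[off : off + 4]
    score = 0
    if ctx[3] in "AG":
        score += 3
    if ctx[9] == "G":
        score += 3
    score += sum(ctx[i] == w for i, w in [(0, "G"), (1, "C"), (2, "C"), (4, "C"), (5, "C")])
    return score, (ctx[3] in "AG") or ctx[9] == "G"


class TestKozak:
    def test_strong(self):
        a = kozak_assess("GCCACCATGG", 6)
        assert a.score == 11 and a.viable

    def test_weak(self):
        a = kozak_assess("TTTTTTATGT", 6)
        assert a.score == 0 and not a.viable

    def test_plus4_only_is_viable(self):
        a = kozak_assess("TTTTTTATGG", 6)
        assert a.viable and a.score == 3

    def test_truncated_padding(self):
        a = kozak_assess("ATGG", 0)
        assert a.context == "NNNNNNATGG" and a.viable

    def test_not_an_atg(self):
        with pytest.raises(InputError):
            kozak_assess("GCCACCAAGG", 6)

    def test_window_past_end(self):
        with pytest.raises(InputError):
            kozak_assess("GCCACCATG", 6)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        n = 0
        for _ in range(300):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=80))
            for off in range(len(seq) - 3):
                if seq[off : off + 3] != "ATG":
                    continue
                a = kozak_assess(seq, off)
                score, viable = kozak_oracle(seq, off)
                assert (a.score, a.viable) == (score, viable)
                n += 1
        assert n > 200


def polya_oracle(seq, window):
    hits = []
    region = seq[:window]
    for hexamer in CANONICAL_POLYA + NONCANONICAL_POLYA:
        for m in re.finditer(f"(?={hexamer})", region):
            hits.append((m.start(), hexamer))
    return sorted(hits)


class TestPolyA:
    def test_canonical_flag(self):
        hits = scan_polya("GGGAATAAAGGGAGTAAAGG")
        assert [(h.offset_from_stop, h.hexamer, h.canonical) for h in hits] == [
            (3, "AATAAA", True),
            (12, "AGTAAA", False),
        ]

    def test_window_cutoff(self):
        assert scan_polya("G" * 50 + "AATAAA", window=40) == []

    def test_bad_window(self):
        with pytest.raises(ParameterError):
            scan_polya("AATAAA", window=3)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(1)
        total = 0
        for _ in range(300):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
            for window in (6, 50, 120):
                hits = scan_polya(seq, window=window)
                assert [(h.offset_from_stop, h.hexamer) for h in hits] == polya_oracle(
                    seq, window
                )
                total += len(hits)
        assert total > 0


class TestReadthrough:
    def test_fixture_fingerprint(self, nesp1):
        model, truth = nesp1
        v = truth.make_variant(model, "fp90")
        rt = readthrough_translate(model, v)
        assert rt.fingerprint == "AGAGYPHQ"
        assert not rt.non_stop
        assert rt.stop_offset is not None and rt.stop_offset % 3 == 0

    def test_requires_intron_retained_end(self, nesp1):
        model, truth = nesp1
        v = truth.make_variant(model, "p53KASH")
        with pytest.raises(InputError):
            readthrough_translate(model, v)


class TestFrameshift:
    def test_shifting_exclusion(self, nesp1):
        model, truth = nesp1
        v = truth.make_variant(model, "p53dKASH")
        fs = frameshift_tail(model, v)
        assert fs.frameshift
        assert fs.tail == TAIL_DELTA_KASH_NESP1
        assert "KASH" in fs.lost_domains
        assert fs.excluded_length % 3 != 0

    def test_frame_preserving_exclusion(self, nesp1):
        model, truth = nesp1
        v = truth.make_variant(model, "p56CH")  # excludes 6' (21 nt)
        fs = frameshift_tail(model, v)
        assert not fs.frameshift
        assert fs.excluded_length % 3 == 0
        assert fs.lost_domains == []

    def test_no_exclusions(self, nesp1):
        model, truth = nesp1
        v = truth.make_variant(model, "rod93")  # includes every cassette in span
        with pytest.raises(InputError):
            frameshift_tail(model, v)

    def test_mod3_property(self, nesp1, nesp2):
        for model, truth in (nesp1, nesp2):
            for spec in truth.variants:
                v = truth.make_variant(model, spec.name)
                excluded = sum(
                    model.exon(lab).length
                    for lab, inc in v.cassette_pattern.items()
                    if not inc
                )
                if excluded == 0:
                    continue
                fs = frameshift_tail(model, v)
                assert fs.frameshift == (excluded % 3 != 0)


class TestDomainsAndNames:
    def test_composition_small_variant(self, nesp1):
        model, truth = nesp1
        v = truth.make_variant(model, "p56CH")
        comp = domain_composition(v, model)
        assert comp.has_CH and comp.sr_count == 1 and not comp.has_KASH

    def test_composition_giant(self, nesp1):
        model, truth = nesp1
        v = truth.make_variant(model, "giant")
        comp = domain_composition(v, model)
        # giant excludes cassette 93, truncating SR3 (span 90-91 is fine;
        # span includes 93? SR3 spans 90-91) -> all five SRs complete
        assert comp.has_CH and comp.has_KASH and comp.sr_count == 5

    def test_name_precedence(self):
        base = dict(sequence="M", fingerprint="", mass=53_000.0)
        p = ProteinProduct(**base, has_CH=True, sr_count=2, has_KASH=True)
        assert name_variant(p, "Nesp1") == "p53CH^Nesp1"
        p = ProteinProduct(**base, has_CH=False, sr_count=2, has_KASH=True)
        assert name_variant(p, "Nesp1") == "p53KASH^Nesp1"
        p = ProteinProduct(
            **base, has_CH=False, sr_count=2, has_KASH=False, delta_KASH=True
        )
        assert name_variant(p, "Nesp1") == "p53ΔKASH^Nesp1"
        p = ProteinProduct(**base, has_CH=False, sr_count=2, has_KASH=False)
        assert name_variant(p, "Nesp1") == "p53^Nesp1"

    def test_product_invariants(self):
        with pytest.raises(InputError):
            ProteinProduct(
                sequence="MAA", fingerprint="QQ", mass=100.0,
                has_CH=False, sr_count=0, has_KASH=False,
            )
        with pytest.raises(InputError):
            ProteinProduct(
                sequence="M", fingerprint="", mass=100.0,
                has_CH=False, sr_count=0, has_KASH=True, delta_KASH=True,
            )

    def test_disambiguate(self):
        names = ["p53^N1", "p56^N1", "p53^N1"]
        assert disambiguate_names(names) == ["p53^N1a", "p56^N1", "p53^N1b"]


class TestValidateUTR:
    def test_5p_strong_validates(self, nesp1):
        model, truth = nesp1
        site = truth.site("N1-5′E138")
        assert validate_utr(site, model).validated

    def test_3p_canonical_exonic_validates(self, nesp1):
        model, truth = nesp1
        site = truth.site("N1-3′E146")
        assert validate_utr(site, model).validated

    def test_3p_intron_retained_validates(self, nesp1):
        model, truth = nesp1
        site = truth.site("N1-3′E90")
        assert validate_utr(site, model).validated

    def test_tail_evidence_short_circuit(self, nesp1):
        from dataclasses import replace

        model, truth = nesp1
        site = replace(truth.site("N1-3′E90"), polya_tail_evidence=True)
        assert validate_utr(site, model).validated

    def test_weak_5p_rejected(self):
        from nesprintx.synthetic import SimConfig, make_gene

        config = SimConfig(seed=11, kozak_strengths=("strong", "weak"))
        model, truth, *_ = make_gene(config)
        weak = [p for p in truth.sites if p.kozak == "weak"]
        assert weak
        for p in weak:
            assert not validate_utr(p.site, model).validated
            assert not p.expected_valid
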