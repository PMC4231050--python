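"""Primer design: masking, thermodynamics, gate falsification, pair search."""

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from ssratlas._util import revcomp
from ssratlas.io_formats import SequenceRecord
from ssratlas.primer_design import (Candidate, DesignFailure, PrimerParams,
                                    Template, contains_ssr_run, design_pair,
                                    dust_mask, evaluate_primer,
                                    extract_template, gc_percent, has_hairpin,
                                    max_hairpin_stem, melting_temp)
from ssratlas.repeat_finder import RepeatHit, find_repeats
from ssratlas.synthetic_fixtures import make_background


# ---------------------------------------------------------------------------
# template extraction
# ---------------------------------------------------------------------------

def test_extract_template_arithmetic():
    rec = SequenceRecord("s", "A" * 300 + "ATGC" * 5 + "C" * 680)
    hit = RepeatHit("s", 300, 320, 4, "ATGC")
    tpl = extract_template(rec, hit, flank=250, mask=False)
    assert (tpl.genome_start, len(tpl.sequence)) == (50, 520)
    assert (tpl.ssr_start, tpl.ssr_end) == (250, 270)
    assert not tpl.left_clipped and not tpl.right_clipped


def test_extract_template_clips_at_origin():
    rec = SequenceRecord("s", "ACGT" * 100)
    hit = RepeatHit("s", 5, 25, 2, "AT")
    tpl = extract_template(rec, hit, flank=250, mask=False)
    assert tpl.genome_start == 0
    assert tpl.ssr_start == 5
    assert tpl.left_clipped


# ---------------------------------------------------------------------------
# DUST-style masking
# ---------------------------------------------------------------------------

def test_dust_masks_homopolymer_window():
    assert dust_mask("A" * 64) == [(0, 64)]


def test_dust_leaves_unique_triplets_unmasked():
    rng = np.random.default_rng(3)
    seq = make_background(200, 0.5, rng)
    assert dust_mask(seq) == []


def test_dust_threshold_monotonicity():
    rng = np.random.default_rng(4)
    for _ in range(10):
        bg = make_background(150, 0.4, rng)
        seq = bg[:60] + "ATATATATAT" + bg[60:120]
        areas = []
        for thr in (0.5, 1.0, 2.0, 4.0, 8.0):
            ivs = dust_mask(seq, threshold=thr)
            areas.append(sum(b - a for a, b in ivs))
        assert areas == sorted(areas, reverse=True)


# ---------------------------------------------------------------------------
# melting temperature
# ---------------------------------------------------------------------------

def test_tm_matches_nearest_neighbor_reference():
    """Cross-check against an independent NN implementation (Biopython)."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = int(rng.integers(8, 31))
        s = "".join(rng.choice(list("ACGT"), size=n))
        ref = mt.Tm_NN(s, nn_table=mt.DNA_NN3, Na=50, dnac1=25, dnac2=25,
                       saltcorr=5)
        assert melting_temp(s) == pytest.approx(ref, abs=0.5)


def test_tm_reverse_complement_symmetry():
    rng = np.random.default_rng(12)
    for _ in range(30):
        s = "".join(rng.choice(list("ACGT"), size=20))
        assert melting_temp(s) == pytest.approx(melting_temp(revcomp(s)),
                                                abs=1e-9)


def test_tm_appending_gc_raises_tm():
    base = "ATTAGATTCAATCGATAATA"  # A/T rich 20-mer
    assert melting_temp(base + "G") > melting_temp(base)
    assert melting_temp("G" + base) > melting_temp(base)


def test_tm_input_validation():
    with pytest.raises(ValueError):
        melting_temp("ACGTACG")  # < 8 nt
    with pytest.raises(ValueError):
        melting_temp("ACGTNACGTACG")


# ---------------------------------------------------------------------------
# hairpins and repetitive content
# ---------------------------------------------------------------------------

def test_hairpin_stem_detection():
    stem, loop = "GCATCGA", "TTTT"
    hp = stem + loop + revcomp(stem)
    assert max_hairpin_stem(hp) >= 7
    assert has_hairpin(hp)
    assert not has_hairpin("ACGTGGTTCAACTGGACAAT")


def test_hairpin_existence_matches_max_stem():
    rng = np.random.default_rng(13)
    for _ in range(300):
        s = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 26))))
        assert has_hairpin(s) == (max_hairpin_stem(s) >= 7)


def test_contains_ssr_run_matches_scanner():
    rng = np.random.default_rng(14)
    for _ in range(300):
        s = "".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 26))))
        assert contains_ssr_run(s) == bool(find_repeats(s))
    assert contains_ssr_run("AT" * 10)
    assert contains_ssr_run("CCG" * 6 + "ACGTACG")


# ---------------------------------------------------------------------------
# gate falsification: every constraint independently triggerable
# ---------------------------------------------------------------------------

def _plain_template(seq, ssr=(250, 270), masked=()):
    return Template(scaffold="s", sequence=seq, ssr_start=ssr[0],
                    ssr_end=ssr[1], genome_start=0, masked=list(masked))


@pytest.fixture(scope="module")
def clean_template():
    rng = np.random.default_rng(21)
    bg = make_background(520, 0.5, rng)
    seq = bg[:250] + "AGAT" * 5 + bg[270:]
    return _plain_template(seq)


def test_gate_length(clean_template):
    ok, reasons = evaluate_primer(Candidate(0, 17, "+"), clean_template)
    assert not ok and "length" in reasons
    ok, reasons = evaluate_primer(Candidate(0, 26, "+"), clean_template)
    assert not ok and "length" in reasons


def test_gate_ssr_content(clean_template):
    tpl = _plain_template("AT" * 10 + clean_template.sequence[20:])
    ok, reasons = evaluate_primer(Candidate(0, 20, "+"), tpl)
    assert not ok and "ssr_content" in reasons


def test_gate_masked_3prime(clean_template):
    # take a candidate that passes every gate, then mask its final base:
    # the masked 3' end must become the single reason for rejection
    start = next(s for s in range(230)
                 if evaluate_primer(Candidate(s, 20, "+"), clean_template)[0])
    tpl = _plain_template(clean_template.sequence,
                          masked=[(start + 19, start + 20)])
    ok, reasons = evaluate_primer(Candidate(start, 20, "+"), tpl)
    assert not ok and reasons == ["masked_3prime"]
    # reverse strand: 3' end is the template-start side of the binding site
    tpl = _plain_template(clean_template.sequence, masked=[(300, 301)])
    ok, reasons = evaluate_primer(Candidate(300, 20, "-"), tpl)
    assert "masked_3prime" in reasons


def test_gate_gc(clean_template):
    tpl = _plain_template("GGCCGGAGCCGGCAGGCCGC" + clean_template.sequence[20:])
    ok, reasons = evaluate_primer(Candidate(0, 20, "+"), tpl)
    assert not ok and "gc" in reasons


def test_gate_tm(clean_template):
    low = "ATCGTTAACGATAGTTCA"  # 18-mer, Tm well below 57
    assert melting_temp(low) < 57
    tpl = _plain_template(low + clean_template.sequence[18:])
    ok, reasons = evaluate_primer(Candidate(0, 18, "+"), tpl)
    assert not ok and "tm" in reasons


def test_gate_contains_n(clean_template):
    tpl = _plain_template("N" + clean_template.sequence[1:])
    ok, reasons = evaluate_primer(Candidate(0, 20, "+"), tpl)
    assert not ok and "contains_n" in reasons


def test_gate_hairpin(clean_template):
    stem = "GCATCGA"
    seq = "ACGTA" + stem + "TTTT" + revcomp(stem) + "A"  # 24-mer with 7bp stem
    tpl = _plain_template(seq + clean_template.sequence[len(seq):])
    ok, reasons = evaluate_primer(Candidate(0, len(seq), "+"), tpl)
    assert not ok and "hairpin" in reasons


def test_gate_low_complexity(clean_template):
    tpl = _plain_template(clean_template.sequence, masked=[(0, 15)])
    ok, reasons = evaluate_primer(Candidate(0, 20, "+"), tpl)
    assert not ok and "low_complexity" in reasons


def test_passing_candidate_found_by_rejection_sampling(clean_template):
    """Some 20-mer of the clean flank clears every gate independently."""
    found = None
    for start in range(0, 230):
        ok, reasons = evaluate_primer(Candidate(start, 20, "+"), clean_template)
        if ok:
            found = start
            break
    assert found is not None and reasons == []


# ---------------------------------------------------------------------------
# pair design
# ---------------------------------------------------------------------------

def test_design_pair_on_clean_template(clean_template):
    pair = design_pair(clean_template)
    assert pair.is_pair
    assert 250 <= pair.product_size <= 350
    assert pair.forward_start + pair.forward_len <= clean_template.ssr_start
    assert pair.reverse_start >= clean_template.ssr_end
    assert abs(pair.tm_forward - pair.tm_reverse) <= 3.0
    assert pair.reverse_seq == revcomp(
        clean_template.sequence[pair.reverse_start:
                                pair.reverse_start + pair.reverse_len])
    # standalone Tm agrees with the prefix-sum Tm used during search
    assert melting_temp(pair.forward_seq) == pytest.approx(pair.tm_forward,
                                                           abs=1e-6)


def test_design_pair_deterministic(clean_template):
    assert design_pair(clean_template) == design_pair(clean_template)


def test_design_pair_fully_masked_flank_fails(clean_template):
    tpl = _plain_template(clean_template.sequence,
                          masked=[(0, clean_template.ssr_start)])
    res = design_pair(tpl)
    assert isinstance(res, DesignFailure)
    assert res.reason == "no_forward_candidates"
    assert dict(res.detail)  # aggregated failure reasons present


def test_success_rate_on_clean_flanks():
    """>= 95% design success over 60 templates with clean 50% GC flanks."""
    rng = np.random.default_rng(42)
    ok = 0
    n = 60
    for i in range(n):
        bg = make_background(560, 0.5, rng)
        seq = bg[:250] + "AGAT" * 5 + bg[290:540]
        tpl = _plain_template(seq)
        tpl.masked = dust_mask(seq)
        if design_pair(tpl).is_pair:
            ok += 1
    assert ok / n >= 0.95


def test_primer_params_validation():
    with pytest.raises(ValueError):
        PrimerParams(len_min=20, len_opt=19)


def test_pipeline_primers_respect_all_invariants(pipeline):
    designed = [(sid, p) for sid, p in pipeline.primers.items() if p.is_pair]
    assert designed, "fixture should yield at least one designed pair"
    hits = {sid: h for sid, h in
            zip([r.ssr_id for r in pipeline.records], pipeline.hits)}
    for sid, pair in designed:
        assert 250 <= pair.product_size <= 350
        assert gc_percent(pair.forward_seq) <= 60
        assert 57 <= pair.tm_forward <= 63
        assert 57 <= pair.tm_reverse <= 63
        # genome-coordinate binding sites bracket the SSR
        h = hits[sid]
        assert pair.forward_genome_start + pair.forward_len <= h.start
        assert pair.reverse_genome_start >= h.end
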