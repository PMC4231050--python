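"""Length-class binning, atlas assembly and summary arithmetic."""

import pandas as pd
import pytest

from ssratlas.atlas import (bin_length_class, build_atlas, column_percentages,
                            mean_ssrs_per_gene, screen_summary, ssr_id_of,
                            summarize, with_margins)
from ssratlas.genome_context import GenomicLocation
from ssratlas.repeat_finder import RepeatHit


@pytest.mark.parametrize("size,cls", [(12, "II"), (19, "II"), (20, "I"),
                                      (35, "I")])
def test_bin_length_class(size, cls):
    assert bin_length_class(size) == cls


def test_bin_length_class_rejects_small():
    with pytest.raises(ValueError):
        bin_length_class(11)


def _hits():
    return [RepeatHit("s1", 0, 12, 2, "AT"),
            RepeatHit("s1", 50, 71, 3, "AAG"),
            RepeatHit("s2", 10, 30, 4, "AGAT")]


def test_ssr_id_format():
    assert ssr_id_of(RepeatHit("s1", 99, 111, 2, "AT")) == "s1:100-111:2"


def test_build_atlas_joins_and_flags():
    hits = _hits()
    ids = [ssr_id_of(h) for h in hits]
    contexts = {ids[0]: GenomicLocation("exon", ("gA",)),
                ids[1]: GenomicLocation("intron", ("gA",)),
                ids[2]: GenomicLocation("intergenic")}
    lgs = {i: "LG1" for i in ids}

    class FakePair:
        is_pair = True
        forward_seq = "A" * 20
        reverse_seq = "T" * 20
        product_size = 300
        tm_forward = 60.0
        tm_reverse = 60.0

    records = build_atlas(hits, contexts, lgs,
                          gene_annotations={"gA": ("kinase", "GO:5")},
                          primer_results={ids[0]: FakePair(),
                                          ids[1]: FakePair()})
    assert len(records) == 3
    assert records[0].annotation_text == "kinase"
    assert records[0].length_class == "II"
    assert records[1].length_class == "I"  # size 21
    assert records[2].primer_pair is None
    assert records[2].no_primer_reason == "not_attempted"
    flagged = [r for r in records if r.primer_pair is None]
    assert len(flagged) == 1


def test_build_atlas_empty_and_orphans():
    assert build_atlas([], {}, {}) == []
    hits = _hits()
    with pytest.raises(KeyError, match="s1:1-12:2"):
        build_atlas(hits, {}, {})


def test_build_atlas_matches_fixture_truth(pipeline):
    truth = {t.ssr_id: t for t in pipeline.sim.truth}
    assert set(truth) == {r.ssr_id for r in pipeline.records}
    for rec in pipeline.records:
        t = truth[rec.ssr_id]
        assert (rec.period, rec.size, rec.location, rec.lg_label) == \
            (t.period, t.size, t.location, t.lg)
        assert rec.exponent == pytest.approx(t.exponent)


def test_summarize_conserves_counts(pipeline):
    for dims in [("location", "period"), ("length_class", "lg")]:
        table = summarize(pipeline.records, *dims)
        assert table.grand_total == len(pipeline.records)
        # percentages sum to 100 per column
        for col in table.percents.columns:
            body = table.percents[col].drop("Total")
            assert abs(body.sum() - 100.0) < 0.1 + 1e-9


def test_summarize_single_record(pipeline):
    table = summarize(pipeline.records[:1], "location", "period")
    counts = table.counts.drop("Total").drop(columns="Total")
    assert counts.to_numpy().sum() == 1
    assert table.percents.iloc[0, 0] == 100.0


def test_summarize_unknown_dimension(pipeline):
    with pytest.raises(ValueError):
        summarize(pipeline.records, "location", "flavour")


def test_margins_and_percentages_on_printed_counts():
    """Arithmetic consistency of the margin/percentage helpers on a
    location-by-period table of genome-scale counts."""
    counts = pd.DataFrame(
        {"Di": [130, 7, 7158, 54853], "Tri": [3588, 27, 1959, 24841],
         "Tetra": [117, 4, 2343, 19584], "Penta": [206, 4, 1878, 19956],
         "Hexa": [1303, 31, 2476, 19853]},
        index=["Exon", "Exon-intron", "Intron", "Intergenic"])
    tot = with_margins(counts)
    assert list(tot.loc["Total"]) == [62148, 30415, 22048, 22044, 23663, 160318]
    assert list(tot["Total"]) == [5344, 73, 15814, 139087, 160318]
    pct = column_percentages(pd.DataFrame({"all": tot["Total"][:-1]}))
    assert pct.loc["Intergenic", "all"] == 86.8
    assert pct.loc["Intron", "all"] == 9.9
    assert pct.loc["Exon", "all"] == 3.3


@pytest.mark.parametrize("n_poly,n_total,pct", [(19, 73, 26), (0, 73, 0),
                                                (73, 73, 100)])
def test_screen_summary(n_poly, n_total, pct):
    assert screen_summary(n_poly, n_total) == pct


def test_screen_summary_validation():
    with pytest.raises(ValueError):
        screen_summary(1, 0)
    with pytest.raises(ValueError):
        screen_summary(5, 3)


def test_mean_ssrs_per_gene():
    assert mean_ssrs_per_gene(257, 113) == 2.3
    assert mean_ssrs_per_gene(528, 187) == 2.8
    assert mean_ssrs_per_gene(1, 1) == 1.0


def test_length_class_partitions_atlas(pipeline):
    n1 = sum(1 for r in pipeline.records if r.length_class == "I")
    n2 = sum(1 for r in pipeline.records if r.length_class == "II")
    assert n1 + n2 == len(pipeline.records)
    assert all(r.size >= 20 for r in pipeline.records if r.length_class == "I")
    assert all(12 <= r.size <= 19 for r in pipeline.records
               if r.length_class == "II")
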