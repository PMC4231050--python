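"""Candidate-gene marker nomination from protein-alignment hit tables.

Protein queries with a known role (e.g. fruit-ripening genes from a related
species) are aligned against the predicted proteome; hits surviving the
stringent thresholds — E-value <= 1e-30, similarity (percent positives)
>= 50 %, and both query and hit coverage >= 75 %, all inclusive — nominate
their subject genes, which are then joined to the genic SSR atlas to yield
trait-associated markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pandas as pd

from .atlas import AtlasRecord, mean_ssrs_per_gene


@dataclass(frozen=True)
class OrthologFilter:
    max_evalue: float = 1e-30
    min_similarity: float = 50.0
    min_query_coverage: float = 75.0
    min_hit_coverage: float = 75.0

    def __post_init__(self) -> None:
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")
        for v in (self.min_similarity, self.min_query_coverage,
                  self.min_hit_coverage):
            if not 0 <= v <= 100:
                raise ValueError("percent thresholds must be within 0-100")


def filter_hits(hits: pd.DataFrame, flt: OrthologFilter | None = None,
                similarity_column: str = "ppos") -> pd.DataFrame:
    """Keep hits passing every threshold (all comparisons inclusive).

    ``hits`` uses the extended tabular columns (qseqid, sseqid, evalue, ppos,
    length, qlen, slen).  ``similarity_column`` may be switched to an
    identity column if the table carries one.  Zero-length query/subject
    raises, naming the offending record.
    """
    flt = flt or OrthologFilter()
    bad = hits[(hits["qlen"] <= 0) | (hits["slen"] <= 0)]
    if len(bad):
        raise ValueError(
            f"zero-length query/subject in records: "
            f"{bad['qseqid'].tolist()} vs {bad['sseqid'].tolist()}")
    qcov = 100.0 * hits["length"] / hits["qlen"]
    scov = 100.0 * hits["length"] / hits["slen"]
    keep = ((hits["evalue"] <= flt.max_evalue)
            & (hits[similarity_column] >= flt.min_similarity)
            & (qcov >= flt.min_query_coverage)
            & (scov >= flt.min_hit_coverage))
    return hits[keep].reset_index(drop=True)


def best_hit_per_subject(hits: pd.DataFrame,
                         similarity_column: str = "ppos") -> pd.DataFrame:
    """One row per subject gene: lowest E-value, ties to highest similarity."""
    ordered = hits.sort_values(
        ["sseqid", "evalue", similarity_column, "qseqid"],
        ascending=[True, True, False, True], kind="mergesort")
    return ordered.drop_duplicates("sseqid", keep="first").reset_index(drop=True)


def nominate_genes(filtered: pd.DataFrame, atlas: Sequence[AtlasRecord]
                   ) -> pd.DataFrame:
    """Join surviving subject genes to the genic SSR atlas.

    Returns one row per nominated gene: SSR counts (total / exonic /
    intronic, counting markers with designed primers), the best query and
    its E-value, plus the provenance list of all passing queries.
    """
    best = best_hit_per_subject(filtered)
    queries_by_subject: Dict[str, List[str]] = {}
    for r in filtered.itertuples():
        queries_by_subject.setdefault(r.sseqid, [])
        if r.qseqid not in queries_by_subject[r.sseqid]:
            queries_by_subject[r.sseqid].append(r.qseqid)
    per_gene: Dict[str, Dict[str, int]] = {}
    for rec in atlas:
        if rec.location not in ("exon", "exon_intron", "intron"):
            continue
        if rec.primer_pair is None:
            continue
        for gid in rec.gene_ids:
            d = per_gene.setdefault(gid, {"n": 0, "exon": 0, "intron": 0})
            d["n"] += 1
            if rec.location == "exon":
                d["exon"] += 1
            elif rec.location == "intron":
                d["intron"] += 1
    rows = []
    for r in best.itertuples():
        counts = per_gene.get(r.sseqid, {"n": 0, "exon": 0, "intron": 0})
        rows.append({
            "gene_id": r.sseqid, "n_ssrs": counts["n"],
            "n_exonic": counts["exon"], "n_intronic": counts["intron"],
            "best_query": r.qseqid, "best_evalue": r.evalue,
            "all_queries": ";".join(queries_by_subject[r.sseqid])})
    return pd.DataFrame(rows, columns=["gene_id", "n_ssrs", "n_exonic",
                                       "n_intronic", "best_query",
                                       "best_evalue", "all_queries"])


def ssrs_per_gene(atlas: Sequence[AtlasRecord], gene_set: Iterable[str]
                  ) -> Tuple[Dict[str, int], float]:
    """Genic SSR markers (with primers) per gene of ``gene_set``.

    Genes with zero markers are dropped from the denominator; the mean is
    total markers / genes with >= 1 marker, rounded to one decimal.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    counts: Dict[str, int] = {}
    for rec in atlas:
        if rec.location not in ("exon", "exon_intron", "intron"):
            continue
        if rec.primer_pair is None:
            continue
        for gid in rec.gene_ids:
            if gid in gene_set:
                counts[gid] = counts.get(gid, 0) + 1
    total = sum(counts.values())
    mean = mean_ssrs_per_gene(total, len(counts)) if counts else 0.0
    return counts, mean
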