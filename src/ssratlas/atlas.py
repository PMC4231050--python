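"""Atlas assembly and summary statistics.

Joins repeat hits with their genomic context, linkage group, gene
annotations and designed primers into one catalog row per SSR, bins arrays
into length class I (>= 20 bases, typically hypervariable) and class II
(12-19 bases), and cross-tabulates the catalog along any pair of dimensions
with the conventional one-decimal percentage columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._util import percentage, round_half_up
from .genome_context import GenomicLocation, UNPLACED
from .motif_algebra import canonical_motif
from .repeat_finder import RepeatHit

CLASS_I_MIN = 20
MIN_SSR_SIZE = 12

DIMENSIONS = ("location", "period", "motif_class", "lg", "length_class")


def bin_length_class(size: int) -> str:
    """'I' for arrays >= 20 bases, 'II' for 12-19; smaller sizes are invalid."""
    if size < MIN_SSR_SIZE:
        raise ValueError(f"SSR size {size} < {MIN_SSR_SIZE}")
    return "I" if size >= CLASS_I_MIN else "II"


def ssr_id_of(hit: RepeatHit) -> str:
    """Deterministic SSR identifier: scaffold:start1-end1:period."""
    return f"{hit.scaffold}:{hit.start + 1}-{hit.end}:{hit.period}"


@dataclass
class AtlasRecord:
    """One catalog row: SSR + context + gene + LG + primer columns."""

    ssr_id: str
    scaffold: str
    start: int  # 0-based half-open internally
    end: int
    motif: str
    canonical_class: str
    period: int
    size: int
    exponent: float
    length_class: str
    location: str
    gene_ids: Tuple[str, ...] = ()
    annotation_text: str = ""
    go_terms: str = ""
    lg_label: str = UNPLACED
    primer_pair: Optional[object] = None  # PrimerPair
    no_primer_reason: str = ""

    @property
    def primary_gene(self) -> str:
        return self.gene_ids[0] if self.gene_ids else ""

    def to_row(self) -> dict:
        pp = self.primer_pair
        return {
            "ssr_id": self.ssr_id, "scaffold": self.scaffold,
            "start": self.start + 1, "end": self.end, "motif": self.motif,
            "canonical_class": self.canonical_class, "period": self.period,
            "size": self.size, "exponent": f"{self.exponent:g}",
            "length_class": self.length_class, "location": self.location,
            "gene_id": ";".join(self.gene_ids),
            "annotation": self.annotation_text, "GO": self.go_terms,
            "linkage_group": self.lg_label,
            "fwd_primer": pp.forward_seq if pp else f"NO_PRIMER:{self.no_primer_reason}",
            "rev_primer": pp.reverse_seq if pp else "",
            "product_size": str(pp.product_size) if pp else "",
            "Tm_fwd": f"{pp.tm_forward:.2f}" if pp else "",
            "Tm_rev": f"{pp.tm_reverse:.2f}" if pp else "",
        }


def build_atlas(hits: Sequence[RepeatHit],
                contexts: Dict[str, GenomicLocation],
                lg_assignments: Dict[str, str],
                gene_annotations: Optional[Dict[str, Tuple[str, str]]] = None,
                primer_results: Optional[Dict[str, object]] = None,
                ) -> List[AtlasRecord]:
    """Join the per-stage outputs, keyed by ssr_id, into atlas records.

    ``contexts`` and ``lg_assignments`` must cover every hit (orphans raise);
    ``primer_results`` maps ssr_id to a PrimerPair or a DesignFailure, and
    hits without an entry are marked not_attempted.
    """
    gene_annotations = gene_annotations or {}
    primer_results = primer_results or {}
    ids = [ssr_id_of(h) for h in hits]
    orphans = [i for i in ids if i not in contexts]
    orphans += [i for i in ids if i not in lg_assignments]
    if orphans:
        raise KeyError(f"ssr_ids missing from stage inputs: {sorted(set(orphans))}")

    records: List[AtlasRecord] = []
    for hit, sid in zip(hits, ids):
        ctx = contexts[sid]
        primary = ctx.gene_ids[0] if ctx.gene_ids else ""
        ann, go = gene_annotations.get(primary, ("", ""))
        pp = primer_results.get(sid)
        no_reason = ""
        if pp is None:
            no_reason = "not_attempted"
        elif not getattr(pp, "is_pair", False):
            no_reason = getattr(pp, "reason", "failed")
            pp = None
        records.append(AtlasRecord(
            ssr_id=sid, scaffold=hit.scaffold, start=hit.start, end=hit.end,
            motif=hit.motif,
            canonical_class=canonical_motif(hit.motif).label
            if hit.period > 1 else hit.motif,
            period=hit.period, size=hit.size, exponent=hit.exponent,
            length_class=bin_length_class(hit.size),
            location=ctx.category, gene_ids=ctx.gene_ids,
            annotation_text=ann, go_terms=go,
            lg_label=lg_assignments[sid], primer_pair=pp,
            no_primer_reason=no_reason))
    return records


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class SummaryTable:
    """Cross-tabulated counts with per-column percentage companion table."""

    counts: pd.DataFrame   # includes a Total row and Total column
    percents: pd.DataFrame  # share of each column's total, one decimal

    @property
    def grand_total(self) -> int:
        return int(self.counts.loc["Total", "Total"])


def with_margins(counts: pd.DataFrame) -> pd.DataFrame:
    """Append a Total row and Total column to a counts table."""
    out = counts.copy()
    out["Total"] = out.sum(axis=1)
    out.loc["Total"] = out.sum(axis=0)
    return out


def column_percentages(counts: pd.DataFrame, ndigits: int = 1) -> pd.DataFrame:
    """Each cell as a half-up-rounded percentage of its column total.

    ``counts`` must not already contain margins; a Total row of 100.0 per
    column is appended.
    """
    totals = counts.sum(axis=0)
    pct = counts.copy().astype(float)
    for col in counts.columns:
        t = totals[col]
        pct[col] = [percentage(v, t, ndigits) if t else 0.0
                    for v in counts[col]]
    pct.loc["Total"] = [100.0 if totals[c] else 0.0 for c in counts.columns]
    return pct


def _dim_values(rec: AtlasRecord, dim: str):
    if dim == "location":
        return rec.location
    if dim == "period":
        return rec.period
    if dim == "motif_class":
        return rec.canonical_class
    if dim == "lg":
        return rec.lg_label
    if dim == "length_class":
        return rec.length_class
    raise ValueError(f"unknown dimension {dim!r}; use one of {DIMENSIONS}")


def summarize(atlas: Sequence[AtlasRecord], row_dim: str, col_dim: str
              ) -> SummaryTable:
    """Cross-tabulate the atlas over two dimensions.

    Percentages are computed down each column of the raw counts (each
    column's Total = 100.0), matching the conventional layout of SSR
    distribution tables.
    """
    rows = [_dim_values(r, row_dim) for r in atlas]
    cols = [_dim_values(r, col_dim) for r in atlas]
    if atlas:
        counts = pd.crosstab(pd.Series(rows, name=row_dim),
                             pd.Series(cols, name=col_dim))
    else:
        counts = pd.DataFrame()
    counts = counts.sort_index(axis=0).sort_index(axis=1)
    return SummaryTable(counts=with_margins(counts) if len(counts) else
                        pd.DataFrame({"Total": [0]}, index=["Total"]),
                        percents=column_percentages(counts) if len(counts)
                        else pd.DataFrame())


def screen_summary(n_polymorphic: int, n_screened: int) -> int:
    """Marker-screen rate: 100*n_polymorphic/n_screened, nearest integer."""
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if not 0 <= n_polymorphic <= n_screened:
        raise ValueError("need 0 <= n_polymorphic <= n_screened")
    return int(round_half_up(100.0 * n_polymorphic / n_screened, 0))


def mean_ssrs_per_gene(total_ssrs: int, n_genes: int) -> float:
    """Mean SSR markers per gene (genes with >=1 marker), one decimal."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return round_half_up(total_ssrs / n_genes, 1)
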