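"""Genomic-context classification of SSRs and linkage-group assignment.

Each SSR is assigned exactly one of four categories against the gene
annotation, with priority exon > exon_intron > intron > intergenic:

* ``exon`` — entirely within a single exon (or CDS segment, in ``cds`` mode)
  of any transcript of any gene containing the SSR;
* ``exon_intron`` — within some transcript, overlapping both exonic sequence
  and an intron (a splice-junction straddler);
* ``intron`` — entirely within an intron of some transcript (introns are the
  gaps between consecutive exons, never read from GFF intron features);
* ``intergenic`` — everything else.  An SSR overlapping a gene but sticking
  out of its span is intergenic with ``boundary_flag`` set.

Isoform disagreements resolve by the same priority: an SSR fully inside one
transcript's exon is exonic even if it would be intronic in another isoform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .io_formats import AnnotationSet, GeneModel
from .repeat_finder import RepeatHit
from ._util import round_half_up

CATEGORIES = ("exon", "exon_intron", "intron", "intergenic")
UNPLACED = "Un"


@dataclass(frozen=True)
class GenomicLocation:
    category: str
    gene_ids: Tuple[str, ...] = ()
    boundary_flag: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _segments_of(gene: GeneModel, mode: str) -> List[List[Tuple[int, int]]]:
    if mode == "exon":
        return gene.transcripts
    if mode == "cds":
        return [c for c in gene.cds if c]
    raise ValueError(f"mode must be 'exon' or 'cds', got {mode!r}")


def classify_location(hit: RepeatHit, annotation: AnnotationSet,
                      mode: str = "exon") -> GenomicLocation:
    """Classify one SSR against the annotation (see module docstring).

    ``gene_ids`` lists every gene whose span fully contains the SSR, in
    coordinate order.  A scaffold absent from the annotation is intergenic.
    """
    s, e = hit.start, hit.end
    overlapping = annotation.overlapping(hit.scaffold, s, e)
    if not overlapping:
        return GenomicLocation("intergenic")
    containing = [g for g in overlapping if g.start <= s and e <= g.end]
    if not containing:
        return GenomicLocation("intergenic", boundary_flag=True)
    gene_ids = tuple(g.gene_id for g in containing)

    segsets = [segs for g in containing for segs in _segments_of(g, mode) if segs]
    # 1) fully inside one exon/CDS segment
    for segs in segsets:
        if any(a <= s and e <= b for a, b in segs):
            return GenomicLocation("exon", gene_ids)
    # 2) splice-junction straddler within a transcript that contains the SSR
    for segs in segsets:
        tstart, tend = segs[0][0], segs[-1][1]
        if not (tstart <= s and e <= tend):
            continue
        introns = [(b1, a2) for (_, b1), (a2, _) in zip(segs, segs[1:])]
        hits_exon = any(a < e and s < b for a, b in segs)
        hits_intron = any(a < e and s < b for a, b in introns)
        if hits_exon and hits_intron:
            return GenomicLocation("exon_intron", gene_ids)
    # 3) fully inside an intron
    for segs in segsets:
        introns = [(b1, a2) for (_, b1), (a2, _) in zip(segs, segs[1:])]
        if any(a <= s and e <= b for a, b in introns):
            return GenomicLocation("intron", gene_ids)
    # inside the gene span but in none of the above (e.g. outside every
    # transcript, or in UTR sequence under cds mode)
    return GenomicLocation("intergenic", gene_ids, boundary_flag=False)


@dataclass(frozen=True)
class LinkageAssignment:
    lg_label: str

    @property
    def placed(self) -> bool:
        return self.lg_label != UNPLACED


def assign_linkage_group(scaffold: str, lg_map: Dict[str, str]) -> LinkageAssignment:
    """Look a scaffold up in the scaffold->LG map; unmapped scaffolds are 'Un'."""
    return LinkageAssignment(lg_map.get(scaffold, UNPLACED))


def genes_with_ssr_fraction(atlas_records: Sequence, annotation: AnnotationSet
                            ) -> Tuple[int, int, int]:
    """(genes with >=1 genic SSR, total genes, percentage to nearest integer)."""
    if len(annotation) == 0:
        raise ValueError("annotation contains no genes")
    with_ssr = set()
    for rec in atlas_records:
        if rec.location in ("exon", "exon_intron", "intron"):
            with_ssr.update(rec.gene_ids)
    n, total = len(with_ssr), len(annotation)
    return n, total, int(round_half_up(100.0 * n / total, 0))
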