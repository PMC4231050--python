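"""Readers and writers for the pipeline's on-disk formats.

Owns every coordinate-convention conversion: internally all intervals are
0-based half-open; everything printed to disk (atlas TSV, repeat TSV) is
1-based inclusive, GFF/GenBank style.  GFF3 input (1-based inclusive) is
converted on read.

FASTA is read with Bio.SeqIO; sequences are uppercased and the lowercase
(soft-masked) positions are recorded on a parallel track.  GFF3 is parsed
with gffutils into an in-memory database and reduced to plain
:class:`GeneModel` objects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]  # 0-based half-open


# ---------------------------------------------------------------------------
# sequence records
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One scaffold/contig: uppercase sequence plus soft-mask positions."""

    id: str
    sequence: str
    softmask: frozenset = field(default_factory=frozenset, repr=False)

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> List[SequenceRecord]:
    """Read a multi-record FASTA.

    Sequences are uppercased; positions that were lowercase in the file are
    recorded in ``softmask``.  Raises on a missing/empty file or duplicate
    record ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        mask = frozenset(i for i, c in enumerate(raw) if c.islower())
        records.append(SequenceRecord(rec.id, raw.upper(), mask))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene span with per-transcript exon (and optional CDS) intervals."""

    gene_id: str
    scaffold: str
    strand: str
    start: int  # 0-based half-open span
    end: int
    transcripts: List[List[Interval]] = field(default_factory=list)
    cds: List[List[Interval]] = field(default_factory=list)
    annotation_text: str = ""
    go_terms: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for exons in self.transcripts:
            exons.sort()
            for (a, b), (c, d) in zip(exons, exons[1:]):
                if c < b:
                    raise ValueError(
                        f"overlapping exons in gene {self.gene_id}: "
                        f"({a},{b}) and ({c},{d})")
            for a, b in exons:
                if a < self.start or b > self.end:
                    raise ValueError(
                        f"exon ({a},{b}) outside gene span of {self.gene_id}")


class AnnotationSet:
    """All gene models of a genome, indexed per scaffold for interval lookup."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes: Dict[str, GeneModel] = {}
        self._trees: Dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id: {g.gene_id}")
            self.genes[g.gene_id] = g
            self._trees.setdefault(g.scaffold, IntervalTree()).addi(
                g.start, g.end, g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, scaffold: str, start: int, end: int) -> List[GeneModel]:
        """Genes whose span overlaps [start, end), sorted by coordinate."""
        tree = self._trees.get(scaffold)
        if tree is None:
            return []
        ids = [iv.data for iv in tree.overlap(start, end)]
        return sorted((self.genes[i] for i in ids),
                      key=lambda g: (g.start, g.end, g.gene_id))


def read_gff3(path, annotations: Optional[Dict[str, Tuple[str, str]]] = None
              ) -> AnnotationSet:
    """Parse a GFF3 file with gene/mRNA/exon (CDS optional) features.

    1-based inclusive GFF coordinates become 0-based half-open.  Exons whose
    Parent cannot be resolved are skipped with a warning; a line with the
    wrong column count raises with its line number.  ``annotations``
    optionally maps gene_id -> (annotation_text, go_terms).
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns")
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            sort_attribute_values=True)
    known_parents = {f.id for f in db.all_features()
                     if f.featuretype in {"gene", "mRNA", "transcript"}}
    for feat in db.features_of_type(("exon", "CDS")):
        parents = feat.attributes.get("Parent", [])
        if parents and not any(p in known_parents for p in parents):
            warnings.warn(
                f"{feat.featuretype} at {feat.seqid}:{feat.start}-{feat.end} "
                f"has unresolvable Parent {parents}; skipped")

    annotations = annotations or {}
    genes: List[GeneModel] = []
    for gf in db.features_of_type("gene"):
        transcripts: List[List[Interval]] = []
        cds_sets: List[List[Interval]] = []
        mrnas = list(db.children(gf, featuretype=("mRNA", "transcript"), level=1))
        if mrnas:
            for mrna in mrnas:
                exons = sorted((e.start - 1, e.end)
                               for e in db.children(mrna, featuretype="exon"))
                cds = sorted((c.start - 1, c.end)
                             for c in db.children(mrna, featuretype="CDS"))
                if exons:
                    transcripts.append(exons)
                cds_sets.append(cds)
        else:  # exons directly under the gene: treat as a single transcript
            exons = sorted((e.start - 1, e.end)
                           for e in db.children(gf, featuretype="exon"))
            if exons:
                transcripts.append(exons)
            cds_sets.append(sorted((c.start - 1, c.end)
                                   for c in db.children(gf, featuretype="CDS")))
        ann, go = annotations.get(gf.id, ("", ""))
        genes.append(GeneModel(
            gene_id=gf.id, scaffold=gf.seqid, strand=gf.strand,
            start=gf.start - 1, end=gf.end,
            transcripts=transcripts, cds=cds_sets,
            annotation_text=ann, go_terms=go))
    return AnnotationSet(genes)


def write_gff3(annotation: AnnotationSet, path) -> None:
    """Write gene/mRNA/exon features, 1-based inclusive (identity round-trip)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes.values(),
                        key=lambda g: (g.scaffold, g.start)):
            fh.write("\t".join([g.scaffold, "ssratlas", "gene",
                                str(g.start + 1), str(g.end), ".", g.strand,
                                ".", f"ID={g.gene_id}"]) + "\n")
            for t, exons in enumerate(g.transcripts):
                tid = f"{g.gene_id}.t{t + 1}"
                tstart = min(a for a, _ in exons)
                tend = max(b for _, b in exons)
                fh.write("\t".join([g.scaffold, "ssratlas", "mRNA",
                                    str(tstart + 1), str(tend), ".", g.strand,
                                    ".", f"ID={tid};Parent={g.gene_id}"]) + "\n")
                for a, b in exons:
                    fh.write("\t".join([g.scaffold, "ssratlas", "exon",
                                        str(a + 1), str(b), ".", g.strand, ".",
                                        f"Parent={tid}"]) + "\n")
                if t < len(g.cds):
                    for a, b in g.cds[t]:
                        fh.write("\t".join([g.scaffold, "ssratlas", "CDS",
                                            str(a + 1), str(b), ".", g.strand,
                                            "0", f"Parent={tid}"]) + "\n")


# ---------------------------------------------------------------------------
# linkage-group map, hit tables, gene annotations
# ---------------------------------------------------------------------------

def read_lg_map(path) -> Dict[str, str]:
    """Two-column TSV ``scaffold<TAB>LG_label``; conflicting duplicates raise."""
    df = pd.read_csv(path, sep="\t", header=None, names=["scaffold", "lg"],
                     dtype=str, comment="#")
    mapping: Dict[str, str] = {}
    for scaffold, lg in zip(df["scaffold"], df["lg"]):
        if scaffold in mapping and mapping[scaffold] != lg:
            raise ValueError(
                f"scaffold {scaffold!r} mapped to both {mapping[scaffold]!r} "
                f"and {lg!r}")
        mapping[scaffold] = lg
    return mapping


HIT_TABLE_COLUMNS = ["qseqid", "sseqid", "evalue", "ppos", "length",
                     "qlen", "slen"]


def read_hit_table(path) -> pd.DataFrame:
    """Extended tabular protein-alignment hits.

    Tab-separated, no header: query id, subject id, E-value, percent
    positives, alignment length, query length, subject length.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_TABLE_COLUMNS,
                     comment="#")
    return df


def read_gene_annotations(path) -> Dict[str, Tuple[str, str]]:
    """TSV gene_id<TAB>annotation_text<TAB>go_terms (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     names=["gene_id", "annotation", "go"], comment="#")
    df = df.fillna("")
    if list(df.iloc[0]) == ["gene_id", "annotation", "go"]:
        df = df.iloc[1:]
    return {r.gene_id: (r.annotation, r.go) for r in df.itertuples()}


# ---------------------------------------------------------------------------
# atlas TSV
# ---------------------------------------------------------------------------

ATLAS_COLUMNS = ["ssr_id", "scaffold", "start", "end", "motif",
                 "canonical_class", "period", "size", "exponent",
                 "length_class", "location", "gene_id", "annotation", "GO",
                 "linkage_group", "fwd_primer", "rev_primer", "product_size",
                 "Tm_fwd", "Tm_rev"]


def write_atlas(records, path) -> None:
    """Write atlas rows as TSV; coordinates printed 1-based inclusive.

    ``records`` are :class:`~ssratlas.atlas.AtlasRecord`; an empty list
    produces a header-only file.
    """
    rows = [r.to_row() for r in records]
    df = pd.DataFrame(rows, columns=ATLAS_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_atlas(path) -> pd.DataFrame:
    """Read an atlas TSV back; string columns stay strings, '' for missing."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != ATLAS_COLUMNS:
        raise ValueError(f"unexpected atlas columns in {path}")
    return df


def write_repeat_tsv(hits, path) -> None:
    """Dump repeat hits: scaffold, 1-based start, end, period, motif, size, exponent."""
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tperiod\tmotif\tsize\texponent\n")
        for h in hits:
            fh.write(f"{h.scaffold}\t{h.start + 1}\t{h.end}\t{h.period}\t"
                     f"{h.motif}\t{h.size}\t{h.exponent:g}\n")


def read_repeat_tsv(path):
    """Read a repeat TSV back into RepeatHit objects (internal coordinates)."""
    from .repeat_finder import RepeatHit

    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str})
    return [RepeatHit(r.scaffold, int(r.start) - 1, int(r.end),
                      int(r.period), r.motif) for r in df.itertuples()]
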