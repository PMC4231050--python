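"""Synthetic toy genomes with planted SSRs and known ground truth.

The generator builds scaffold backgrounds that are certified repeat-free
(rejection-resampled until the brute-force oracle scanner reports zero
hits), splices in declared SSR arrays, and repairs insertion junctions so a
plant never extends into a longer run than declared.  Gene models, a
scaffold-to-linkage-group map and a truth table accompany the sequence, so
every pipeline stage can be validated end to end: the scanner must recover
exactly the planted arrays, the context classifier must reproduce the
declared locations, and the LG assignment must match the map.

Backgrounds are i.i.d. bases at a configurable GC fraction (default 0.35,
a typical plant nuclear genome); no other compositional structure (isochores,
transposon landscapes) is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .atlas import ssr_id_of
from .genome_context import CATEGORIES, UNPLACED
from .io_formats import (AnnotationSet, GeneModel, SequenceRecord,
                         write_fasta, write_gff3)
from .repeat_finder import (RepeatHit, ScanParams, find_repeats,
                            oracle_find_repeats, primitive_period)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Plant:
    """One declared SSR insertion; ``location`` is caller-declared truth."""

    scaffold: str
    pos: int
    motif: str
    size: int
    location: str

    def __post_init__(self) -> None:
        if self.size < 12:
            raise ValueError(f"planted size must be >= 12, got {self.size}")
        from .motif_algebra import is_power
        if is_power(self.motif):
            raise ValueError(f"plant motif {self.motif!r} is not primitive")
        if self.location not in CATEGORIES:
            raise ValueError(f"unknown truth location {self.location!r}")

    @property
    def end(self) -> int:
        return self.pos + self.size

    @property
    def sequence(self) -> str:
        reps = -(-self.size // len(self.motif))
        return (self.motif * reps)[:self.size]

    @property
    def period(self) -> int:
        return len(self.motif)


@dataclass
class SimSpec:
    """Everything needed to build a deterministic toy genome."""

    scaffolds: Dict[str, int]
    plants: List[Plant]
    genes: List[GeneModel] = field(default_factory=list)
    lg_map: Dict[str, str] = field(default_factory=dict)
    gc: float = 0.35
    seed: int = 0
    scan_params: ScanParams = field(default_factory=ScanParams)

    def validate(self) -> None:
        by_scaffold: Dict[str, List[Plant]] = {}
        for p in self.plants:
            if p.scaffold not in self.scaffolds:
                raise ValueError(f"plant on unknown scaffold {p.scaffold!r}")
            if p.end > self.scaffolds[p.scaffold]:
                raise ValueError(f"plant at {p.pos} exceeds scaffold length")
            by_scaffold.setdefault(p.scaffold, []).append(p)
        gap = self.scan_params.max_period
        for plants in by_scaffold.values():
            plants.sort(key=lambda p: p.pos)
            for a, b in zip(plants, plants[1:]):
                if b.pos < a.end + gap:
                    raise ValueError(
                        f"plants at {a.pos} and {b.pos} overlap or are closer "
                        f"than {gap} bases")
        for p in self.plants:
            own = find_repeats(p.sequence, self.scan_params)
            if [(h.start, h.end, h.period) for h in own] != \
                    [(0, p.size, p.period)]:
                raise ValueError(
                    f"plant {p.motif}x{p.size} is not a clean single run")


@dataclass(frozen=True)
class TruthRow:
    ssr_id: str
    scaffold: str
    start: int
    end: int
    period: int
    motif: str
    size: int
    exponent: float
    location: str
    lg: str


@dataclass
class SimResult:
    records: List[SequenceRecord]
    annotation: AnnotationSet
    lg_map: Dict[str, str]
    truth: List[TruthRow]


def make_background(length: int, gc: float, seed) -> str:
    """Repeat-free i.i.d. background at the requested GC fraction.

    Deterministic given the seed; resamples any region where the scanner
    finds a qualifying run until the brute-force oracle certifies zero hits.
    Pathological GC (0 or 1) cannot be repeat-free and raises.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(_BASES, size=length, p=probs)
    params = ScanParams()
    for _ in range(200):
        seq = "".join(arr)
        hits = find_repeats(seq, params)
        if not hits:
            break
        for h in hits:
            arr[h.start:h.end] = rng.choice(_BASES, size=h.size, p=probs)
    else:  # pragma: no cover - would need absurdly unlucky sampling
        raise RuntimeError("background failed to become repeat-free")
    assert not oracle_find_repeats(seq, params)
    return seq


def _repair_scaffold(arr: np.ndarray, plants: List[Plant], rng, probs,
                     params: ScanParams) -> None:
    """Resample non-plant bases until the scan reports exactly the plants."""
    expected = {(p.pos, p.end, p.period) for p in plants}
    planted_pos = np.zeros(len(arr), dtype=bool)
    for p in plants:
        planted_pos[p.pos:p.end] = True
    for _ in range(200):
        hits = find_repeats("".join(arr), params)
        bad = [h for h in hits if (h.start, h.end, h.period) not in expected]
        if not bad and {(h.start, h.end, h.period) for h in hits} == expected:
            return
        touched = False
        for h in bad:
            idx = [i for i in range(h.start, h.end) if not planted_pos[i]]
            if idx:
                arr[idx] = rng.choice(_BASES, size=len(idx), p=probs)
                touched = True
        if not touched:  # pragma: no cover
            raise RuntimeError(f"cannot repair junction near {bad[0]}")
    raise RuntimeError("junction repair did not converge")  # pragma: no cover


def simulate_genome(spec: SimSpec) -> SimResult:
    """Build the toy genome: sequences, annotation, LG map and truth table."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    probs = [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    records: List[SequenceRecord] = []
    truth: List[TruthRow] = []
    for name, length in spec.scaffolds.items():
        background = make_background(length, spec.gc, rng)
        arr = np.array(list(background))
        plants = sorted((p for p in spec.plants if p.scaffold == name),
                        key=lambda p: p.pos)
        for p in plants:
            arr[p.pos:p.end] = list(p.sequence)
        _repair_scaffold(arr, plants, rng, probs, spec.scan_params)
        records.append(SequenceRecord(name, "".join(arr)))
        lg = spec.lg_map.get(name, UNPLACED)
        for p in plants:
            hit = RepeatHit(name, p.pos, p.end, p.period, p.motif)
            truth.append(TruthRow(
                ssr_id=ssr_id_of(hit), scaffold=name, start=p.pos, end=p.end,
                period=p.period, motif=p.motif, size=p.size,
                exponent=p.size / p.period, location=p.location, lg=lg))
    return SimResult(records=records, annotation=AnnotationSet(spec.genes),
                     lg_map=dict(spec.lg_map), truth=truth)


def write_fixture(result: SimResult, outdir) -> Dict[str, Path]:
    """Write genome.fasta, annotation.gff3, lg_map.tsv and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff3": outdir / "annotation.gff3",
        "lg_map": outdir / "lg_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(result.records, paths["fasta"])
    write_gff3(result.annotation, paths["gff3"])
    with open(paths["lg_map"], "w") as fh:
        for scaffold, lg in sorted(result.lg_map.items()):
            fh.write(f"{scaffold}\t{lg}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("ssr_id\tscaffold\tstart\tend\tperiod\tmotif\tsize\t"
                 "exponent\tlocation\tlg\n")
        for t in result.truth:
            fh.write(f"{t.ssr_id}\t{t.scaffold}\t{t.start + 1}\t{t.end}\t"
                     f"{t.period}\t{t.motif}\t{t.size}\t{t.exponent:g}\t"
                     f"{t.location}\t{t.lg}\n")
    return paths


def default_fixture(seed: int = 0) -> SimSpec:
    """The standard 20-plant, ~100 kb, 3-scaffold validation genome.

    Plants cover periods 2-6, fractional exponents, and all four genomic
    contexts; scf03 is deliberately absent from the LG map (unplaced).
    """
    genes = [
        GeneModel("g1", "scf01", "+", 5000, 9000,
                  transcripts=[[(5000, 6200), (6800, 8000), (8600, 9000)]]),
        GeneModel("g2", "scf01", "-", 15000, 20000,
                  transcripts=[[(15000, 16000), (17000, 18500), (19000, 20000)]]),
        GeneModel("g3", "scf01", "+", 30000, 33000,
                  transcripts=[[(30000, 33000)]]),
        GeneModel("g4", "scf02", "-", 4000, 10000,
                  transcripts=[[(4000, 5000), (6000, 7000), (8000, 10000)]]),
        GeneModel("g5", "scf02", "+", 20000, 26000,
                  transcripts=[[(20000, 21000), (23000, 26000)]]),
        GeneModel("g6", "scf03", "+", 10000, 14000,
                  transcripts=[[(10000, 11000), (13000, 14000)]]),
    ]
    plants = [
        Plant("scf01", 5500, "AT", 16, "exon"),
        Plant("scf01", 6190, "AAG", 20, "exon_intron"),
        Plant("scf01", 6400, "AC", 14, "intron"),
        Plant("scf01", 2000, "AGAT", 24, "intergenic"),
        Plant("scf01", 7000, "AAT", 15, "exon"),
        Plant("scf01", 8200, "AATG", 16, "intron"),
        Plant("scf01", 12000, "AAAAT", 25, "intergenic"),
        Plant("scf01", 15500, "AG", 12, "exon"),
        Plant("scf01", 16400, "ACG", 18, "intron"),
        Plant("scf01", 18990, "CT", 16, "exon_intron"),
        Plant("scf01", 31000, "AAC", 21, "exon"),
        Plant("scf01", 36000, "AAGT", 20, "intergenic"),
        Plant("scf02", 4500, "CTT", 18, "exon"),
        Plant("scf02", 5500, "TA", 14, "intron"),
        Plant("scf02", 8800, "CCG", 12, "exon"),
        Plant("scf02", 15000, "ATT", 27, "intergenic"),
        Plant("scf02", 20500, "GATA", 28, "exon"),
        Plant("scf02", 22000, "AATT", 16, "intron"),
        Plant("scf03", 10500, "AAAAG", 30, "exon"),
        Plant("scf03", 18000, "AACGTC", 24, "intergenic"),
    ]
    return SimSpec(
        scaffolds={"scf01": 40000, "scf02": 35000, "scf03": 25000},
        plants=plants, genes=genes,
        lg_map={"scf01": "LG1", "scf02": "LG5"},
        gc=0.35, seed=seed)
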