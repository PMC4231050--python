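"""Stringent PCR primer design around SSR arrays.

For each SSR the genomic template is the array plus up to 250 bp of flank on
either side.  Low-complexity stretches are masked with a windowed triplet
(DUST-style) score.  Candidate primers are enumerated exhaustively in the
flanks and must clear every gate:

* length 18-25 nt (optimum 20);
* melting temperature 57-63 °C (optimum 60), nearest-neighbor model;
* GC content 20-60 %;
* no N and no more than half of the bases masked;
* neither of the two 3'-terminal bases masked (soft-mask 3' rule);
* no qualifying SSR run inside the primer itself (the mispriming rule:
  primers must not sit in repetitive sequence);
* no self-complementary hairpin stem longer than 6 bp with a loop of >= 3
  (4 points per stem pair against a ceiling of 24).

Pairs must bracket the SSR with a product of 250-350 bp (optimum 300) and a
Tm difference of at most 3 °C; the pair minimising
``|len-20| + |Tm-60|`` (both primers) ``+ |product-300|/10`` wins, ties going
to the leftmost forward primer and then the shortest product.

The melting temperature uses the unified nearest-neighbor ΔH/ΔS parameter
set with the entropy salt correction (50 mM monovalent cation, 25 nM each
strand).  This module is a self-contained approximation of a Primer3-style
configuration, not a Primer3 reimplementation: hairpins are scored by stem
length, not full secondary-structure thermodynamics.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._util import revcomp
from .repeat_finder import RepeatHit, ScanParams, find_repeats

# unified nearest-neighbor parameters, kcal/mol and cal/(mol*K)
_NN_STACKS = {
    "AA/TT": (-7.9, -22.2), "AT/TA": (-7.2, -20.4), "TA/AT": (-7.2, -21.3),
    "CA/GT": (-8.5, -22.7), "GT/CA": (-8.4, -22.4), "CT/GA": (-7.8, -21.0),
    "GA/CT": (-8.2, -22.2), "CG/GC": (-10.6, -27.2), "GC/CG": (-9.8, -24.4),
    "GG/CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_SYM = (0.0, -1.4)
_R = 1.987  # gas constant, cal/(mol*K)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _stack_table() -> Dict[str, Tuple[float, float]]:
    table = {}
    for a in "ACGT":
        for b in "ACGT":
            d = a + b
            key = d + "/" + _COMP[a] + _COMP[b]
            table[d] = _NN_STACKS.get(key) or _NN_STACKS[key[::-1]]
    return table


_STACKS_BY_DINUC = _stack_table()


@dataclass(frozen=True)
class PrimerParams:
    """All primer-design constraints (module docstring gives the rationale)."""

    flank: int = 250
    len_min: int = 18
    len_opt: int = 20
    len_max: int = 25
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    product_min: int = 250
    product_opt: int = 300
    product_max: int = 350
    gc_min: float = 20.0
    gc_max: float = 60.0
    hairpin_score_max: int = 24  # 4 points per stem pair -> stems of <= 6 bp
    mask_3prime_window: int = 2
    max_tm_diff: float = 3.0
    max_masked_fraction: float = 0.5
    na_mM: float = 50.0
    dnac1_nM: float = 25.0
    dnac2_nM: float = 25.0

    def __post_init__(self) -> None:
        for lo, opt, hi in ((self.len_min, self.len_opt, self.len_max),
                            (self.tm_min, self.tm_opt, self.tm_max),
                            (self.product_min, self.product_opt, self.product_max)):
            if not lo <= opt <= hi:
                raise ValueError("min <= opt <= max violated in PrimerParams")

    @property
    def max_hairpin_stem(self) -> int:
        return self.hairpin_score_max // 4


@dataclass
class Template:
    """SSR plus flanking sequence cut from a scaffold."""

    scaffold: str
    sequence: str
    ssr_start: int  # template coordinates, 0-based half-open
    ssr_end: int
    genome_start: int  # genome coordinate of template position 0
    left_clipped: bool = False
    right_clipped: bool = False
    masked: List[Tuple[int, int]] = field(default_factory=list)

    def masked_array(self) -> np.ndarray:
        arr = np.zeros(len(self.sequence), dtype=bool)
        for a, b in self.masked:
            arr[a:b] = True
        return arr


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair; positions are template coordinates of binding sites."""

    forward_seq: str
    reverse_seq: str
    forward_start: int
    forward_len: int
    reverse_start: int  # template start of the reverse binding site
    reverse_len: int
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    product_size: int
    penalty: float
    template_genome_start: int = 0

    is_pair = True

    @property
    def forward_genome_start(self) -> int:
        return self.template_genome_start + self.forward_start

    @property
    def reverse_genome_start(self) -> int:
        return self.template_genome_start + self.reverse_start


@dataclass(frozen=True)
class DesignFailure:
    """No acceptable pair; ``reason`` aggregates the gate failures seen."""

    reason: str
    detail: Tuple[Tuple[str, int], ...] = ()

    is_pair = False


def extract_template(record, hit: RepeatHit, flank: int = 250,
                     mask: bool = True) -> Template:
    """Cut SSR +/- ``flank`` bases from the scaffold, clipping at the ends.

    When ``mask`` is true the low-complexity intervals are computed with
    :func:`dust_mask` immediately.
    """
    start = max(0, hit.start - flank)
    end = min(record.length, hit.end + flank)
    seq = record.sequence[start:end]
    tpl = Template(scaffold=hit.scaffold, sequence=seq,
                   ssr_start=hit.start - start, ssr_end=hit.end - start,
                   genome_start=start,
                   left_clipped=start > hit.start - flank or hit.start < flank,
                   right_clipped=hit.end + flank > record.length)
    if mask:
        tpl.masked = dust_mask(seq)
    return tpl


def dust_mask(sequence: str, window: int = 64, threshold: float = 2.0
              ) -> List[Tuple[int, int]]:
    """Windowed triplet low-complexity score; returns merged masked intervals.

    For every window the score is sum_t c_t(c_t - 1)/2 / (w - 3) over the
    counts c_t of each ACGT 3-mer; every position of a window scoring above
    ``threshold`` is masked.
    """
    n = len(sequence)
    if n < 4:
        return []
    w = min(window, n)
    mask = np.zeros(n, dtype=bool)
    counts: Dict[str, int] = {}
    pair_sum = 0  # sum over triplets of c*(c-1)/2

    def _valid(t: str) -> bool:
        return all(c in "ACGT" for c in t)

    for i in range(w - 2):
        t = sequence[i:i + 3]
        if _valid(t):
            c = counts.get(t, 0)
            pair_sum += c
            counts[t] = c + 1
    denom = w - 3
    for i in range(n - w + 1):
        if denom > 0 and pair_sum / denom > threshold:
            mask[i:i + w] = True
        if i < n - w:  # slide: drop triplet at i, add triplet at i+w-2
            t_out = sequence[i:i + 3]
            if _valid(t_out):
                counts[t_out] -= 1
                pair_sum -= counts[t_out]
            t_in = sequence[i + w - 2:i + w + 1]
            if _valid(t_in):
                c = counts.get(t_in, 0)
                pair_sum += c
                counts[t_in] = c + 1
    # boolean array -> merged intervals
    out: List[Tuple[int, int]] = []
    idx = np.flatnonzero(mask)
    if len(idx):
        start = prev = int(idx[0])
        for j in idx[1:]:
            if j != prev + 1:
                out.append((start, prev + 1))
                start = int(j)
            prev = int(j)
        out.append((start, prev + 1))
    return out


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------

def _tm_from_sums(dh: float, ds: float, seq_len: int, selfcomp: bool,
                  na_mM: float, dnac1_nM: float, dnac2_nM: float) -> float:
    if selfcomp:
        dh += _SYM[0]
        ds += _SYM[1]
        k = dnac1_nM * 1e-9
    else:
        k = (dnac1_nM - dnac2_nM / 2.0) * 1e-9
    ds += 0.368 * (seq_len - 1) * math.log(na_mM / 1000.0)
    return (1000.0 * dh) / (ds + _R * math.log(k)) - 273.15


def melting_temp(primer: str, na_mM: float = 50.0, dnac1_nM: float = 25.0,
                 dnac2_nM: float = 25.0) -> float:
    """Nearest-neighbor duplex melting temperature in °C.

    Unified ΔH/ΔS stack parameters with terminal A·T / G·C initiation terms,
    symmetry correction for self-complementary primers, and the entropy salt
    correction 0.368·(N-1)·ln[monovalent].  Requires an ACGT primer of at
    least 8 bases.
    """
    if len(primer) < 8:
        raise ValueError("primer too short for a meaningful NN Tm (< 8 nt)")
    if any(c not in "ACGT" for c in primer):
        raise ValueError(f"ambiguity codes not allowed in Tm: {primer!r}")
    dh = ds = 0.0
    for i in range(len(primer) - 1):
        h, s = _STACKS_BY_DINUC[primer[i:i + 2]]
        dh += h
        ds += s
    for base in (primer[0], primer[-1]):
        inc = _INIT_AT if base in "AT" else _INIT_GC
        dh += inc[0]
        ds += inc[1]
    return _tm_from_sums(dh, ds, len(primer), primer == revcomp(primer),
                         na_mM, dnac1_nM, dnac2_nM)


def gc_percent(seq: str) -> float:
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


# ---------------------------------------------------------------------------
# hairpins and repetitive content
# ---------------------------------------------------------------------------

def max_hairpin_stem(seq: str, min_loop: int = 3) -> int:
    """Longest self-complementary stem closable with a loop of >= min_loop."""
    n = len(seq)
    best = 0
    for a in range(n):
        for b in range(n - 1, a + min_loop, -1):
            L = 0
            while (a + L < b - L and b - a - 2 * (L + 1) + 1 >= min_loop
                   and seq[a + L] == _COMP.get(seq[b - L], "?")):
                L += 1
            if L > best:
                best = L
    return best


def has_hairpin(seq: str, max_stem: int = 6, min_loop: int = 3) -> bool:
    """True iff a stem of ``max_stem + 1`` pairs (or longer) can form."""
    L = max_stem + 1
    n = len(seq)
    if n < 2 * L + min_loop:
        return False
    positions: Dict[str, List[int]] = {}
    for i in range(n - L + 1):
        positions.setdefault(seq[i:i + L], []).append(i)
    for a in range(n - L + 1):
        rc = revcomp(seq[a:a + L])
        for b in positions.get(rc, ()):
            if b >= a + L + min_loop:
                return True
    return False


def contains_ssr_run(seq: str, scan_params: Optional[ScanParams] = None) -> bool:
    """Mispriming gate: does the primer itself contain a qualifying SSR run?

    Equivalent to running the repeat scanner on the candidate; a cheap
    periodicity pre-scan avoids the full call for the common clean case.
    """
    scan_params = scan_params or ScanParams()
    n = len(seq)
    hitp = False
    for p in range(scan_params.min_period, scan_params.max_period + 1):
        run = 0
        for k in range(n - p):
            if seq[k] == seq[k + p]:
                run += 1
                if run + p >= scan_params.min_size:
                    hitp = True
                    break
            else:
                run = 0
        if hitp:
            break
    if not hitp:
        return False
    return bool(find_repeats(seq, scan_params))


# ---------------------------------------------------------------------------
# candidate evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    """A primer candidate: template binding site plus strand."""

    start: int
    length: int
    strand: str  # '+' forward, '-' reverse

    @property
    def end(self) -> int:
        return self.start + self.length


def evaluate_primer(candidate: Candidate, template: Template,
                    params: Optional[PrimerParams] = None,
                    scan_params: Optional[ScanParams] = None
                    ) -> Tuple[bool, List[str]]:
    """Run every gate on one candidate; returns (passed, failure reasons)."""
    params = params or PrimerParams()
    reasons: List[str] = []
    sub = template.sequence[candidate.start:candidate.end]
    seq = sub if candidate.strand == "+" else revcomp(sub)
    masked = template.masked_array()

    if not params.len_min <= candidate.length <= params.len_max:
        reasons.append("length")
    if any(c not in "ACGT" for c in sub):
        reasons.append("contains_n")
    else:
        gc = gc_percent(seq)
        if not params.gc_min <= gc <= params.gc_max:
            reasons.append("gc")
        if candidate.length >= 8:
            tm = melting_temp(seq, params.na_mM, params.dnac1_nM, params.dnac2_nM)
            if not params.tm_min <= tm <= params.tm_max:
                reasons.append("tm")
        if contains_ssr_run(seq, scan_params):
            reasons.append("ssr_content")
        if has_hairpin(seq, params.max_hairpin_stem):
            reasons.append("hairpin")
    if candidate.strand == "+":
        three_prime = range(candidate.end - params.mask_3prime_window,
                            candidate.end)
    else:
        three_prime = range(candidate.start,
                            candidate.start + params.mask_3prime_window)
    if any(masked[i] for i in three_prime if 0 <= i < len(masked)):
        reasons.append("masked_3prime")
    if masked[candidate.start:candidate.end].mean() > params.max_masked_fraction:
        reasons.append("low_complexity")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# pair search
# ---------------------------------------------------------------------------

def _prefix_arrays(seq: str):
    """Prefix sums enabling O(1) GC / N / stack-energy lookups per substring."""
    n = len(seq)
    gc = np.zeros(n + 1, dtype=np.int32)
    nn = np.zeros(n + 1, dtype=np.int32)
    dh = np.zeros(n, dtype=np.float64)  # dh[i] = sum of stacks before pos i
    ds = np.zeros(n, dtype=np.float64)
    for i, c in enumerate(seq):
        gc[i + 1] = gc[i] + (c in "GC")
        nn[i + 1] = nn[i] + (c not in "ACGT")
    for i in range(n - 1):
        pair = _STACKS_BY_DINUC.get(seq[i:i + 2])
        if pair is None:
            pair = (math.nan, math.nan)
        dh[i + 1] = dh[i] + pair[0]
        ds[i + 1] = ds[i] + pair[1]
    return gc, nn, dh, ds


def _enumerate_side(template: Template, params: PrimerParams,
                    scan_params: Optional[ScanParams],
                    lo: int, hi: int, strand: str,
                    prefix, masked, mask_pref, fail: Dict[str, int]):
    """All passing candidates with start/end inside [lo, hi)."""
    seq = template.sequence
    gc_pref, n_pref, dh_pref, ds_pref = prefix
    out = []
    for length in range(params.len_min, params.len_max + 1):
        for start in range(lo, hi - length + 1):
            end = start + length
            if n_pref[end] - n_pref[start] > 0:
                fail["contains_n"] = fail.get("contains_n", 0) + 1
                continue
            gc = 100.0 * (gc_pref[end] - gc_pref[start]) / length
            if not params.gc_min <= gc <= params.gc_max:
                fail["gc"] = fail.get("gc", 0) + 1
                continue
            if mask_pref[end] - mask_pref[start] > params.max_masked_fraction * length:
                fail["low_complexity"] = fail.get("low_complexity", 0) + 1
                continue
            if strand == "+":
                tp = (end - 2, end - 1)
            else:
                tp = (start, start + 1)
            if masked[tp[0]] or masked[tp[1]]:
                fail["masked_3prime"] = fail.get("masked_3prime", 0) + 1
                continue
            sub = seq[start:end]
            dh = dh_pref[end - 1] - dh_pref[start]
            ds = ds_pref[end - 1] - ds_pref[start]
            for base in (sub[0], sub[-1]):
                inc = _INIT_AT if base in "AT" else _INIT_GC
                dh += inc[0]
                ds += inc[1]
            tm = _tm_from_sums(dh, ds, length, sub == revcomp(sub),
                               params.na_mM, params.dnac1_nM, params.dnac2_nM)
            if not params.tm_min <= tm <= params.tm_max:
                fail["tm"] = fail.get("tm", 0) + 1
                continue
            if contains_ssr_run(sub, scan_params):
                fail["ssr_content"] = fail.get("ssr_content", 0) + 1
                continue
            if has_hairpin(sub, params.max_hairpin_stem):
                fail["hairpin"] = fail.get("hairpin", 0) + 1
                continue
            out.append((start, length, tm, gc))
    return out


def design_pair(template: Template, params: Optional[PrimerParams] = None,
                scan_params: Optional[ScanParams] = None):
    """Best primer pair for one template, or a DesignFailure.

    Deterministic: exhaustive enumeration, total ordering of the penalty key.
    The forward primer lies entirely upstream of the SSR and the reverse
    primer entirely downstream; the product always contains the SSR.
    """
    params = params or PrimerParams()
    seq = template.sequence
    n = len(seq)
    masked = template.masked_array()
    mask_pref = np.zeros(n + 1, dtype=np.int64)
    mask_pref[1:] = np.cumsum(masked)
    prefix = _prefix_arrays(seq)
    fail_f: Dict[str, int] = {}
    fail_r: Dict[str, int] = {}

    fwd = _enumerate_side(template, params, scan_params, 0, template.ssr_start,
                          "+", prefix, masked, mask_pref, fail_f)
    rev = _enumerate_side(template, params, scan_params, template.ssr_end, n,
                          "-", prefix, masked, mask_pref, fail_r)
    detail = tuple(sorted({**{f"fwd_{k}": v for k, v in fail_f.items()},
                           **{f"rev_{k}": v for k, v in fail_r.items()}}.items()))
    if not fwd or not rev:
        side = "no_forward_candidates" if not fwd else "no_reverse_candidates"
        return DesignFailure(reason=side, detail=detail)

    rev_sorted = sorted(rev, key=lambda r: r[0] + r[1])  # by binding-site end
    rev_ends = [r[0] + r[1] for r in rev_sorted]
    best = None
    best_key = None
    for fstart, flen, ftm, fgc in sorted(fwd):
        pf = abs(flen - params.len_opt) + abs(ftm - params.tm_opt)
        lo = bisect_left(rev_ends, fstart + params.product_min)
        hi = bisect_right(rev_ends, fstart + params.product_max)
        for ri in range(lo, hi):
            rstart, rlen, rtm, rgc = rev_sorted[ri]
            if abs(ftm - rtm) > params.max_tm_diff:
                continue
            product = rev_ends[ri] - fstart
            penalty = (pf + abs(rlen - params.len_opt) + abs(rtm - params.tm_opt)
                       + abs(product - params.product_opt) / 10.0)
            key = (penalty, fstart, product, flen, rlen, rstart)
            if best_key is None or key < best_key:
                best_key = key
                best = (fstart, flen, ftm, fgc, rstart, rlen, rtm, rgc, product,
                        penalty)
    if best is None:
        return DesignFailure(reason="no_compatible_pair", detail=detail)
    fstart, flen, ftm, fgc, rstart, rlen, rtm, rgc, product, penalty = best
    pair = PrimerPair(
        forward_seq=seq[fstart:fstart + flen],
        reverse_seq=revcomp(seq[rstart:rstart + rlen]),
        forward_start=fstart, forward_len=flen,
        reverse_start=rstart, reverse_len=rlen,
        tm_forward=ftm, tm_reverse=rtm, gc_forward=fgc, gc_reverse=rgc,
        product_size=product, penalty=penalty,
        template_genome_start=template.genome_start)
    # re-verify every gate on the winning pair
    ok_f, why_f = evaluate_primer(Candidate(fstart, flen, "+"), template,
                                  params, scan_params)
    ok_r, why_r = evaluate_primer(Candidate(rstart, rlen, "-"), template,
                                  params, scan_params)
    assert ok_f and ok_r, f"winning pair fails re-check: {why_f} {why_r}"
    assert pair.forward_start + pair.forward_len <= template.ssr_start
    assert pair.reverse_start >= template.ssr_end
    return pair


def design_primers_for_hits(records: Sequence, hits: Sequence[RepeatHit],
                            params: Optional[PrimerParams] = None,
                            scan_params: Optional[ScanParams] = None
                            ) -> Dict[str, object]:
    """Design one pair per hit; returns {ssr_id: PrimerPair | DesignFailure}."""
    from .atlas import ssr_id_of

    params = params or PrimerParams()
    by_id = {r.id: r for r in records}
    results: Dict[str, object] = {}
    for hit in hits:
        record = by_id.get(hit.scaffold)
        if record is None:
            results[ssr_id_of(hit)] = DesignFailure(reason="scaffold_missing")
            continue
        tpl = extract_template(record, hit, params.flank)
        results[ssr_id_of(hit)] = design_pair(tpl, params, scan_params)
    return results


def write_primer_tsv(results: Dict[str, object], path) -> None:
    """Primer results TSV: one row per SSR, pass or fail with reason."""
    cols = ["ssr_id", "status", "fwd_primer", "rev_primer",
            "fwd_genome_start", "rev_genome_start", "Tm_fwd", "Tm_rev",
            "GC_fwd", "GC_rev", "product_size", "penalty", "reason"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for sid in sorted(results):
            res = results[sid]
            if res.is_pair:
                fh.write("\t".join([
                    sid, "ok", res.forward_seq, res.reverse_seq,
                    str(res.forward_genome_start + 1),
                    str(res.reverse_genome_start + 1),
                    f"{res.tm_forward:.2f}", f"{res.tm_reverse:.2f}",
                    f"{res.gc_forward:.1f}", f"{res.gc_reverse:.1f}",
                    str(res.product_size), f"{res.penalty:.3f}", ""]) + "\n")
            else:
                fh.write("\t".join([sid, "no_primer", "", "", "", "", "", "",
                                    "", "", "", "", res.reason]) + "\n")
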