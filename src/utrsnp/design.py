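"""Amplicon selection and primer design for the three PCR strategies.

Three methods, differing only in where primers may sit and how long the
product must be:

* ``utr_primed`` — both primers inside the 3'UTR, product 350-450 bp
  (long enough to be fully sequenced in one direction);
* ``insilico`` — a short 130-170 bp product spanning a mined candidate
  SNP (short to limit co-amplification of introns from genomic DNA);
* ``epic`` — 200-250 bp on transcript coordinates, intended to cross an
  intron in genomic DNA (experimental here: no genomic sequence is
  modelled, only the size constraint applies).

Primer quality is scored against a 60 degC optimum melting temperature
(nearest-neighbor thermodynamics), a GC-content window, deviation of the
product length from the range midpoint, and a 3'-end complementarity
penalty as a primer-dimer proxy.  Size ranges are hard constraints.
Universal M13 sequencing tails are appended to the 5' ends of the
returned tailed primers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .core import FlicRecord, revcomp

M13_FORWARD = "TGTAAAACGACGGCCAGT"
M13_REVERSE = "CAGGAAACAGCTATGACC"

PRODUCT_SIZE_RANGES = {
    "utr_primed": (350, 450),
    "insilico": (130, 170),
    "epic": (200, 250),
}


@dataclass
class DesignParams:
    method: str = "utr_primed"
    product_size_range: Optional[tuple[int, int]] = None  # default per method
    tm_optimum: float = 60.0
    primer_len_range: tuple[int, int] = (18, 24)
    gc_range: tuple[float, float] = (0.35, 0.65)
    m13_forward_tail: str = M13_FORWARD
    m13_reverse_tail: str = M13_REVERSE
    candidate_margin: int = 20  # min distance of candidate from primer inner edges
    w_length: float = 0.05  # per-bp penalty for product length off midpoint
    w_gc: float = 50.0  # per-unit-GC penalty outside gc_range
    dimer_min_run: int = 4
    dimer_penalty: float = 5.0

    def __post_init__(self) -> None:
        if self.method not in PRODUCT_SIZE_RANGES:
            raise ValueError(f"unknown design method {self.method!r}")
        if self.product_size_range is None:
            self.product_size_range = PRODUCT_SIZE_RANGES[self.method]


@dataclass
class AmpliconDesign:
    flic_accession: str
    method: str
    product_start: int  # 0-based half-open on the transcript
    product_end: int
    forward_primer: str
    reverse_primer: str
    forward_tailed: str
    reverse_tailed: str
    product_length: int
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    score: float


@dataclass
class DesignFailure:
    flic_accession: str
    method: str
    reason: str  # "utr_too_short" | "no_valid_pair" | ...


# ---------------------------------------------------------------------------
# Melting temperature
#
# Unified nearest-neighbor parameters (dimer stacks + initiation terms),
# dH in kcal/mol, dS in cal/(mol K).  Conditions are fixed at 50 mM
# monovalent salt and 0.25 uM total oligo; the entropy salt correction is
# 0.368 * (N-1) * ln[Na+].
# ---------------------------------------------------------------------------

_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_R_GAS = 1.987  # cal/(mol K)
_NA_MOLAR = 0.05
_OLIGO_MOLAR = 0.25e-6


def melting_temp(primer: str, method: str = "nn") -> float:
    """Primer melting temperature in degC.

    ``method="nn"`` (default) is the nearest-neighbor thermodynamic Tm at
    the fixed standard conditions above; ``method="wallace"`` is the
    2(A+T) + 4(G+C) rule of thumb.
    """
    primer = primer.upper()
    if len(primer) < 8:
        raise ValueError(f"primer too short ({len(primer)} < 8 nt)")
    bad = set(primer) - set("ACGT")
    if bad:
        raise ValueError(f"primer contains non-ACGT characters {sorted(bad)}")
    if method == "wallace":
        at = primer.count("A") + primer.count("T")
        gc = primer.count("G") + primer.count("C")
        return float(2 * at + 4 * gc)
    if method != "nn":
        raise ValueError(f"unknown Tm method {method!r}")
    dh = ds = 0.0
    for i in range(len(primer) - 1):
        h, s = _NN[primer[i : i + 2]]
        dh += h
        ds += s
    for terminal in (primer[0], primer[-1]):
        h, s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += s
    ds += 0.368 * (len(primer) - 1) * math.log(_NA_MOLAR)
    tm_kelvin = dh * 1000.0 / (ds + _R_GAS * math.log(_OLIGO_MOLAR / 4.0))
    return tm_kelvin - 273.15


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def three_prime_complementarity(primer_a: str, primer_b: str, max_check: int = 8) -> int:
    """Length of the longest mutual 3'-end anneal (antiparallel match)."""
    best = 0
    limit = min(len(primer_a), len(primer_b), max_check)
    for s in range(1, limit + 1):
        if primer_a[-s:] == revcomp(primer_b[-s:]):
            best = s
    return best


# ---------------------------------------------------------------------------
# Primer search
# ---------------------------------------------------------------------------


def _primer_quality(seq: str, params: DesignParams) -> tuple[float, float, float]:
    """(penalty, tm, gc) for one primer core."""
    tm = melting_temp(seq)
    gc = gc_fraction(seq)
    penalty = abs(tm - params.tm_optimum)
    lo, hi = params.gc_range
    if gc < lo:
        penalty += params.w_gc * (lo - gc)
    elif gc > hi:
        penalty += params.w_gc * (gc - hi)
    return penalty, tm, gc


_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_DH_TABLE = np.zeros(16)
_DS_TABLE = np.zeros(16)
for _d, (_h, _s) in _NN.items():
    _DH_TABLE[4 * _BASE_CODE[ord(_d[0])] + _BASE_CODE[ord(_d[1])]] = _h
    _DS_TABLE[4 * _BASE_CODE[ord(_d[0])] + _BASE_CODE[ord(_d[1])]] = _s


def _window_profiles(sequence: str, lengths: range):
    """Vectorized per-window Tm and GC for every window of each length.

    Returns ``{L: (tm, gc, valid)}`` where index ``i`` describes window
    ``sequence[i:i+L]``.  The arithmetic matches :func:`melting_temp`
    (nearest-neighbor stacks + initiation + entropy salt correction);
    the NN table is reverse-complement symmetric, so the same profile
    serves forward primers and reverse primers read off the other strand.
    """
    codes = _BASE_CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    n = len(codes)
    valid_base = codes < 4
    is_gc = (codes == 1) | (codes == 2)
    dinuc = 4 * codes[:-1] + codes[1:]
    dinuc_ok = valid_base[:-1] & valid_base[1:]
    dh_p = np.concatenate([[0.0], np.cumsum(np.where(dinuc_ok, _DH_TABLE[dinuc], 0.0))])
    ds_p = np.concatenate([[0.0], np.cumsum(np.where(dinuc_ok, _DS_TABLE[dinuc], 0.0))])
    gc_p = np.concatenate([[0], np.cumsum(is_gc)])
    ok_p = np.concatenate([[0], np.cumsum(valid_base)])
    log_ct = _R_GAS * math.log(_OLIGO_MOLAR / 4.0)
    out = {}
    for L in lengths:
        if L > n:
            out[L] = (np.empty(0), np.empty(0), np.empty(0, dtype=bool))
            continue
        starts = np.arange(n - L + 1)
        dh = dh_p[starts + L - 1] - dh_p[starts]
        ds = ds_p[starts + L - 1] - ds_p[starts]
        first, last = codes[starts], codes[starts + L - 1]
        for term in (first, last):
            gc_term = (term == 1) | (term == 2)
            dh = dh + np.where(gc_term, _INIT_GC[0], _INIT_AT[0])
            ds = ds + np.where(gc_term, _INIT_GC[1], _INIT_AT[1])
        ds = ds + 0.368 * (L - 1) * math.log(_NA_MOLAR)
        tm = dh * 1000.0 / (ds + log_ct) - 273.15
        gc = (gc_p[starts + L] - gc_p[starts]) / L
        valid = (ok_p[starts + L] - ok_p[starts]) == L
        out[L] = (tm, gc, valid)
    return out


def _best_primers(
    sequence: str, region_start: int, region_end: int, params: DesignParams, sense: str
):
    """Best primer anchored at each position of the permitted region.

    For ``sense="forward"`` the anchor is the primer's 5' start; for
    ``sense="reverse"`` it is the product end (the primer binds the
    template ending there).  Returns dict anchor -> (penalty, seq, tm, gc);
    ties between lengths break toward the shorter primer.
    """
    lmin, lmax = params.primer_len_range
    profiles = _window_profiles(sequence, range(lmin, lmax + 1))
    gc_lo, gc_hi = params.gc_range
    out: dict[int, tuple[float, str, float, float]] = {}
    for length in range(lmin, lmax + 1):
        tm, gc, valid = profiles[length]
        pen = np.abs(tm - params.tm_optimum)
        pen = pen + params.w_gc * np.maximum(0.0, gc_lo - gc)
        pen = pen + params.w_gc * np.maximum(0.0, gc - gc_hi)
        if sense == "forward":
            anchors = np.arange(region_start, region_end - length + 1)
            window_starts = anchors
        else:
            anchors = np.arange(region_start + length, region_end + 1)
            window_starts = anchors - length
        for anchor, ws in zip(anchors, window_starts):
            if ws >= len(valid) or not valid[ws]:
                continue
            penalty = float(pen[ws])
            prev = out.get(anchor)
            if prev is None or penalty < prev[0] - 1e-12:
                core = sequence[ws : ws + length]
                if sense == "reverse":
                    core = revcomp(core)
                out[anchor] = (penalty, core, float(tm[ws]), float(gc[ws]))
    return out


def design_amplicon(
    record: FlicRecord,
    params: Optional[DesignParams] = None,
    candidate_position: Optional[int] = None,
) -> Union[AmpliconDesign, DesignFailure]:
    """Pick the best-scoring primer pair for one target gene.

    Hard constraints: product length within the method's size range;
    primers within the permitted region (3'UTR for ``utr_primed``); for
    ``insilico``, the candidate at least ``candidate_margin`` nt inside
    both primers.  Soft score: |Tm - optimum| per primer, GC outside the
    window, product-length deviation from the range midpoint, and a
    3'-end complementarity penalty (re-scored over the best 200 base
    pairs of positions).  Ties break leftmost-then-shortest, so a fixed
    input yields a fixed design.
    """
    params = params or DesignParams()
    record.validate()
    size_lo, size_hi = params.product_size_range
    if params.method == "utr_primed":
        region = (record.utr3.start, record.utr3.end)
        if len(record.utr3) < size_lo:
            return DesignFailure(record.accession, params.method, "utr_too_short")
    else:
        region = (0, len(record.sequence))
        if params.method == "insilico":
            if candidate_position is None:
                raise ValueError("insilico design requires candidate_position")
            if not 0 <= candidate_position < len(record.sequence):
                return DesignFailure(
                    record.accession, params.method, "candidate_outside_sequence"
                )
    if region[1] - region[0] < size_lo:
        return DesignFailure(record.accession, params.method, "region_too_short")

    fwd = _best_primers(record.sequence, region[0], region[1], params, "forward")
    rev = _best_primers(record.sequence, region[0], region[1], params, "reverse")
    mid = (size_lo + size_hi) / 2.0

    # dense arrays over absolute positions for vectorized pairing
    n_pos = len(record.sequence) + 1
    fpen_arr = np.full(n_pos, np.inf)
    flen_arr = np.zeros(n_pos, dtype=np.int64)
    for start, (fpen, fseq, _, _) in fwd.items():
        fpen_arr[start] = fpen
        flen_arr[start] = len(fseq)
    rpen_arr = np.full(n_pos, np.inf)
    rlen_arr = np.zeros(n_pos, dtype=np.int64)
    for end, (rpen, rseq, _, _) in rev.items():
        rpen_arr[end] = rpen
        rlen_arr[end] = len(rseq)

    all_scores, all_starts, all_lens = [], [], []
    for plen in range(size_lo, size_hi + 1):
        starts = np.arange(region[0], region[1] - plen + 1)
        if len(starts) == 0:
            continue
        ends = starts + plen
        base = fpen_arr[starts] + rpen_arr[ends] + params.w_length * abs(plen - mid)
        ok = np.isfinite(base)
        if params.method == "insilico":
            # candidate strictly interior, margin nt clear of both primers
            ok &= starts + flen_arr[starts] + params.candidate_margin <= candidate_position
            ok &= candidate_position < ends - rlen_arr[ends] - params.candidate_margin + 1
        if not ok.any():
            continue
        all_scores.append(base[ok])
        all_starts.append(starts[ok])
        all_lens.append(np.full(int(ok.sum()), plen))
    if not all_scores:
        return DesignFailure(record.accession, params.method, "no_valid_pair")
    scores = np.concatenate(all_scores)
    starts = np.concatenate(all_starts)
    plens = np.concatenate(all_lens)
    order = np.lexsort((plens, starts, scores))[:200]

    # exact base score everywhere; dimer penalty on the best 200 pairs
    best = None
    for idx in order:
        base, start, end = float(scores[idx]), int(starts[idx]), int(starts[idx] + plens[idx])
        fpen, fseq, ftm, fgc = fwd[start]
        rpen, rseq, rtm, rgc = rev[end]
        run = three_prime_complementarity(fseq, rseq)
        score = base
        if run >= params.dimer_min_run:
            score += params.dimer_penalty + (run - params.dimer_min_run)
        key = (score, start, end - start)
        if best is None or key < best[0]:
            best = (key, start, end, fseq, rseq, ftm, rtm, fgc, rgc)
    key, start, end, fseq, rseq, ftm, rtm, fgc, rgc = best
    score = key[0]
    return AmpliconDesign(
        flic_accession=record.accession,
        method=params.method,
        product_start=start,
        product_end=end,
        forward_primer=fseq,
        reverse_primer=rseq,
        forward_tailed=params.m13_forward_tail + fseq,
        reverse_tailed=params.m13_reverse_tail + rseq,
        product_length=end - start,
        tm_forward=ftm,
        tm_reverse=rtm,
        gc_forward=fgc,
        gc_reverse=rgc,
        score=float(score),
    )


def amplify(design: AmpliconDesign, template: str) -> str:
    """In silico PCR: the template substring the primer pair would amplify."""
    fwd = design.forward_primer
    rev_site = revcomp(design.reverse_primer)
    start = template.find(fwd)
    if start < 0:
        raise ValueError("forward primer site not found on template")
    end = template.find(rev_site, start)
    if end < 0:
        raise ValueError("reverse primer site not found on template")
    return template[start : end + len(rev_site)]
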