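"""In silico candidate-SNP mining: align ESTs to a FLIc, filter, emit sites.

An EST that truly derives from an allele of the target gene aligns at
high identity and differs from the FLIc only at sequencing errors and
genuine polymorphisms.  The filter chain removes the other sources of
apparent difference:

* low-identity / short alignments (spurious or non-target matches);
* ESTs with clustered differences (> ``max_diffs_per_100bp`` in any
  100-column window) — these derive from a highly similar paralog, and
  every difference in them is a paralogous sequence variant, not a SNP;
* differences within the first or last ``end_trim`` bases of the EST
  read itself, where single-pass quality decays;
* differences inside simple repeats of the target (homopolymer runs and
  short tandem repeats), where slippage errors concentrate.

Whatever survives is a candidate SNP to carry into amplicon design and
panel validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import Align

from .core import FlicRecord, revcomp

REJECT_IDENTITY = "rejected_identity"
REJECT_PARALOG = "rejected_paralog_est"
REJECT_SHORT = "rejected_short_alignment"
REJECT_END_TRIM = "rejected_end_trim"
REJECT_REPEAT = "rejected_repeat"
CANDIDATE = "candidate"

# status precedence when no clean supporter remains
_STATUS_ORDER = [REJECT_IDENTITY, REJECT_SHORT, REJECT_PARALOG, REJECT_END_TRIM, REJECT_REPEAT]


@dataclass
class MiningParams:
    """Filter thresholds; defaults follow the operational protocol."""

    min_identity: float = 0.96
    max_diffs_per_100bp: int = 4
    window: int = 100
    end_trim: int = 50
    min_aln_len: int = 100  # surrogate for a database E-value cutoff
    min_supporting: int = 1
    min_homopolymer: int = 5
    min_tandem_units: int = 3
    search_revcomp: bool = False
    match_score: float = 1.0
    mismatch_score: float = -2.0
    open_gap_score: float = -5.0
    extend_gap_score: float = -2.0


@dataclass
class EstAlignment:
    """A trimmed global alignment of an EST to its target FLIc.

    ``aligned_est``/``aligned_flic`` are the gapped strings over the
    matched region (end-gap columns removed); ``est_span``/``flic_span``
    are the matched intervals on the original sequences (0-based,
    half-open, in the EST read's own orientation-corrected coordinates).
    """

    est_id: str
    flic_accession: str
    aligned_flic: str
    aligned_est: str
    identity: float
    score: float
    est_span: tuple[int, int]
    flic_span: tuple[int, int]
    est_length: int
    orientation: str = "+"
    usable: bool = True


def _make_aligner(params: MiningParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.open_gap_score
    aligner.extend_gap_score = params.extend_gap_score
    # free end gaps: the EST is a fragment of the transcript
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _trim_end_gaps(target_g: str, query_g: str) -> tuple[str, str, int, int]:
    """Drop leading/trailing columns where either string is gapped."""
    n = len(target_g)
    start, end = 0, n
    while start < n and (target_g[start] == "-" or query_g[start] == "-"):
        start += 1
    while end > start and (target_g[end - 1] == "-" or query_g[end - 1] == "-"):
        end -= 1
    return target_g[start:end], query_g[start:end], start, end


def _align_once(est_seq: str, flic: FlicRecord, aligner) -> tuple:
    aln = aligner.align(flic.sequence, est_seq)[0]
    tg, qg = aln[0], aln[1]
    tg_t, qg_t, col_start, col_end = _trim_end_gaps(tg, qg)
    flic_start = sum(1 for ch in tg[:col_start] if ch != "-")
    est_start = sum(1 for ch in qg[:col_start] if ch != "-")
    flic_end = flic_start + sum(1 for ch in tg_t if ch != "-")
    est_end = est_start + sum(1 for ch in qg_t if ch != "-")
    matches = sum(1 for a, b in zip(tg_t, qg_t) if a == b)
    identity = matches / len(tg_t) if tg_t else 0.0
    return aln.score, tg_t, qg_t, (est_start, est_end), (flic_start, flic_end), identity


def align_est(
    est_id: str,
    est_seq: str,
    flic: FlicRecord,
    params: Optional[MiningParams] = None,
) -> EstAlignment:
    """Globally align one EST to a FLIc with free end gaps.

    With ``params.search_revcomp`` the reverse complement is also tried
    and the higher-scoring orientation kept; the EST span is reported in
    the read's original coordinates either way.
    """
    params = params or MiningParams()
    if not est_seq or not flic.sequence:
        raise ValueError("empty sequence")
    aligner = _make_aligner(params)
    score, tg, qg, est_span, flic_span, identity = _align_once(est_seq, flic, aligner)
    orientation = "+"
    if params.search_revcomp:
        rc = revcomp(est_seq)
        r_score, r_tg, r_qg, r_span, r_fspan, r_ident = _align_once(rc, flic, aligner)
        if r_score > score:
            n = len(est_seq)
            score, tg, qg, flic_span, identity = r_score, r_tg, r_qg, r_fspan, r_ident
            est_span = (n - r_span[1], n - r_span[0])
            orientation = "-"
    usable = score > 0 and len(tg) > 0
    return EstAlignment(
        est_id=est_id,
        flic_accession=flic.accession,
        aligned_flic=tg,
        aligned_est=qg,
        identity=identity,
        score=float(score),
        est_span=est_span,
        flic_span=flic_span,
        est_length=len(est_seq),
        orientation=orientation,
        usable=usable,
    )


def _window_max_diffs(diff: np.ndarray, window: int) -> int:
    """Max number of differences in any sliding window of aligned columns."""
    n = len(diff)
    if n == 0:
        return 0
    if n <= window:
        return int(diff.sum())
    csum = np.concatenate([[0], np.cumsum(diff)])
    return int((csum[window:] - csum[:-window]).max())


def filter_est(alignment: EstAlignment, params: Optional[MiningParams] = None):
    """EST-level accept/reject: identity floor, length floor, paralog rule.

    Returns ``(keep, reason)`` with ``reason`` empty when kept.
    """
    params = params or MiningParams()
    if not alignment.usable:
        return False, REJECT_SHORT
    n_cols = len(alignment.aligned_flic)
    if n_cols < params.min_aln_len:
        return False, REJECT_SHORT
    if alignment.identity < params.min_identity:
        return False, REJECT_IDENTITY
    diff = np.fromiter(
        (a != b for a, b in zip(alignment.aligned_flic, alignment.aligned_est)),
        dtype=np.uint8,
        count=n_cols,
    )
    if _window_max_diffs(diff, params.window) > params.max_diffs_per_100bp:
        return False, REJECT_PARALOG
    return True, ""


def mask_repeats(
    sequence: str, min_homopolymer: int = 5, min_tandem_units: int = 3
) -> np.ndarray:
    """Boolean mask of simple-repeat positions on the target.

    Marks homopolymer runs of length >= ``min_homopolymer`` (poly-G/C and
    poly-A/T alike) and perfect di-/tri-nucleotide tandem repeats of at
    least ``min_tandem_units`` units.
    """
    n = len(sequence)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:  # homopolymers
        j = i
        while j < n and sequence[j] == sequence[i]:
            j += 1
        if j - i >= min_homopolymer:
            mask[i:j] = True
        i = j
    for unit in (2, 3):  # tandem repeats (every offset: overlapping runs count)
        min_len = unit * min_tandem_units
        for i in range(n - min_len + 1):
            if len(set(sequence[i : i + unit])) == 1:
                continue  # homopolymers handled above
            j = i + unit
            while j + unit <= n and sequence[j : j + unit] == sequence[i : i + unit]:
                j += unit
            if j - i >= min_len:
                mask[i:j] = True
    return mask


@dataclass
class CandidateSnp:
    """A putative variant site on the FLIc, merged over supporting ESTs."""

    flic_accession: str
    position: int  # 0-based transcript coordinate
    flic_allele: str
    est_allele: str
    status: str
    supporting_ests: list[str] = field(default_factory=list)
    rejected_ests: dict[str, str] = field(default_factory=dict)


def _iter_differences(alignment: EstAlignment):
    """Yield (flic_pos, est_pos, flic_char, est_char) per difference column.

    For gap columns the position on the gapped side is the coordinate of
    the next real base (i.e. the insertion point / deleted base).
    """
    fpos, epos = alignment.flic_span[0], alignment.est_span[0]
    step = 1 if alignment.orientation == "+" else -1
    if alignment.orientation == "-":
        epos = alignment.est_span[1] - 1
    for fc, ec in zip(alignment.aligned_flic, alignment.aligned_est):
        if fc != ec:
            yield fpos, epos, fc, ec
        if fc != "-":
            fpos += 1
        if ec != "-":
            epos += step


def mine_candidates(
    alignments: list[EstAlignment],
    flic: FlicRecord,
    params: Optional[MiningParams] = None,
) -> list[CandidateSnp]:
    """Apply the full filter chain and merge per-site evidence.

    Each filter is evaluated independently per (EST, column); a site is a
    candidate when at least ``min_supporting`` ESTs support it cleanly.
    Sites seen only in rejected evidence are reported with the rejection
    status (fixed precedence: identity, short, paralog, end-trim, repeat),
    so nothing is silently dropped.
    """
    params = params or MiningParams()
    repeat_mask = mask_repeats(
        flic.sequence, params.min_homopolymer, params.min_tandem_units
    )
    sites: dict[tuple[int, str, str], CandidateSnp] = {}
    for aln in alignments:
        if aln.flic_accession != flic.accession:
            continue
        keep, est_reason = filter_est(aln, params)
        for fpos, epos, fc, ec in _iter_differences(aln):
            key = (fpos, fc, ec)
            site = sites.get(key)
            if site is None:
                site = CandidateSnp(
                    flic_accession=flic.accession,
                    position=fpos,
                    flic_allele=fc,
                    est_allele=ec,
                    status=CANDIDATE,
                )
                sites[key] = site
            if not keep:
                site.rejected_ests[aln.est_id] = est_reason
                continue
            if epos < params.end_trim or epos >= aln.est_length - params.end_trim:
                site.rejected_ests[aln.est_id] = REJECT_END_TRIM
            elif fpos < len(repeat_mask) and repeat_mask[fpos]:
                site.rejected_ests[aln.est_id] = REJECT_REPEAT
            else:
                site.supporting_ests.append(aln.est_id)
    out = []
    for key in sorted(sites):
        site = sites[key]
        if len(site.supporting_ests) >= params.min_supporting:
            site.status = CANDIDATE
        else:
            reasons = set(site.rejected_ests.values())
            site.status = next(s for s in _STATUS_ORDER if s in reasons)
        out.append(site)
    return out
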