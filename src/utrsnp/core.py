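"""Domain types and IUPAC genotype algebra for targeted SNP discovery.

The discovery targets are full-length insert cDNAs (FLIcs): transcripts
annotated with a coding sequence (CDS) and a complete 3' untranslated
region (3'UTR).  Panel genotypes are Sanger-style consensus strings, one
per diploid individual, with heterozygous positions written as IUPAC
ambiguity codes.

Coordinate convention: 0-based, half-open internally; 1-based inclusive
in all files and reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "Interval",
    "FlicRecord",
    "PanelGenotypes",
    "VariantSite",
    "ValidationError",
    "iupac_decode",
    "iupac_encode",
    "genotype_from_call",
    "extract_utr3",
    "Utr3Sequence",
    "revcomp",
]


class ValidationError(ValueError):
    """A record violated a structural invariant; the message names it."""


@dataclass(frozen=True)
class Interval:
    """0-based, half-open interval on a transcript."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValidationError(f"invalid interval ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


_VALID_BASES = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC-aware, gap-preserving."""
    return seq.translate(COMPLEMENT)[::-1]


def normalize_sequence(seq: str, *, accession: str = "?") -> str:
    """Uppercase and restrict to A/C/G/T/N (U is read as T)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValidationError(
            f"{accession}: sequence contains invalid characters {sorted(bad)}"
        )
    return s


@dataclass
class FlicRecord:
    """An annotated full-length cDNA: the SNP-discovery target.

    ``cds`` and ``utr3`` are transcript intervals (0-based half-open); the
    3'UTR follows the CDS on the sense strand.
    """

    accession: str
    sequence: str
    utr3: Interval
    cds: Optional[Interval] = None
    complete_cds_flag: bool = False

    def validate(self) -> "FlicRecord":
        self.sequence = normalize_sequence(self.sequence, accession=self.accession)
        n = len(self.sequence)
        if not (0 <= self.utr3.start and self.utr3.end <= n):
            raise ValidationError(
                f"{self.accession}: utr3 {self.utr3} exceeds sequence length {n}"
            )
        if len(self.utr3) == 0:
            raise ValidationError(f"{self.accession}: empty 3'UTR interval")
        if self.cds is not None:
            if not (0 <= self.cds.start and self.cds.end <= n):
                raise ValidationError(
                    f"{self.accession}: cds {self.cds} exceeds sequence length {n}"
                )
            if self.cds.overlaps(self.utr3):
                raise ValidationError(
                    f"{self.accession}: cds {self.cds} overlaps utr3 {self.utr3}"
                )
            if self.cds.end > self.utr3.start:
                raise ValidationError(
                    f"{self.accession}: 3'UTR must follow the CDS "
                    f"(cds.end={self.cds.end} > utr3.start={self.utr3.start})"
                )
        return self


# ---------------------------------------------------------------------------
# IUPAC algebra
#
# The six two-base ambiguity codes cover every possible bi-allelic
# heterozygote; B/D/H/V/N are decoded for completeness but a diploid
# bi-allelic consensus never needs them.  Two artifact conventions for
# deletion-insertion polymorphisms (DIPs): '-' is a homozygous single-base
# deletion, and lowercase a/c/g/t is a base/gap heterozygote.
# ---------------------------------------------------------------------------

IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset("-"),
    "a": frozenset("A-"),
    "c": frozenset("C-"),
    "g": frozenset("G-"),
    "t": frozenset("T-"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}


def iupac_decode(code: str, *, position: Optional[int] = None) -> frozenset[str]:
    """Decode one consensus character into its allele set.

    Raises :class:`ValidationError` for unknown characters, naming the
    character and (if given) the column position.
    """
    try:
        return IUPAC_TO_BASES[code]
    except KeyError:
        where = "" if position is None else f" at position {position}"
        raise ValidationError(f"unknown IUPAC character {code!r}{where}") from None


def iupac_encode(alleles: Iterable[str], *, allow_multi: bool = False) -> str:
    """Encode an allele set as a single consensus character.

    The pipeline is bi-allelic: sets of three or more bases are rejected
    unless ``allow_multi`` is set (which restores the full bijection over
    the standard codes).
    """
    key = frozenset(alleles)
    if not allow_multi and len(key) > 2:
        raise ValidationError(
            f"allele set {sorted(key)} unsupported: bi-allelic model admits "
            "at most two alleles per site"
        )
    try:
        return BASES_TO_IUPAC[key]
    except KeyError:
        raise ValidationError(f"no IUPAC code for allele set {sorted(key)}") from None


def genotype_from_call(call: str, *, position: Optional[int] = None):
    """Turn one consensus character into a diploid genotype.

    Returns a sorted 2-tuple of alleles, or ``None`` for a no-call ('N').
    Three-or-more-base ambiguity codes are invalid in a diploid consensus.
    """
    if call == "N":
        return None
    alleles = iupac_decode(call, position=position)
    if len(alleles) == 1:
        (a,) = alleles
        return (a, a)
    if len(alleles) == 2:
        a, b = sorted(alleles)
        return (a, b)
    where = "" if position is None else f" at position {position}"
    raise ValidationError(
        f"call {call!r}{where} implies >2 alleles; invalid diploid consensus"
    )


# ---------------------------------------------------------------------------
# Panel genotypes and variant sites
# ---------------------------------------------------------------------------

PANEL_ALPHABET = frozenset(IUPAC_TO_BASES)


@dataclass
class PanelGenotypes:
    """Per-individual consensus strings over one amplicon, pre-aligned.

    ``calls[i]`` is the consensus of ``individuals[i]``; all strings have
    the amplicon's aligned length.  ``extension_*`` hold the optional
    extra individuals used when a rare variant was seen only once in the
    primary panel.
    """

    amplicon_id: str
    individuals: list[str]
    calls: list[str]
    extension_individuals: list[str] = field(default_factory=list)
    extension_calls: list[str] = field(default_factory=list)
    reference: Optional[str] = None

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def length(self) -> int:
        return len(self.calls[0]) if self.calls else 0

    def validate(self) -> "PanelGenotypes":
        if self.n < 2:
            raise ValidationError(f"{self.amplicon_id}: panel size {self.n} < 2")
        if len(self.calls) != self.n:
            raise ValidationError(f"{self.amplicon_id}: calls/individuals mismatch")
        if len(set(self.individuals)) != self.n:
            raise ValidationError(f"{self.amplicon_id}: duplicate individual ids")
        lengths = {len(c) for c in self.calls} | {
            len(c) for c in self.extension_calls
        }
        if self.reference is not None:
            lengths.add(len(self.reference))
        if len(lengths) > 1:
            raise ValidationError(
                f"{self.amplicon_id}: consensus strings differ in length {sorted(lengths)}"
            )
        if len(self.extension_calls) != len(self.extension_individuals):
            raise ValidationError(
                f"{self.amplicon_id}: extension calls/individuals mismatch"
            )
        for ind, call in zip(
            self.individuals + self.extension_individuals,
            self.calls + self.extension_calls,
        ):
            bad = set(call) - PANEL_ALPHABET
            if bad:
                raise ValidationError(
                    f"{self.amplicon_id}/{ind}: invalid consensus characters {sorted(bad)}"
                )
        return self

    def pooled(self) -> "PanelGenotypes":
        """Primary + extension individuals as one panel (the 15-fish re-test)."""
        if not self.extension_individuals:
            return self
        return replace(
            self,
            individuals=self.individuals + self.extension_individuals,
            calls=self.calls + self.extension_calls,
            extension_individuals=[],
            extension_calls=[],
        )


@dataclass
class VariantSite:
    """A bi-allelic polymorphic column in a panel alignment."""

    amplicon_id: str
    position: int  # 0-based column index
    ref_allele: str
    alt_allele: str
    site_class: str  # "SNP" | "DIP"
    genotype_counts: tuple[int, int, int]  # (hom_ref, het, hom_alt)
    carriers_of_rare: int
    status: str = "candidate"
    n_called: int = 0

    def __post_init__(self) -> None:
        if self.site_class not in ("SNP", "DIP"):
            raise ValidationError(f"invalid site_class {self.site_class!r}")
        expected = "DIP" if "-" in (self.ref_allele, self.alt_allele) else "SNP"
        if self.site_class != expected:
            raise ValidationError(
                f"site_class {self.site_class} inconsistent with alleles "
                f"{self.ref_allele}/{self.alt_allele}"
            )
        if self.n_called and sum(self.genotype_counts) != self.n_called:
            raise ValidationError("genotype counts do not sum to called individuals")


# ---------------------------------------------------------------------------
# 3'UTR extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Utr3Sequence:
    """A 3'UTR subsequence plus the exact coordinate map to the transcript."""

    accession: str
    sequence: str
    offset: int  # transcript coordinate of subsequence position 0

    def to_transcript(self, utr_pos: int) -> int:
        if not 0 <= utr_pos < len(self.sequence):
            raise ValidationError(
                f"{self.accession}: UTR position {utr_pos} outside [0, {len(self.sequence)})"
            )
        return self.offset + utr_pos

    def to_utr(self, transcript_pos: int) -> int:
        pos = transcript_pos - self.offset
        if not 0 <= pos < len(self.sequence):
            raise ValidationError(
                f"{self.accession}: transcript position {transcript_pos} not in 3'UTR"
            )
        return pos


def extract_utr3(record: FlicRecord) -> Utr3Sequence:
    """Slice out the 3'UTR with its transcript-coordinate offset."""
    record.validate()
    if len(record.utr3) == 0:
        raise ValidationError(f"{record.accession}: empty 3'UTR")
    return Utr3Sequence(
        accession=record.accession,
        sequence=record.sequence[record.utr3.start : record.utr3.end],
        offset=record.utr3.start,
    )
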