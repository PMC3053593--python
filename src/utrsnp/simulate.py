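"""Synthetic duplicated-genome targets, diploid panels, and error-bearing ESTs.

The generator emulates the study system: a partially tetraploid genome in
which many genes have a recently duplicated paralog.  Paralog pairs
diverge by point substitution, faster in the 3'UTR than in the CDS
(conserved coding sequence), so 3'UTR-primed amplification can stay
locus-specific while CDS-primed amplification risks co-amplifying the
paralog.  True variants (SNPs and single-base DIPs) are planted at chosen
minor-allele frequencies and panel genotypes are drawn under
Hardy-Weinberg equilibrium; ESTs are error-bearing fragments of allelic
or paralogous transcripts.

Every operation is deterministic given the config seed: the same config
yields byte-identical FASTA output.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .core import FlicRecord, Interval, PanelGenotypes, iupac_encode

BASES = np.array(list("ACGT"))
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults mirror the study design where it states them: a 10-individual
    validation panel with a 5-individual extension, and a DIP fraction of
    16/79 (the observed share of DIPs among discovered polymorphisms).
    Paralog divergence in 3'UTRs is a free parameter of the system; 0.03
    per base keeps paralogs above the 96%-identity mining floor while the
    CDS, at 0.3x that rate, stays highly conserved.
    """

    seed: int = 0
    n_genes: int = 20
    utr3_len_range: tuple[int, int] = (200, 800)
    cds_len_range: tuple[int, int] = (300, 1500)
    paralog_fraction: float = 0.5
    paralog_divergence: float = 0.03
    cds_divergence_factor: float = 0.3
    panel_size: int = 10
    extension_size: int = 5
    planted_snps_per_gene: int = 2
    maf_distribution: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5)
    dip_fraction: float = 16 / 79
    est_per_gene: int = 5
    est_error_rate: float = 0.01
    est_len_range: tuple[int, int] = (300, 600)
    est_paralog_fraction: float = 0.3
    plant_region: str = "utr3"  # "utr3" | "cds" | "any"
    plant_repeats: bool = False
    est_indel_errors: bool = False

    def validate(self) -> "SimConfig":
        for name in (
            "paralog_fraction",
            "paralog_divergence",
            "cds_divergence_factor",
            "dip_fraction",
            "est_error_rate",
            "est_paralog_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("utr3_len_range", "cds_len_range", "est_len_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name}=({lo}, {hi}) is empty or non-positive")
        if any(not 0.0 <= m <= 0.5 for m in self.maf_distribution):
            raise ValueError("minor-allele frequencies must lie in [0, 0.5]")
        if self.panel_size < 2:
            raise ValueError("panel_size must be >= 2")
        if self.plant_region not in ("utr3", "cds", "any"):
            raise ValueError(f"invalid plant_region {self.plant_region!r}")
        if self.paralog_divergence > 0.25:
            warnings.warn(
                "paralog_divergence > 0.25: alignment-based mining assumptions break",
                stacklevel=2,
            )
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("utr3_len_range", "cds_len_range", "est_len_range", "maf_distribution"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data).validate()


@dataclass
class PlantedVariant:
    position: int  # transcript coordinate on the source gene
    ref: str
    alt: str  # '-' for a deletion DIP
    maf: float
    site_class: str  # "SNP" | "DIP"


@dataclass
class GeneTruth:
    accession: str
    planted: list[PlantedVariant] = field(default_factory=list)
    paralog_accession: Optional[str] = None
    fixed_differences: list[int] = field(default_factory=list)
    repeat_intervals: list[tuple[int, int]] = field(default_factory=list)
    diplotypes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    genes: dict[str, GeneTruth] = field(default_factory=dict)
    est_sources: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "genes": {
                acc: {
                    "planted": [dataclasses.asdict(v) for v in g.planted],
                    "paralog_accession": g.paralog_accession,
                    "fixed_differences": g.fixed_differences,
                    "repeat_intervals": [list(t) for t in g.repeat_intervals],
                    "diplotypes": {
                        ind: [list(gt) for gt in gts]
                        for ind, gts in g.diplotypes.items()
                    },
                }
                for acc, g in self.genes.items()
            },
            "est_sources": self.est_sources,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random codons + stop; length forced to a multiple of 3 (>= 9)."""
    length = max(9, length - length % 3)
    middle = _random_seq(rng, length - 6)
    stop = STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + middle + stop


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def _diverge(
    rng: np.random.Generator, seq: str, rate_cds: float, rate_utr: float, cds: Interval
) -> tuple[str, list[int]]:
    """Substitute bases independently; CDS positions at the reduced rate."""
    out = list(seq)
    positions: list[int] = []
    rates = np.full(len(seq), rate_utr)
    rates[cds.start : cds.end] = rate_cds
    hits = np.nonzero(rng.random(len(seq)) < rates)[0]
    for i in hits:
        out[i] = _mutate_base(rng, out[i])
        positions.append(int(i))
    return "".join(out), positions


def simulate_targets(config: SimConfig):
    """Generate FLIc target genes, their paralogs, and the ground truth.

    Returns ``(flics, paralogs, truth)`` where ``paralogs`` maps source
    accession to the paralog's sequence.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    flics: list[FlicRecord] = []
    paralogs: dict[str, str] = {}
    truth = SimTruth()
    for i in range(config.n_genes):
        acc = f"SIM{i:04d}"
        cds_len = int(rng.integers(config.cds_len_range[0], config.cds_len_range[1] + 1))
        utr_len = int(rng.integers(config.utr3_len_range[0], config.utr3_len_range[1] + 1))
        cds_seq = _random_cds(rng, cds_len)
        utr_seq = _random_seq(rng, utr_len)
        gene = GeneTruth(accession=acc)
        if config.plant_repeats and utr_len >= 40:
            run_len = int(rng.integers(6, 11))
            run_base = "G" if rng.random() < 0.5 else "C"
            start = int(rng.integers(10, utr_len - run_len - 10))
            utr_seq = utr_seq[:start] + run_base * run_len + utr_seq[start + run_len :]
            gene.repeat_intervals.append(
                (len(cds_seq) + start, len(cds_seq) + start + run_len)
            )
        seq = cds_seq + utr_seq
        cds = Interval(0, len(cds_seq))
        utr3 = Interval(len(cds_seq), len(seq))
        record = FlicRecord(
            accession=acc, sequence=seq, utr3=utr3, cds=cds, complete_cds_flag=True
        ).validate()
        flics.append(record)

        # plant variants
        if config.plant_region == "utr3":
            lo, hi = utr3.start, utr3.end
        elif config.plant_region == "cds":
            lo, hi = cds.start, cds.end
        else:
            lo, hi = 0, len(seq)
        n_plant = min(config.planted_snps_per_gene, hi - lo)
        positions = rng.choice(np.arange(lo, hi), size=n_plant, replace=False)
        for pos in sorted(int(p) for p in positions):
            ref = seq[pos]
            is_dip = rng.random() < config.dip_fraction
            alt = "-" if is_dip else _mutate_base(rng, ref)
            maf = float(
                config.maf_distribution[rng.integers(0, len(config.maf_distribution))]
            )
            gene.planted.append(
                PlantedVariant(pos, ref, alt, maf, "DIP" if is_dip else "SNP")
            )

        if rng.random() < config.paralog_fraction:
            pacc = f"{acc}p"
            pseq, fixed = _diverge(
                rng,
                seq,
                config.paralog_divergence * config.cds_divergence_factor,
                config.paralog_divergence,
                cds,
            )
            paralogs[acc] = pseq
            gene.paralog_accession = pacc
            gene.fixed_differences = fixed
        truth.genes[acc] = gene
    return flics, paralogs, truth


# ---------------------------------------------------------------------------
# Diploid panel under Hardy-Weinberg sampling
# ---------------------------------------------------------------------------


def _draw_diplotype(rng: np.random.Generator, variant: PlantedVariant) -> tuple[str, str]:
    """Two independent allele draws at the site's minor-allele frequency."""
    a1 = variant.alt if rng.random() < variant.maf else variant.ref
    a2 = variant.alt if rng.random() < variant.maf else variant.ref
    return (a1, a2)


def _consensus_call(alleles: set[str]) -> str:
    if len(alleles) == 1:
        return next(iter(alleles))
    if len(alleles) == 2:
        if "-" in alleles:
            (base,) = alleles - {"-"}
            return base.lower()  # heterozygous base/gap convention
        return iupac_encode(alleles)
    return "N"  # >2 distinct alleles cannot be expressed in a diploid consensus


def simulate_panel(
    flics: list[FlicRecord],
    truth: SimTruth,
    config: SimConfig,
    paralogs: Optional[dict[str, str]] = None,
    coamplify_paralogs: bool = False,
) -> dict[str, PanelGenotypes]:
    """Draw HWE panel genotypes and emit per-individual IUPAC consensus.

    With ``coamplify_paralogs`` the amplicon co-amplifies the paralog, so
    every paralog fixed difference appears heterozygous in every
    individual — the paralogous-sequence-variant (PSV) signature.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    panel_ids = [f"IND{j:02d}" for j in range(config.panel_size)]
    ext_ids = [f"EXT{j:02d}" for j in range(config.extension_size)]
    panels: dict[str, PanelGenotypes] = {}
    for record in flics:
        gene = truth.genes[record.accession]
        by_pos = {v.position: v for v in gene.planted}
        fixed = set(gene.fixed_differences) if coamplify_paralogs else set()
        pseq = (paralogs or {}).get(record.accession) if coamplify_paralogs else None
        calls: list[str] = []
        ext_calls: list[str] = []
        for ind in panel_ids + ext_ids:
            row = list(record.sequence)
            diplotype: list[tuple[str, str]] = []
            for pos, variant in by_pos.items():
                gt = _draw_diplotype(rng, variant)
                diplotype.append(gt)
                alleles = set(gt)
                if pseq is not None:
                    alleles.add(pseq[pos])
                row[pos] = _consensus_call(alleles)
            for pos in fixed:
                if pos in by_pos:
                    continue
                row[pos] = _consensus_call({record.sequence[pos], pseq[pos]})
            gene.diplotypes[ind] = diplotype
            if ind.startswith("EXT"):
                ext_calls.append("".join(row))
            else:
                calls.append("".join(row))
        panels[record.accession] = PanelGenotypes(
            amplicon_id=record.accession,
            individuals=list(panel_ids),
            calls=calls,
            extension_individuals=list(ext_ids),
            extension_calls=ext_calls,
            reference=record.sequence,
        ).validate()
    return panels


# ---------------------------------------------------------------------------
# ESTs
# ---------------------------------------------------------------------------


def _haplotype(rng: np.random.Generator, seq: str, planted: list[PlantedVariant]) -> str:
    """One allelic transcript: each planted allele drawn at its MAF."""
    out = list(seq)
    for v in planted:
        if rng.random() < v.maf:
            out[v.position] = "" if v.alt == "-" else v.alt
    return "".join(out)


def simulate_ests(
    flics: list[FlicRecord],
    paralogs: dict[str, str],
    truth: SimTruth,
    config: SimConfig,
) -> list[tuple[str, str]]:
    """Error-bearing EST fragments of allelic or paralogous transcripts.

    Per-base substitution errors at ``est_error_rate``; fragment start
    uniform, length uniform in ``est_len_range`` (clipped, with a warning,
    if it exceeds the transcript).  Source labels go into ``truth``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    ests: list[tuple[str, str]] = []
    clipped = False
    for record in flics:
        gene = truth.genes[record.accession]
        for k in range(config.est_per_gene):
            use_paralog = (
                record.accession in paralogs
                and rng.random() < config.est_paralog_fraction
            )
            if use_paralog:
                source_seq = paralogs[record.accession]
                source = "paralog"
            else:
                source_seq = _haplotype(rng, record.sequence, gene.planted)
                source = "allelic"
            length = int(rng.integers(config.est_len_range[0], config.est_len_range[1] + 1))
            if length > len(source_seq):
                length = len(source_seq)
                clipped = True
            start = int(rng.integers(0, len(source_seq) - length + 1))
            frag = list(source_seq[start : start + length])
            n_err = 0
            if config.est_error_rate > 0:
                hits = np.nonzero(rng.random(length) < config.est_error_rate)[0]
                for i in hits:
                    frag[i] = _mutate_base(rng, frag[i])
                n_err = len(hits)
            if config.est_indel_errors and config.est_error_rate > 0:
                # rare single-base deletion errors, half the substitution rate
                hits = np.nonzero(rng.random(len(frag)) < config.est_error_rate / 2)[0]
                for i in sorted(hits, reverse=True):
                    del frag[i]
                n_err += len(hits)
            est_id = f"{record.accession}.est{k:03d}"
            ests.append((est_id, "".join(frag)))
            truth.est_sources[est_id] = {
                "gene": record.accession,
                "source": source,
                "start": start,
                "length": length,
                "n_errors": int(n_err),
            }
    if clipped:
        warnings.warn("est_len_range exceeded transcript length; fragments clipped")
    return ests
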