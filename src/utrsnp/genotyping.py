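"""Panel genotyping: amplicon QC, site calling, SNP/DIP validation, PSV exclusion.

The validation panel is a small diploid population (default 10
individuals).  Per amplicon, each individual contributes one consensus
string; heterozygous positions carry IUPAC ambiguity codes.  Validation
follows three rules:

* amplicons whose two-individual screen shows five or more heterozygous
  sites are dropped (multi-site heterozygosity indicates co-amplified
  paralogs or poor quality);
* a variant is approved only if the rare allele is carried by at least
  two individuals; a single carrier triggers an extension typing of five
  more individuals and a re-test on the pooled panel;
* a site heterozygous in every individual is a paralogous sequence
  variant (PSV), not a SNP: a fixed difference between co-amplified
  paralogs.  Under Hardy-Weinberg equilibrium the all-heterozygote
  pattern has probability (2pq)^n <= 0.5^n — about 0.001 for n = 10 — so
  total heterozygosity is a significant heterozygote excess.

CDS variants are annotated as synonymous/missense/nonsense by codon
translation; CDS DIPs are frameshifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Optional

from Bio.Data import CodonTable

from .core import (
    FlicRecord,
    PanelGenotypes,
    ValidationError,
    VariantSite,
    genotype_from_call,
    iupac_decode,
)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate_codon(codon: str) -> str:
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


# ---------------------------------------------------------------------------
# Amplicon QC
# ---------------------------------------------------------------------------


@dataclass
class AmpliconQc:
    amplicon_id: str
    screen_individuals: list[str]
    het_site_count: int
    verdict: str  # "pass" | "fail_multi_het" | "fail_no_product" | "fail_quality"


def qc_amplicon(
    panel: PanelGenotypes,
    screen_ids: Optional[list[str]] = None,
    threshold: int = 5,
) -> AmpliconQc:
    """Initial two-individual screen: count heterozygous columns, pooled.

    The count is the union of heterozygous columns over the screen
    individuals; ``threshold`` or more fails the amplicon.  All-N screen
    sequences fail on quality.
    """
    panel.validate()
    if screen_ids is None:
        screen_ids = panel.individuals[:2]
    if not screen_ids:
        raise ValidationError("empty screen set")
    unknown = set(screen_ids) - set(panel.individuals)
    if unknown:
        raise ValidationError(f"screen ids not in panel: {sorted(unknown)}")
    rows = [panel.calls[panel.individuals.index(i)] for i in screen_ids]
    if all(set(row) <= {"N"} for row in rows):
        return AmpliconQc(panel.amplicon_id, list(screen_ids), 0, "fail_quality")
    het_columns = set()
    for row in rows:
        for pos, call in enumerate(row):
            if call == "N":
                continue
            if len(iupac_decode(call, position=pos)) == 2:
                het_columns.add(pos)
    count = len(het_columns)
    verdict = "fail_multi_het" if count >= threshold else "pass"
    return AmpliconQc(panel.amplicon_id, list(screen_ids), count, verdict)


# ---------------------------------------------------------------------------
# Site calling
# ---------------------------------------------------------------------------


def _column_site(
    amplicon_id: str,
    position: int,
    calls: list[str],
    reference: Optional[str],
) -> Optional[VariantSite]:
    """Decode one aligned column; None if monomorphic or no-call only.

    Raises :class:`ValidationError` for columns implying more than two
    alleles (flagged upstream, excluded from the bi-allelic pipeline).
    """
    genotypes = []
    for call in calls:
        gt = genotype_from_call(call[position], position=position)
        if gt is not None:
            genotypes.append(gt)
    alleles = sorted({a for gt in genotypes for a in gt})
    if len(alleles) < 2:
        return None
    if len(alleles) > 2:
        raise ValidationError(
            f"{amplicon_id}: column {position} has {len(alleles)} alleles {alleles}"
        )
    a, b = alleles
    if reference is not None and reference[position] in (a, b):
        ref, alt = (a, b) if reference[position] == a else (b, a)
    else:
        # no usable reference: major allele (ties broken lexicographically) is ref
        count_a = sum(gt.count(a) for gt in genotypes)
        ref, alt = (a, b) if 2 * count_a >= 2 * len(genotypes) else (b, a)
    hom_ref = sum(1 for gt in genotypes if gt == (ref, ref))
    hom_alt = sum(1 for gt in genotypes if gt == (alt, alt))
    het = len(genotypes) - hom_ref - hom_alt
    n_ref = 2 * hom_ref + het
    n_alt = 2 * hom_alt + het
    minor_is_alt = n_alt <= n_ref
    carriers = het + (hom_alt if minor_is_alt else hom_ref)
    return VariantSite(
        amplicon_id=amplicon_id,
        position=position,
        ref_allele=ref,
        alt_allele=alt,
        site_class="DIP" if "-" in (ref, alt) else "SNP",
        genotype_counts=(hom_ref, het, hom_alt),
        carriers_of_rare=carriers,
        n_called=len(genotypes),
    )


def call_sites(panel: PanelGenotypes):
    """All bi-allelic variant columns of a panel alignment.

    Returns ``(sites, multi_allelic_positions)``; columns with more than
    two alleles are flagged, not fatal, and excluded from the bi-allelic
    pipeline.
    """
    panel.validate()
    sites: list[VariantSite] = []
    multi: list[int] = []
    for pos in range(panel.length):
        try:
            site = _column_site(panel.amplicon_id, pos, panel.calls, panel.reference)
        except ValidationError:
            multi.append(pos)
            continue
        if site is not None:
            sites.append(site)
    return sites, multi


# ---------------------------------------------------------------------------
# PSV (heterozygote excess) check
# ---------------------------------------------------------------------------


def all_het_probability(n: int, p: float) -> float:
    """P(all n diploid individuals heterozygous) under HWE: (2p(1-p))^n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return (2.0 * p * (1.0 - p)) ** n


def heterozygote_excess_exact(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact P(heterozygote count >= observed | allele counts).

    Sums the conditional probabilities of all genotype tables with the
    observed allele counts and at least the observed number of
    heterozygotes; each table's probability is the standard exact-HWE
    weight  n! / (nAA! nAa! naa!) * 2^nAa * nA! na! / (2n)!.
    """
    n = hom_ref + het + hom_alt
    if n == 0:
        raise ValueError("no called genotypes")
    n_a = 2 * hom_ref + het
    n_b = 2 * hom_alt + het
    total = 0.0
    denom = comb(2 * n, n_a)  # multinomial weights / C(2n, nA) sums to 1
    for h in range(het, min(n_a, n_b) + 1):
        if (n_a - h) % 2:
            continue
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        if aa < 0 or bb < 0 or aa + h + bb != n:
            continue
        weight = (
            comb(n, aa) * comb(n - aa, h) * (2**h)
        )  # n!/(aa! h! bb!) * 2^h
        total += weight / denom
    return total


def psv_check(site: VariantSite, n: Optional[int] = None):
    """Paralogous-sequence-variant test: total heterozygosity in the panel.

    Returns ``(is_psv, all_het_p_max, all_het_p_observed, excess_p)``:
    ``is_psv`` is True iff every called individual is heterozygous;
    ``all_het_p_max`` is (2pq)^n at the maximizing p = 0.5;
    ``all_het_p_observed`` uses the observed allele frequencies; and
    ``excess_p`` is the exact heterozygote-excess probability, reported
    for non-total excess as well.
    """
    hom_ref, het, hom_alt = site.genotype_counts
    n = n if n is not None else hom_ref + het + hom_alt
    if n <= 0:
        raise ValueError("n must be positive")
    called = hom_ref + het + hom_alt
    is_psv = called > 0 and het == called
    p_hat = (2 * hom_ref + het) / (2 * called) if called else 0.5
    return (
        is_psv,
        all_het_probability(n, 0.5),
        all_het_probability(n, p_hat),
        heterozygote_excess_exact(hom_ref, het, hom_alt),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidatedVariant:
    site: VariantSite
    p: float  # ref-allele frequency over called alleles
    q: float
    hw_all_het_probability: float
    excess_probability: float
    status: str
    extension_requested: bool = False
    low_power: bool = False
    region: str = "unknown"  # "UTR3" | "CDS" | "intron" | "unknown"
    cds_effect: str = "not_applicable"


def validate_variant(
    site: VariantSite,
    extension_site: Optional[VariantSite] = None,
    min_carriers: int = 2,
    low_power_n: int = 6,
) -> ValidatedVariant:
    """Apply the carrier and PSV rules to one site.

    PSV exclusion comes first; then the rare allele must be carried by at
    least ``min_carriers`` individuals.  A single carrier yields status
    ``unconfirmed_single_carrier`` with an extension request; when the
    pooled 15-individual re-typing is supplied as ``extension_site`` (the
    same column called on primary + extension individuals), both rules
    are re-applied to the pooled panel.
    """
    target = site
    if site.carriers_of_rare == 1 and extension_site is not None:
        target = extension_site
    hom_ref, het, hom_alt = target.genotype_counts
    called = hom_ref + het + hom_alt
    is_psv, p_max, _p_obs, excess_p = psv_check(target)
    p = (2 * hom_ref + het) / (2 * called) if called else 0.0
    if is_psv:
        status = "psv_excluded"
    elif target.carriers_of_rare >= min_carriers:
        status = "validated"
    elif target.carriers_of_rare == 1:
        status = "unconfirmed_single_carrier"
    else:
        status = "monomorphic"
    target.status = status
    return ValidatedVariant(
        site=target,
        p=p,
        q=1.0 - p,
        hw_all_het_probability=p_max,
        excess_probability=excess_p,
        status=status,
        extension_requested=(
            status == "unconfirmed_single_carrier" and extension_site is None
        ),
        low_power=called < low_power_n,
    )


# ---------------------------------------------------------------------------
# Region / CDS-effect annotation
# ---------------------------------------------------------------------------


def annotate_region(variant: ValidatedVariant, record: FlicRecord) -> ValidatedVariant:
    """Locate the variant on the transcript and classify its CDS effect.

    CDS SNPs are translated both ways under the standard genetic code:
    same residue = synonymous, new stop = nonsense, otherwise missense.
    CDS DIPs shift the reading frame.
    """
    pos = variant.site.position
    if not 0 <= pos < len(record.sequence):
        raise ValidationError(
            f"{record.accession}: variant position {pos} outside record"
        )
    if pos in record.utr3:
        variant.region = "UTR3"
        variant.cds_effect = "not_applicable"
        return variant
    if record.cds is None or pos not in record.cds:
        variant.region = "unknown"
        variant.cds_effect = "not_applicable"
        return variant
    variant.region = "CDS"
    if variant.site.site_class == "DIP":
        variant.cds_effect = "frameshift"
        return variant
    offset = pos - record.cds.start
    codon_start = record.cds.start + 3 * (offset // 3)
    codon = record.sequence[codon_start : codon_start + 3]
    if len(codon) < 3:
        variant.cds_effect = "not_applicable"  # truncated terminal codon
        return variant
    within = pos - codon_start
    ref_aa = _translate_codon(codon)
    # the reference base at the site may be either observed allele
    alleles = {variant.site.ref_allele, variant.site.alt_allele}
    alleles.discard(record.sequence[pos])
    alt = alleles.pop() if alleles else variant.site.alt_allele
    alt_codon = codon[:within] + alt + codon[within + 1 :]
    alt_aa = _translate_codon(alt_codon)
    if alt_aa == ref_aa:
        variant.cds_effect = "synonymous"
    elif alt_aa == "*" or ref_aa == "*":
        variant.cds_effect = "nonsense"
    else:
        variant.cds_effect = "missense"
    return variant


# ---------------------------------------------------------------------------
# Pipeline convenience + VCF/TSV output
# ---------------------------------------------------------------------------


@dataclass
class PanelResult:
    qc: AmpliconQc
    variants: list[ValidatedVariant] = field(default_factory=list)
    multi_allelic_positions: list[int] = field(default_factory=list)


def genotype_panel(
    panel: PanelGenotypes,
    record: Optional[FlicRecord] = None,
    qc_threshold: int = 5,
    use_extension: bool = True,
) -> PanelResult:
    """QC, call, validate and annotate one amplicon's panel."""
    qc = qc_amplicon(panel, threshold=qc_threshold)
    result = PanelResult(qc=qc)
    if qc.verdict != "pass":
        return result
    sites, multi = call_sites(panel)
    result.multi_allelic_positions = multi
    pooled_sites = None
    for site in sites:
        extension_site = None
        if (
            use_extension
            and site.carriers_of_rare == 1
            and panel.extension_individuals
        ):
            if pooled_sites is None:
                pooled, _ = call_sites(panel.pooled())
                pooled_sites = {s.position: s for s in pooled}
            extension_site = pooled_sites.get(site.position)
        variant = validate_variant(site, extension_site=extension_site)
        if record is not None:
            annotate_region(variant, record)
        result.variants.append(variant)
    return result


def write_vcf(results: dict[str, PanelResult], panels: dict[str, PanelGenotypes], path,
              contig_lengths: Optional[dict[str, int]] = None) -> None:
    """Validated variants as VCF 4.2 (1-based positions, per-individual GT).

    DIPs are written with an anchor-base REF/ALT pair when the reference
    row is available (VCF cannot represent a bare '-').
    """
    individuals: list[str] = []
    for panel in panels.values():
        for ind in panel.individuals:
            if ind not in individuals:
                individuals.append(ind)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=REGION,Number=1,Type=String,Description="Transcript region">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="CDS effect">',
        '##INFO=<ID=CARRIERS,Number=1,Type=Integer,Description="Rare-allele carriers">',
        '##INFO=<ID=ALLHET_P,Number=1,Type=Float,Description="P(all het) under HWE at p=0.5">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for amplicon_id in sorted(results):
        length = (contig_lengths or {}).get(amplicon_id)
        if length is None and panels[amplicon_id].reference is not None:
            length = len(panels[amplicon_id].reference)
        if length is not None:
            lines.append(f"##contig=<ID={amplicon_id},length={length}>")
        else:
            lines.append(f"##contig=<ID={amplicon_id}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(individuals)
    )
    for amplicon_id in sorted(results):
        result = results[amplicon_id]
        panel = panels[amplicon_id]
        for variant in result.variants:
            site = variant.site
            pos = site.position + 1
            ref, alt = site.ref_allele, site.alt_allele
            if site.site_class == "DIP":
                if panel.reference is None or site.position == 0:
                    continue  # no anchor base available
                anchor = panel.reference[site.position - 1]
                pos -= 1
                if alt == "-":
                    ref, alt = anchor + ref, anchor
                else:
                    ref, alt = anchor, anchor + alt
            info = (
                f"REGION={variant.region};EFFECT={variant.cds_effect};"
                f"CARRIERS={site.carriers_of_rare};"
                f"ALLHET_P={variant.hw_all_het_probability:.6g}"
            )
            filt = "PASS" if variant.status == "validated" else variant.status
            gts = []
            for ind in individuals:
                if ind not in panel.individuals:
                    gts.append("./.")
                    continue
                call = panel.calls[panel.individuals.index(ind)][site.position]
                gt = genotype_from_call(call)
                if gt is None:
                    gts.append("./.")
                elif gt == (site.ref_allele, site.ref_allele):
                    gts.append("0/0")
                elif gt == (site.alt_allele, site.alt_allele):
                    gts.append("1/1")
                else:
                    gts.append("0/1")
            lines.append(
                f"{amplicon_id}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}\tGT\t"
                + "\t".join(gts)
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def variants_to_rows(results: dict[str, PanelResult]) -> list[dict]:
    """Flat per-variant records (1-based positions) for TSV/DataFrame output."""
    rows = []
    for amplicon_id in sorted(results):
        for v in results[amplicon_id].variants:
            s = v.site
            rows.append(
                {
                    "amplicon_id": amplicon_id,
                    "position": s.position + 1,
                    "ref": s.ref_allele,
                    "alt": s.alt_allele,
                    "class": s.site_class,
                    "hom_ref": s.genotype_counts[0],
                    "het": s.genotype_counts[1],
                    "hom_alt": s.genotype_counts[2],
                    "carriers": s.carriers_of_rare,
                    "p_ref": round(v.p, 6),
                    "status": v.status,
                    "region": v.region,
                    "cds_effect": v.cds_effect,
                    "all_het_p": v.hw_all_het_probability,
                    "excess_p": v.excess_probability,
                }
            )
    return rows
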