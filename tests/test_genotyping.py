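"""Panel genotyping: QC, site calling, carrier/PSV validation, CDS effects."""

import itertools
import math
from math import comb

import numpy as np
import pytest
from Bio.Seq import Seq

from utrsnp.core import FlicRecord, Interval, PanelGenotypes, ValidationError, VariantSite
from utrsnp.genotyping import (
    all_het_probability,
    annotate_region,
    call_sites,
    genotype_panel,
    heterozygote_excess_exact,
    psv_check,
    qc_amplicon,
    validate_variant,
    variants_to_rows,
    write_vcf,
)
from utrsnp.simulate import SimConfig, simulate_panel, simulate_targets


def _panel(columns, n=10, amplicon_id="AMP", reference=None, ext_columns=None):
    """Build a panel from per-column call strings (one char per individual)."""
    inds = [f"I{j:02d}" for j in range(n)]
    calls = ["".join(col[j] for col in columns) for j in range(n)]
    ext_inds, ext_calls = [], []
    if ext_columns is not None:
        m = len(ext_columns[0])
        ext_inds = [f"E{j}" for j in range(m)]
        ext_calls = ["".join(col[j] for col in ext_columns) for j in range(m)]
    return PanelGenotypes(
        amplicon_id, inds, calls, ext_inds, ext_calls, reference=reference
    ).validate()


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def _screen_panel(het_sites, length=20):
    cols = []
    for i in range(length):
        if i < het_sites:
            cols.append("RR" + "A" * 8)
        else:
            cols.append("A" * 10)
    return _panel(cols)


@pytest.mark.parametrize("het_sites,verdict", [(5, "fail_multi_het"), (4, "pass"), (6, "fail_multi_het")])
def test_qc_multi_het_threshold(het_sites, verdict):
    """Five or more heterozygous sites in the two-individual screen fail."""
    qc = qc_amplicon(_screen_panel(het_sites))
    assert qc.het_site_count == het_sites
    assert qc.verdict == verdict


def test_qc_all_n_fails_quality():
    panel = _panel(["N" * 10] * 8)
    assert qc_amplicon(panel).verdict == "fail_quality"


def test_qc_empty_screen_is_error():
    with pytest.raises(ValidationError, match="screen"):
        qc_amplicon(_screen_panel(0), screen_ids=[])


# ---------------------------------------------------------------------------
# Site calling
# ---------------------------------------------------------------------------


def test_call_sites_decodes_het_column():
    """7 individuals 'A' + 3 'R' -> A/G site, counts (7,3,0), 3 carriers."""
    panel = _panel(["A" * 7 + "R" * 3])
    sites, multi = call_sites(panel)
    assert multi == []
    (site,) = sites
    assert (site.ref_allele, site.alt_allele) == ("A", "G")
    assert site.genotype_counts == (7, 3, 0)
    assert site.carriers_of_rare == 3
    assert site.site_class == "SNP"


def test_call_sites_monomorphic_column_skipped():
    assert call_sites(_panel(["C" * 10]))[0] == []


def test_call_sites_flags_multiallelic():
    panel = _panel(["A" * 4 + "C" * 3 + "G" * 3])
    sites, multi = call_sites(panel)
    assert sites == [] and multi == [0]


def test_call_sites_dip_column():
    """Gap alleles: hom-deletion '-', het lowercase; site class DIP."""
    panel = _panel(["T" * 6 + "t" * 3 + "-"], reference="T")
    (site,), _ = call_sites(panel)
    assert site.site_class == "DIP"
    assert (site.ref_allele, site.alt_allele) == ("T", "-")
    assert site.genotype_counts == (6, 3, 1)
    assert site.carriers_of_rare == 4


def test_call_sites_n_calls_are_missing():
    panel = _panel(["A" * 5 + "R" * 3 + "N" * 2])
    (site,), _ = call_sites(panel)
    assert site.n_called == 8
    assert site.genotype_counts == (5, 3, 0)


# ---------------------------------------------------------------------------
# Carrier-rule validation
# ---------------------------------------------------------------------------


def _site(hom_ref, het, hom_alt, **kw):
    n_ref = 2 * hom_ref + het
    n_alt = 2 * hom_alt + het
    carriers = het + (hom_alt if n_alt <= n_ref else hom_ref)
    defaults = dict(
        amplicon_id="AMP",
        position=0,
        ref_allele="A",
        alt_allele="G",
        site_class="SNP",
        genotype_counts=(hom_ref, het, hom_alt),
        carriers_of_rare=carriers,
        n_called=hom_ref + het + hom_alt,
    )
    defaults.update(kw)
    return VariantSite(**defaults)


def test_two_carriers_validate():
    v = validate_variant(_site(8, 2, 0))
    assert v.status == "validated"
    assert v.p == pytest.approx(0.9)


def test_single_carrier_requests_extension():
    v = validate_variant(_site(9, 1, 0))
    assert v.status == "unconfirmed_single_carrier"
    assert v.extension_requested


def test_single_carrier_confirmed_by_pooled_extension():
    """One carrier in 10, plus one more among the 5 extension individuals:
    the pooled 15-individual panel has 2 carriers -> validated."""
    pooled = _site(13, 2, 0)
    v = validate_variant(_site(9, 1, 0), extension_site=pooled)
    assert v.status == "validated"
    assert not v.extension_requested


def test_extension_pipeline_end_to_end():
    """genotype_panel pools the extension panel when the primary panel has a
    single carrier."""
    cols = ["A" * 9 + "R"]
    ext = ["RAAAA"]
    panel = _panel(cols, ext_columns=ext, reference="A")
    result = genotype_panel(panel)
    (v,) = result.variants
    assert v.status == "validated"
    assert v.site.genotype_counts == (13, 2, 0)


# ---------------------------------------------------------------------------
# PSV / heterozygote excess
# ---------------------------------------------------------------------------


def test_all_heterozygous_panel_is_psv():
    """(2pq)^10 at p = 0.5 is 0.5^10 = 0.000977 ~ 0.001."""
    is_psv, p_max, p_obs, excess = psv_check(_site(0, 10, 0))
    assert is_psv
    assert p_max == pytest.approx(0.5**10)
    assert p_obs == pytest.approx(0.5**10)
    assert excess < 0.01


def test_partial_heterozygosity_is_not_psv():
    is_psv, *_ = psv_check(_site(5, 5, 0))
    assert not is_psv


def test_psv_excluded_before_carrier_rule():
    v = validate_variant(_site(0, 10, 0))
    assert v.status == "psv_excluded"


def test_all_het_probability_maximized_at_half():
    grid = np.linspace(0, 1, 101)
    values = [all_het_probability(10, p) for p in grid]
    assert max(values) == pytest.approx(all_het_probability(10, 0.5))
    assert all_het_probability(10, 0.0) == 0.0
    assert all_het_probability(1, 0.5) == 0.5


def _excess_oracle(hom_ref, het, hom_alt):
    """Exact heterozygote-excess probability by brute-force enumeration of
    allele arrangements: place the minor alleles among 2n slots, pair
    consecutive slots into individuals, count arrangements with at least
    the observed number of heterozygous pairs."""
    n = hom_ref + het + hom_alt
    n_minor = min(2 * hom_ref + het, 2 * hom_alt + het)
    slots = 2 * n
    hits = total = 0
    for positions in itertools.combinations(range(slots), n_minor):
        chosen = set(positions)
        h = sum((2 * i in chosen) != (2 * i + 1 in chosen) for i in range(n))
        hits += h >= het
        total += 1
    return hits / total


@pytest.mark.parametrize("counts", [(1, 8, 1), (3, 6, 1), (2, 5, 3), (0, 10, 0)])
def test_heterozygote_excess_matches_enumeration(counts):
    expected = _excess_oracle(*counts)
    assert heterozygote_excess_exact(*counts) == pytest.approx(expected, rel=1e-9)


def test_heterozygote_excess_distribution_sums_to_one():
    # P(het >= 0) is the whole conditional distribution
    assert heterozygote_excess_exact(5, 0, 5) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Region and CDS-effect annotation
# ---------------------------------------------------------------------------


def _variant_at(record, pos, alt):
    ref = record.sequence[pos]
    site = _site(8, 2, 0, position=pos, ref_allele=ref, alt_allele=alt,
                 site_class="DIP" if alt == "-" else "SNP")
    return validate_variant(site)


def test_synonymous_and_missense_classification():
    # CDS: ATG | GCA | TAA ; GCA (Ala) third position A->G is synonymous,
    # second position C->A (GCA->GAA, Ala->Glu) is missense.
    seq = "ATGGCATAA" + "C" + "ACGTACGTAC" * 5
    rec = FlicRecord("R", seq, cds=Interval(0, 9), utr3=Interval(10, 60)).validate()
    v_syn = annotate_region(_variant_at(rec, 5, "G"), rec)
    assert (v_syn.region, v_syn.cds_effect) == ("CDS", "synonymous")
    v_mis = annotate_region(_variant_at(rec, 4, "A"), rec)
    assert (v_mis.region, v_mis.cds_effect) == ("CDS", "missense")


def test_nonsense_and_frameshift_classification():
    # TGG (Trp) -> TGA (stop) at codon 2; any CDS DIP is a frameshift
    seq = "ATGTGGTAA" + "C" + "ACGTACGTAC" * 5
    rec = FlicRecord("R", seq, cds=Interval(0, 9), utr3=Interval(10, 60)).validate()
    v_non = annotate_region(_variant_at(rec, 5, "A"), rec)
    assert v_non.cds_effect == "nonsense"
    v_fs = annotate_region(_variant_at(rec, 4, "-"), rec)
    assert v_fs.cds_effect == "frameshift"


def test_utr3_variant_region():
    seq = "ATGGCATAA" + "C" + "ACGTACGTAC" * 5
    rec = FlicRecord("R", seq, cds=Interval(0, 9), utr3=Interval(10, 60)).validate()
    v = annotate_region(_variant_at(rec, 25, "A" if seq[25] != "A" else "C"), rec)
    assert (v.region, v.cds_effect) == ("UTR3", "not_applicable")


def test_annotation_position_outside_record_is_error():
    seq = "ATGGCATAA" + "C" + "ACGTACGTAC" * 5
    rec = FlicRecord("R", seq, cds=Interval(0, 9), utr3=Interval(10, 60)).validate()
    stray = validate_variant(_site(8, 2, 0, position=999))
    with pytest.raises(ValidationError):
        annotate_region(stray, rec)


def test_cds_effect_agrees_with_translation_oracle():
    """Every CDS codon position: classification matches translating the
    whole CDS both ways with Biopython and comparing protein strings."""
    rng = np.random.default_rng(55)
    cds = "ATG" + "".join(
        "ACGT"[i] for i in rng.integers(0, 4, 60)
    ) + "TAA"
    seq = cds + "ACGTACGTAC" * 3
    rec = FlicRecord("R", seq, cds=Interval(0, len(cds)), utr3=Interval(len(cds), len(seq))).validate()
    for pos in range(len(cds)):
        ref = seq[pos]
        alt = "ACGT"[(("ACGT".index(ref)) + 1) % 4]
        got = annotate_region(_variant_at(rec, pos, alt), rec).cds_effect
        mutated = cds[:pos] + alt + cds[pos + 1 :]
        prot_ref = str(Seq(cds).translate())
        prot_alt = str(Seq(mutated).translate())
        codon_idx = pos // 3
        if prot_ref[codon_idx] == prot_alt[codon_idx]:
            expected = "synonymous"
        elif "*" in (prot_ref[codon_idx], prot_alt[codon_idx]):
            expected = "nonsense"
        else:
            expected = "missense"
        assert got == expected, (pos, cds[3 * codon_idx : 3 * codon_idx + 3])


# ---------------------------------------------------------------------------
# Simulation-backed soundness
# ---------------------------------------------------------------------------


def test_psv_flag_rate_on_true_snps():
    """True SNPs are flagged PSV only when the panel genuinely drew
    all-heterozygous genotypes: rate ~ (2pq)^n over 2000 replicates."""
    rng = np.random.default_rng(60)
    n, q, reps = 10, 0.5, 2000
    flagged = 0
    for _ in range(reps):
        gts = rng.random((n, 2)) < q
        het = (gts[:, 0] != gts[:, 1]).sum()
        hom_alt = (gts.all(axis=1)).sum()
        hom_ref = n - het - hom_alt
        if het == n:
            site = _site(0, n, 0)
        elif het + hom_alt == 0:
            continue  # monomorphic draw: no site is called
        else:
            site = _site(hom_ref, het, hom_alt)
        flagged += psv_check(site)[0]
    p = all_het_probability(n, q)
    se = math.sqrt(reps * p * (1 - p))
    assert abs(flagged - reps * p) < 3 * se + 1


def test_coamplified_fixed_differences_always_flagged():
    """Error-free PSV-mode simulation: every paralog fixed difference is
    heterozygous in all individuals and flagged by the PSV rule."""
    config = SimConfig(seed=61, n_genes=5, paralog_fraction=1.0)
    flics, paralogs, truth = simulate_targets(config)
    panels = simulate_panel(flics, truth, config, paralogs=paralogs, coamplify_paralogs=True)
    n_checked = 0
    for rec in flics:
        gene = truth.genes[rec.accession]
        planted = {v.position for v in gene.planted}
        sites, _ = call_sites(panels[rec.accession])
        by_pos = {s.position: s for s in sites}
        for pos in gene.fixed_differences:
            if pos in planted:
                continue
            assert psv_check(by_pos[pos])[0]
            n_checked += 1
    assert n_checked > 0


def test_validation_power_matches_exact_enumeration():
    """P(validated | MAF, n=10) from simulation matches exact trinomial
    enumeration of the carrier and PSV rules, within 3 s.e."""

    def exact_p_validated(q, n=10):
        p = 1 - q
        total = 0.0
        for het in range(n + 1):
            for hom_alt in range(n - het + 1):
                hom_ref = n - het - hom_alt
                w = (
                    math.comb(n, het)
                    * math.comb(n - het, hom_alt)
                    * (2 * p * q) ** het
                    * (q * q) ** hom_alt
                    * (p * p) ** hom_ref
                )
                n_ref, n_alt = 2 * hom_ref + het, 2 * hom_alt + het
                carriers = het + (hom_alt if n_alt <= n_ref else hom_ref)
                if carriers >= 2 and het != n and (het or hom_alt):
                    total += w
        return total

    rng = np.random.default_rng(62)
    reps = 500
    for q in (0.05, 0.1, 0.25, 0.5):
        validated = 0
        for _ in range(reps):
            gts = rng.random((10, 2)) < q
            het = int((gts[:, 0] != gts[:, 1]).sum())
            hom_alt = int(gts.all(axis=1).sum())
            hom_ref = 10 - het - hom_alt
            if het == 0 and hom_alt == 0:
                continue
            v = validate_variant(_site(hom_ref, het, hom_alt))
            validated += v.status == "validated"
        p_exact = exact_p_validated(q)
        se = math.sqrt(reps * p_exact * (1 - p_exact))
        assert abs(validated - reps * p_exact) < 3 * se + 1, q


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------


def test_vcf_output_parses_with_pysam(tmp_path):
    pysam = pytest.importorskip("pysam")
    config = SimConfig(seed=63, n_genes=3, maf_distribution=(0.25, 0.5))
    flics, paralogs, truth = simulate_targets(config)
    panels = simulate_panel(flics, truth, config, paralogs=paralogs)
    results = {
        rec.accession: genotype_panel(panels[rec.accession], rec) for rec in flics
    }
    out = tmp_path / "out.vcf"
    write_vcf(results, panels, out)
    variants = list(pysam.VariantFile(str(out)))
    expected = sum(
        1 for r in results.values() for v in r.variants
        if v.site.site_class == "SNP" or v.site.position > 0
    )
    assert len(variants) == expected
    for var in variants:
        assert var.info["CARRIERS"] >= 1
        assert len(var.samples) == 10
    rows = variants_to_rows(results)
    assert len(rows) == sum(len(r.variants) for r in results.values())
    assert all(row["position"] >= 1 for row in rows)
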