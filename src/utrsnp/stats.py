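"""Summary statistics: stage success rates, SNP density, 2x2 method comparison.

Success-rate accounting follows the pipeline stages of each discovery
strategy.  The 3'UTR-primed strategy has two stages (initial PCR +
sequencing screen, then panel genotyping); the in silico strategy adds a
prior candidate-mining stage, and its initial-PCR rate is computed
against candidates rather than genes (one amplicon per candidate).
Rates are printed half-up at two decimals alongside their fractions;
undefined rates (zero denominator) print as "-".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd
from scipy import stats as sps


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (what a printed table uses, not banker's)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Rate:
    name: str
    numerator: Optional[int]
    denominator: Optional[int]

    @property
    def value(self) -> Optional[float]:
        if not self.denominator or self.numerator is None:
            return None
        return round_half_up(self.numerator / self.denominator, 2)

    @property
    def display(self) -> str:
        if self.value is None:
            return "-"
        return f"{self.value:.2f} ({self.numerator}/{self.denominator})"


@dataclass
class StageCounts:
    """Stage-by-stage outcome counts for one discovery strategy."""

    method: str  # "utr_primed" | "insilico"
    genes_tested: int
    initial_pcr_pass: int
    snps_discovered_fragments: int
    genes_with_snp: int
    candidates_found: Optional[int] = None  # insilico only

    def validate(self) -> "StageCounts":
        counts = [
            self.genes_tested,
            self.initial_pcr_pass,
            self.snps_discovered_fragments,
            self.genes_with_snp,
        ]
        if self.candidates_found is not None:
            counts.append(self.candidates_found)
        if any(c < 0 for c in counts):
            raise ValueError("negative stage count")
        if self.snps_discovered_fragments < self.genes_with_snp - 0:
            pass  # one gene may carry several fragments; no constraint here
        if self.initial_pcr_pass > self.genes_tested and self.candidates_found is None:
            raise ValueError("initial_pcr_pass exceeds genes_tested")
        if (
            self.candidates_found is not None
            and self.initial_pcr_pass > self.candidates_found
        ):
            raise ValueError("initial_pcr_pass exceeds candidates_found")
        if self.snps_discovered_fragments > self.initial_pcr_pass:
            raise ValueError("snps_discovered_fragments exceeds initial_pcr_pass")
        if self.genes_with_snp > self.genes_tested:
            raise ValueError("genes_with_snp exceeds genes_tested")
        return self


def success_rates(counts: StageCounts) -> dict[str, Rate]:
    """The stage rate table for one strategy.

    * candidate rate: candidates / genes tested (mining strategies only);
    * initial PCR + sequencing rate: passes / genes for the UTR-primed
      strategy, passes / candidates where a mining stage preceded it;
    * discovery rate: fragments yielding a variant / fragments genotyped;
    * overall success: genes yielding a variant / genes tested.
    """
    counts.validate()
    if counts.candidates_found is not None:
        candidate = Rate("candidate_rate", counts.candidates_found, counts.genes_tested)
        initial = Rate(
            "initial_pcr_rate", counts.initial_pcr_pass, counts.candidates_found
        )
    else:
        candidate = Rate("candidate_rate", None, None)
        initial = Rate("initial_pcr_rate", counts.initial_pcr_pass, counts.genes_tested)
    return {
        "candidate_rate": candidate,
        "initial_pcr_rate": initial,
        "discovery_rate": Rate(
            "discovery_rate", counts.snps_discovered_fragments, counts.initial_pcr_pass
        ),
        "overall_success_rate": Rate(
            "overall_success_rate", counts.genes_with_snp, counts.genes_tested
        ),
    }


def success_table(*counts: StageCounts) -> pd.DataFrame:
    """Strategies side by side, one row per rate, printed like a report table."""
    data = {}
    for c in counts:
        rates = success_rates(c)
        col = {"genes_tested": str(c.genes_tested)}
        col.update({name: r.display for name, r in rates.items()})
        data[c.method] = col
    return pd.DataFrame(data)


def conversion_rate(n_validated: int, n_genotyped: int) -> float:
    """Percent of genotyped putative SNPs confirmed polymorphic (half-up)."""
    if n_genotyped <= 0:
        raise ValueError("n_genotyped must be positive")
    return round_half_up(100.0 * n_validated / n_genotyped, 0)


@dataclass
class DensityInput:
    total_bp_scanned: int
    n_snps: int
    n_dips: int

    def validate(self) -> "DensityInput":
        if self.total_bp_scanned <= 0:
            raise ValueError("total_bp_scanned must be positive")
        if self.n_snps < 0 or self.n_dips < 0:
            raise ValueError("negative variant count")
        return self


def snp_density(d: DensityInput):
    """Base pairs per bi-allelic polymorphism: raw and half-up to nearest 10.

    Returns ``(raw, rounded)``; ``(None, None)`` when no polymorphisms
    were found (density undefined).
    """
    d.validate()
    n = d.n_snps + d.n_dips
    if n == 0:
        return None, None
    raw = d.total_bp_scanned / n
    rounded = int(round_half_up(raw / 10.0, 0) * 10)
    return raw, rounded


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    statistic_yates: float
    p_value_yates: float
    fisher_two_sided: float
    fisher_one_sided: float  # alternative: first row enriched in first column


def chi2_2x2(a: int, b: int, c: int, d: int) -> Chi2Result:
    """Pearson chi-square on a 2x2 table (no continuity correction), with
    Yates-corrected and Fisher exact companions.

    Table layout: rows are the two groups, columns success/failure —
    ``[[a, b], [c, d]]``.  Both margins must be positive.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin: chi-square undefined")
    det = a * d - b * c
    denom = r1 * r2 * c1 * c2
    statistic = n * det * det / denom
    yates_num = max(abs(det) - n / 2.0, 0.0)
    statistic_yates = n * yates_num * yates_num / denom
    p = float(sps.chi2.sf(statistic, 1))
    p_yates = float(sps.chi2.sf(statistic_yates, 1))
    fisher_two = float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    fisher_one = float(sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
    return Chi2Result(
        statistic=statistic,
        df=1,
        p_value=p,
        statistic_yates=statistic_yates,
        p_value_yates=p_yates,
        fisher_two_sided=fisher_two,
        fisher_one_sided=fisher_one,
    )


def all_het_probability(n: int, p: float) -> float:
    """(2p(1-p))^n — maximal at p = 0.5; the PSV exclusion p-value."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return (2.0 * p * (1.0 - p)) ** n


def report_markdown(
    utr: StageCounts,
    insilico: StageCounts,
    density: Optional[DensityInput] = None,
) -> str:
    """Assemble the run report: rate table, density, method comparison."""
    table = success_table(utr, insilico)
    lines = ["# SNP discovery report", "", "## Stage success rates", ""]
    lines.append("```")
    lines.append(table.to_string())
    lines.append("```")
    lines.append("")
    if density is not None:
        raw, rounded = snp_density(density)
        if raw is None:
            lines.append("SNP density: undefined (no polymorphisms found)")
        else:
            lines.append(
                f"SNP density: one bi-allelic polymorphism per {rounded} bp "
                f"({density.total_bp_scanned} bp scanned, "
                f"{density.n_snps} SNPs + {density.n_dips} DIPs; raw {raw:.1f})"
            )
        lines.append("")
    res = chi2_2x2(
        utr.genes_with_snp,
        utr.genes_tested - utr.genes_with_snp,
        insilico.genes_with_snp,
        insilico.genes_tested - insilico.genes_with_snp,
    )
    lines.append("## Method comparison (2x2 chi-square)")
    lines.append("")
    lines.append(
        f"chi2 = {res.statistic:.3f} (df 1), p = {res.p_value:.3g}; "
        f"Yates chi2 = {res.statistic_yates:.3f}, p = {res.p_value_yates:.3g}; "
        f"Fisher two-sided p = {res.fisher_two_sided:.3g}, "
        f"one-sided p = {res.fisher_one_sided:.3g}"
    )
    lines.append("")
    return "\n".join(lines)
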