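"""Segregation-distortion tests on inferred gamete genotypes.

Three Pearson chi-square tests per marker, all without continuity
correction and without multiple-testing adjustment (a Bonferroni-adjusted
significance column is emitted alongside for reference):

* ``allele``: M-allele count (2*n_MM + n_AM out of 2n alleles) against 1:1;
* ``hom_excess``: n_AA vs n_MM against 1:1, homozygous gametes only;
* ``genotype_141``: genotype counts against the 1:4:1 random-pairing ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import GameteMatrix
from .inheritance import GenotypeCounts, counts_at


@dataclass
class DistortionResult:
    marker_id: str
    test: str  # allele | hom_excess | genotype_141
    statistic: float
    df: int
    p_value: float
    direction: str  # excess_M | excess_A | none
    delta: float  # observed - 0.5 M-allele frequency
    testable: bool = True
    small_counts: bool = False


def _chisq(observed: np.ndarray, expected: np.ndarray) -> tuple[float, float, int]:
    df = len(observed) - 1
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df)), df


def _direction(delta: float) -> str:
    if delta > 0:
        return "excess_M"
    if delta < 0:
        return "excess_A"
    return "none"


def allele_test(counts: GenotypeCounts, marker_id: str = "") -> DistortionResult:
    """Chi-square test of the M-allele frequency against 0.5 (df = 1)."""
    n_alleles = 2 * counts.n
    if n_alleles == 0:
        return DistortionResult(marker_id, "allele", float("nan"), 1, float("nan"),
                                "none", float("nan"), testable=False)
    m_count = 2 * counts.n_MM + counts.n_AM
    observed = np.array([m_count, n_alleles - m_count], dtype=float)
    expected = np.array([n_alleles / 2.0] * 2)
    stat, p, df = _chisq(observed, expected)
    delta = m_count / n_alleles - 0.5
    direction = _direction(delta) if p < 1.0 and delta != 0 else "none"
    return DistortionResult(marker_id, "allele", stat, df, p, direction, delta)


def hom_excess_test(counts: GenotypeCounts, marker_id: str = "") -> DistortionResult:
    """Chi-square test of n_AA vs n_MM against 1:1, homozygotes only."""
    n_hom = counts.n_AA + counts.n_MM
    m_freq_delta = (
        counts.n_MM / n_hom - 0.5 if n_hom > 0 else float("nan")
    )
    if n_hom == 0:
        return DistortionResult(marker_id, "hom_excess", float("nan"), 1, float("nan"),
                                "none", float("nan"), testable=False)
    observed = np.array([counts.n_MM, counts.n_AA], dtype=float)
    expected = np.array([n_hom / 2.0] * 2)
    stat, p, df = _chisq(observed, expected)
    return DistortionResult(
        marker_id, "hom_excess", stat, df, p, _direction(m_freq_delta), m_freq_delta
    )


def genotype_141_test(counts: GenotypeCounts, marker_id: str = "") -> DistortionResult:
    """Chi-square goodness of fit to the 1:4:1 duplex ratio (df = 2)."""
    if counts.n == 0:
        return DistortionResult(marker_id, "genotype_141", float("nan"), 2, float("nan"),
                                "none", float("nan"), testable=False)
    observed = counts.as_array()
    expected = counts.n * np.array([1.0 / 6.0, 2.0 / 3.0, 1.0 / 6.0])
    stat, p, df = _chisq(observed, expected)
    m_freq = (2 * counts.n_MM + counts.n_AM) / (2 * counts.n)
    delta = m_freq - 0.5
    return DistortionResult(
        marker_id, "genotype_141", stat, df, p, _direction(delta), delta,
        small_counts=bool((expected < 5).any()),
    )


def distortion_table(
    g: GameteMatrix, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All three tests per marker plus a per-chromosome homozygote summary.

    The per-chromosome table classifies each marker by its homozygous-gamete
    test: NDM (no significant deviation at ``alpha``), excess of the M allele
    or excess of the A allele.
    """
    n_tests = g.n_markers
    rows = []
    for j in range(n_tests):
        c = counts_at(g, j)
        mid = g.markers[j].marker_id
        chrom = g.markers[j].chromosome
        for res in (allele_test(c, mid), hom_excess_test(c, mid), genotype_141_test(c, mid)):
            rows.append(
                {
                    "marker_id": mid,
                    "chromosome": chrom,
                    "test": res.test,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "direction": res.direction,
                    "delta": res.delta,
                    "testable": res.testable,
                    "small_counts": res.small_counts,
                    "significant": bool(res.testable and res.p_value < alpha),
                    "significant_bonferroni": bool(
                        res.testable and res.p_value < alpha / max(n_tests, 1)
                    ),
                }
            )
    per_marker = pd.DataFrame(rows)

    chrom_rows = []
    hom = per_marker[per_marker["test"] == "hom_excess"]
    for chrom, sub in hom.groupby("chromosome", sort=False):
        signif = sub["significant"] & sub["testable"]
        excess_m = int((signif & (sub["direction"] == "excess_M")).sum())
        excess_a = int((signif & (sub["direction"] == "excess_A")).sum())
        chrom_rows.append(
            {
                "chromosome": chrom,
                "n_markers": len(sub),
                "NDM": len(sub) - excess_m - excess_a,
                "excess_M": excess_m,
                "excess_A": excess_a,
            }
        )
    per_chromosome = pd.DataFrame(chrom_rows)
    return per_marker, per_chromosome
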