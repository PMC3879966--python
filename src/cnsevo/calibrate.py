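"""Lineage conservation thresholds from one-to-one ortholog coding pairs.

The detection cutoff for a lineage is anchored on how much its
protein-coding genes have diverged between the reference species and the
most diverged member: noncoding alignments at least as conserved as an
average coding gene are unlikely to be neutral leftovers. Two cutoffs are
derived:

* the **whole-coding threshold** — mean percent divergence of the best
  local alignment per ortholog CDS pair;
* the stricter **skip3 threshold** — divergence of the third-codon-skipped,
  per-gene concatenated sequences, removing the mostly synonymous (fastest)
  sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .align import AlignmentHit, ScoringScheme, local_align, percent_divergence

logger = logging.getLogger(__name__)


@dataclass
class ThresholdSpec:
    """Conservation cutoffs for one lineage, with their source statistics."""

    lineage: str
    whole_coding_divergence: float
    whole_coding_sd: float
    skip3_divergence: float
    n_genes: int
    genomic_noncoding_divergence: float | None = None
    min_length: int = 100
    n_excluded: int = 0
    presets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")

    def stricter_presets(self) -> dict[str, float]:
        """Optional stricter cutoffs: mean - 1 SD, and half the mean."""
        return {
            "minus_1sd": max(0.0, self.whole_coding_divergence - self.whole_coding_sd),
            "half": self.whole_coding_divergence / 2.0,
        }


def best_gene_divergences(
    cds_pairs: list[tuple[str, str, str]],
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-5,
    min_coverage: float = 0.3,
) -> tuple[dict[str, float], int]:
    """Per gene, % divergence of the most conserved passing local alignment.

    Genes with no alignment under the e-value cutoff, or whose best
    alignment covers less than ``min_coverage`` of the shorter CDS, are
    excluded (the e-value filter drops poorly conserved alignments and
    keeps the spread of the statistic small).
    """
    scheme = scheme or ScoringScheme()
    out: dict[str, float] = {}
    excluded = 0
    for gid, s1, s2 in cds_pairs:
        hits = local_align({gid: s1}, {gid: s2}, scheme, evalue_max,
                           engine="internal")
        if not hits:
            excluded += 1
            logger.info("gene %s: no alignment under e-value filter", gid)
            continue
        best = min(hits, key=percent_divergence)
        if len(best.query) < min_coverage * min(len(s1), len(s2)):
            excluded += 1
            logger.info("gene %s: best alignment below coverage floor", gid)
            continue
        out[gid] = percent_divergence(best)
    return out, excluded


def whole_coding_threshold(
    cds_pairs: list[tuple[str, str, str]],
    scheme: ScoringScheme | None = None,
    lineage: str = "lineage",
    evalue_max: float = 1e-5,
) -> ThresholdSpec:
    """Mean (and SD) of per-gene best-alignment divergence, plus skip3."""
    if len(cds_pairs) < 2:
        raise ValueError("need at least 2 ortholog gene pairs")
    divs, excluded = best_gene_divergences(cds_pairs, scheme, evalue_max)
    if len(divs) < 2:
        raise ValueError("fewer than 2 usable genes after filtering")
    values = np.array(list(divs.values()))
    spec = ThresholdSpec(
        lineage=lineage,
        whole_coding_divergence=float(values.mean()),
        whole_coding_sd=float(values.std(ddof=1)),
        skip3_divergence=skip3_threshold(cds_pairs),
        n_genes=len(divs),
        n_excluded=excluded,
    )
    spec.presets = spec.stricter_presets()
    return spec


def skip3_divergence_of_pair(s1: str, s2: str) -> tuple[int, int]:
    """(differences, sites) after dropping every third base of both sequences.

    Sequences must be equal-length, in-frame and positionally codon-aligned;
    homology of remaining columns is preserved because the same columns are
    deleted from both.
    """
    if len(s1) != len(s2):
        raise ValueError("skip3 requires positionally aligned equal-length CDS")
    if len(s1) % 3:
        raise ValueError("CDS length not divisible by 3")
    a = np.frombuffer(s1.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(s2.upper().encode(), dtype=np.uint8)
    keep = np.arange(len(a)) % 3 != 2
    return int(np.sum(a[keep] != b[keep])), int(keep.sum())


def skip3_threshold(cds_pairs: list[tuple[str, str, str]]) -> float:
    """% divergence of the third-codon-skipped concatenation across genes."""
    diffs = sites = 0
    usable = 0
    for gid, s1, s2 in cds_pairs:
        try:
            d, n = skip3_divergence_of_pair(s1, s2)
        except ValueError:
            logger.info("gene %s excluded from skip3 (frame/length)", gid)
            continue
        diffs += d
        sites += n
        usable += 1
    if usable == 0 or sites == 0:
        raise ValueError("no usable in-frame gene pairs for skip3")
    return 100.0 * diffs / sites


@dataclass
class DivergenceReport:
    normality_stat: float | None
    normality_p: float | None
    t_stat: float | None
    t_p: float | None
    coding_mean: float
    noncoding_mean: float | None
    skipped: str = ""


def divergence_stats(
    cds_divergences: np.ndarray,
    noncoding_divergences: np.ndarray | None = None,
) -> DivergenceReport:
    """Report-only statistics: D'Agostino-Pearson omnibus normality test of
    the coding divergences, and a two-sample t test against noncoding
    divergences. Thresholds never depend on these."""
    cds = np.asarray(cds_divergences, dtype=float)
    report = DivergenceReport(None, None, None, None, float(cds.mean()),
                              None)
    if len(cds) >= 8 and cds.std() > 0:
        k2, p = stats.normaltest(cds)
        report.normality_stat, report.normality_p = float(k2), float(p)
    else:
        report.skipped += "normality(n<8 or zero variance);"
    if noncoding_divergences is not None:
        nc = np.asarray(noncoding_divergences, dtype=float)
        report.noncoding_mean = float(nc.mean())
        if cds.std() > 0 or nc.std() > 0:
            t, p = stats.ttest_ind(cds, nc, equal_var=False)
            report.t_stat, report.t_p = float(t), float(p)
        elif report.coding_mean == report.noncoding_mean:
            report.t_stat, report.t_p = 0.0, 1.0
        else:
            report.skipped += "t-test(degenerate variance);"
    return report
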