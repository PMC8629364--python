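"""Trans-splicing vs conservation/cell-type enrichment statistics.

Cross-tabulates SL trans-splicing status against conservation class,
computes the per-column fractions, fold enrichments of a gene subset over
the genome-wide expectation, and chi-square statistics (both goodness of
fit against genome-wide proportions and 2x2 contingency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, chi2_contingency

from .core_io import GeneModel

CONS_ORDER = ("conserved", "non-conserved", "non-coding")


@dataclass
class EnrichmentResult:
    subset_fraction: float
    genome_fraction: float
    fold: float          # subset_fraction / genome_fraction, 2 decimals
    chi2: float | None = None
    p_value: float | None = None
    df: int | None = None


def conservation_crosstab(
    genes: Sequence[GeneModel],
    subset: Iterable[str] | None = None,
) -> pd.DataFrame:
    """2x3 table of counts: ts_status (TS/nonTS) x conservation class.

    Genes with unknown labels are excluded and tallied in the frame's
    ``attrs['excluded']``.  ``subset`` optionally restricts to a gene-id
    set (e.g. the neoblast-enriched genes).
    """
    ids = set(subset) if subset is not None else None
    rows = [(g.ts_status, g.cons_class) for g in genes
            if (ids is None or g.gene_id in ids)]
    kept = [(ts, cons) for ts, cons in rows
            if ts in ("TS", "nonTS") and cons in CONS_ORDER]
    tab = pd.DataFrame(0, index=["TS", "nonTS"], columns=list(CONS_ORDER))
    for ts, cons in kept:
        tab.loc[ts, cons] += 1
    tab.attrs["excluded"] = len(rows) - len(kept)
    return tab


def column_fractions(tab: pd.DataFrame) -> pd.DataFrame:
    """Per-ts_status conservation-class fractions in percent (1 decimal)."""
    totals = tab.sum(axis=1)
    frac = tab.div(totals.replace(0, np.nan), axis=0) * 100.0
    return frac.round(1)


def fold_enrichment(
    subset_with: int, subset_total: int,
    genome_with: int, genome_total: int,
) -> EnrichmentResult:
    """Fold enrichment of a property in a subset over the genome-wide rate."""
    if subset_total <= 0 or genome_total <= 0:
        raise ValueError("totals must be positive")
    if genome_with == 0:
        raise ValueError("genome_with is zero: fold undefined")
    subset_fraction = subset_with / subset_total
    genome_fraction = genome_with / genome_total
    return EnrichmentResult(
        subset_fraction=subset_fraction,
        genome_fraction=genome_fraction,
        fold=round(subset_fraction / genome_fraction, 2),
    )


def chi_square_gof(
    observed: Sequence[int],
    expected_proportions: Sequence[float],
) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square of observed counts vs expected proportions."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected_proportions differ in length")
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    expected = props * obs.sum()
    if np.any((expected == 0) & (obs > 0)):
        raise ValueError("expected cell is zero with observed > 0")
    mask = expected > 0
    stat = float(np.sum((obs[mask] - expected[mask]) ** 2 / expected[mask]))
    df = len(obs) - 1
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Contingency chi-square (no continuity correction) for a 2x2 table."""
    stat, p, df, _ = chi2_contingency([[a, b], [c, d]], correction=False)
    return float(stat), int(df), float(p)


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """A printed-style percentage: 100 * numerator / denominator, rounded."""
    if denominator == 0:
        raise ValueError("denominator is zero")
    return round(100.0 * numerator / denominator, decimals)


def neoblast_conserved_ts_enrichment(genes: Sequence[GeneModel]) -> EnrichmentResult:
    """Fold enrichment of TS among conserved neoblast genes over all conserved genes.

    Mirrors the comparison of the fraction of trans-spliced genes among
    conserved stem-cell genes with the genome-wide fraction of trans-
    spliced genes among all conserved genes, and attaches a goodness-of-fit
    chi-square of the subset counts against the genome-wide proportions.
    """
    cons = [g for g in genes if g.cons_class == "conserved" and g.ts_status in ("TS", "nonTS")]
    neo = [g for g in cons if g.cell_label == "neoblast"]
    subset_with = sum(1 for g in neo if g.ts_status == "TS")
    genome_with = sum(1 for g in cons if g.ts_status == "TS")
    res = fold_enrichment(subset_with, len(neo), genome_with, len(cons))
    p_ts = genome_with / len(cons)
    stat, df, p = chi_square_gof(
        [subset_with, len(neo) - subset_with], [p_ts, 1.0 - p_ts])
    res.chi2, res.df, res.p_value = stat, df, p
    return res
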