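"""Bin quality from essential single-copy genes (ESCGs), F1 and summaries.

A draft genome should contain each essential single-copy marker gene
exactly once.  For any contig selection, with ``c_g`` the summed copies
of gene g over the selection and U the declared universe size (109 by
default, a domain-level bacterial panel):

* completeness  = 100 * |{g : c_g >= 1}| / U
* contamination = 100 * sum_g max(0, c_g - 1) / U   (excess copies; can
  exceed 100)
* F1 = 2PR/(P+R) with recall R = completeness and precision
  P = 100 - contamination floored at 0 and forced to 0 when
  contamination exceeds 100.

The summary utilities reproduce the conventional draft-quality
categories (completeness: Near >= 90, Substantial 70-90, Moderate 50-70,
Partial < 50; contamination: Low <= 5, Medium 5-10, High 10-15,
Very high > 15) and per-method averages where bins without an assignment
("NB") are excluded from the denominator and F1 is averaged per bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .exceptions import BinrefError
from .io import UNBINNED, BinAssignmentTable, ContigSet, ESCGTable

#: Default marker-gene universe size.
DEFAULT_UNIVERSE_SIZE = 109

COMPLETENESS_CATEGORIES = ("near", "substantial", "moderate", "partial")
CONTAMINATION_CATEGORIES = ("low", "medium", "high", "very_high")


@dataclass
class BinQuality:
    """Quality of one bin (or contig selection)."""

    label: str
    completeness: float  # % of the gene universe present
    contamination: float  # % excess copies; may exceed 100
    f1: float  # %
    n_found: int = 0  # genes with >= 1 copy
    n_multi: int = 0  # genes with >= 2 copies
    n_contigs: int | None = None
    total_nt: int | None = None


@dataclass
class QualitySummary:
    """Category counts over a set of bins (draft-quality classification)."""

    completeness_counts: dict[str, int]
    contamination_counts: dict[str, int]
    n_bins: int


@dataclass
class MethodAverages:
    """Arithmetic means over assigned bins of one binning method."""

    mean_completeness: float
    mean_contamination: float
    mean_f1: float
    n_bins: int


def escg_stats(
    selection: Iterable[str],
    escg: ESCGTable,
    universe_size: int | None = None,
) -> BinQuality:
    """Completeness/contamination of a contig selection from ESCG counts.

    Contigs absent from the table contribute no genes; an empty selection
    is valid and scores zero throughout.  Genes kept under the "extra"
    namespace are ignored.
    """
    if universe_size is None:
        universe_size = escg.universe_size
    if universe_size <= 0:
        raise BinrefError("universe_size must be positive")
    ids = [cid for cid in selection if cid in escg.counts.index]
    genes = escg.genes
    if ids and genes:
        copies = escg.counts.loc[ids, genes].sum(axis=0)
    else:
        copies = pd.Series(0, index=genes, dtype=int)
    n_found = int((copies >= 1).sum())
    n_multi = int((copies >= 2).sum())
    excess = int(np.maximum(copies - 1, 0).sum())
    completeness = 100.0 * n_found / universe_size
    contamination = 100.0 * excess / universe_size
    return BinQuality(
        label="selection",
        completeness=completeness,
        contamination=contamination,
        f1=f1_score(completeness, contamination),
        n_found=n_found,
        n_multi=n_multi,
        n_contigs=len(list(ids)),
    )


def f1_score(completeness: float, contamination: float) -> float:
    """Harmonic mean of precision and recall for one bin, in percent.

    Recall is completeness; precision is 100 minus contamination, floored
    at 0 and set to 0 outright when contamination exceeds 100.  Defined
    as 0 when precision and recall are both 0.
    """
    if not 0 <= completeness <= 100:
        raise BinrefError("completeness must be within [0, 100]")
    if contamination < 0:
        raise BinrefError("contamination must be >= 0")
    precision = 0.0 if contamination > 100 else max(0.0, 100.0 - contamination)
    recall = completeness
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def bin_quality_report(
    assignments: BinAssignmentTable,
    method: str,
    escg: ESCGTable,
    universe_size: int | None = None,
    contigs: ContigSet | None = None,
) -> list[BinQuality]:
    """One :class:`BinQuality` per bin of ``method``, sorted by
    descending completeness (ties by label)."""
    groups = assignments.bins(method)
    report = []
    for label, members in groups.items():
        q = escg_stats(members, escg, universe_size=universe_size)
        q.label = label
        q.n_contigs = len(members)
        if contigs is not None:
            q.total_nt = sum(contigs[c].length for c in members if c in contigs)
        report.append(q)
    report.sort(key=lambda q: (-q.completeness, q.label))
    return report


def quality_from_checkm(
    completeness: float, contamination: float, label: str = ""
) -> BinQuality:
    """Wrap externally estimated (e.g. CheckM) completeness/contamination
    pairs so summary utilities can consume published tables."""
    return BinQuality(
        label=label,
        completeness=float(completeness),
        contamination=float(contamination),
        f1=f1_score(completeness, contamination),
    )


def completeness_category(completeness: float) -> str:
    """Draft-quality completeness category; edges closed on the left."""
    if completeness >= 90:
        return "near"
    if completeness >= 70:
        return "substantial"
    if completeness >= 50:
        return "moderate"
    return "partial"


def contamination_category(contamination: float) -> str:
    """Contamination category; Low is closed at 5 (5.0 is Low, 5.3 Medium)."""
    if contamination <= 5:
        return "low"
    if contamination <= 10:
        return "medium"
    if contamination <= 15:
        return "high"
    return "very_high"


def categorize(qualities: Sequence[BinQuality]) -> QualitySummary:
    """Count bins per completeness and contamination category."""
    comp = {c: 0 for c in COMPLETENESS_CATEGORIES}
    cont = {c: 0 for c in CONTAMINATION_CATEGORIES}
    for q in qualities:
        comp[completeness_category(q.completeness)] += 1
        cont[contamination_category(q.contamination)] += 1
    return QualitySummary(
        completeness_counts=comp,
        contamination_counts=cont,
        n_bins=len(qualities),
    )


def method_averages(qualities: Sequence[BinQuality]) -> MethodAverages:
    """Mean completeness, contamination and F1 over assigned bins.

    Callers exclude unassigned ("NB") entries before calling — the
    denominator is the number of bins the method actually produced.  F1
    is computed per bin first, then averaged.
    """
    if not qualities:
        raise BinrefError("method_averages needs at least one quality record")
    return MethodAverages(
        mean_completeness=float(np.mean([q.completeness for q in qualities])),
        mean_contamination=float(np.mean([q.contamination for q in qualities])),
        mean_f1=float(np.mean([q.f1 for q in qualities])),
        n_bins=len(qualities),
    )


def method_averages_from_table(
    table: pd.DataFrame, method: str
) -> MethodAverages:
    """Averages from a tidy table with ``{method}_completeness`` and
    ``{method}_contamination`` columns; NaN rows (NB) are dropped."""
    comp = table[f"{method}_completeness"]
    cont = table[f"{method}_contamination"]
    keep = comp.notna() & cont.notna()
    qualities = [
        quality_from_checkm(c, x, label=str(i))
        for i, c, x in zip(table.index[keep], comp[keep], cont[keep])
    ]
    return method_averages(qualities)


def summary_table(per_method: Mapping[str, Sequence[BinQuality]]) -> pd.DataFrame:
    """Per-method summary (rows = methods) of averages and category counts."""
    rows = {}
    for method, qualities in per_method.items():
        avg = method_averages(qualities)
        cats = categorize(qualities)
        rows[method] = {
            "n_bins": avg.n_bins,
            "mean_completeness": avg.mean_completeness,
            "mean_contamination": avg.mean_contamination,
            "mean_f1": avg.mean_f1,
            **{f"completeness_{k}": v for k, v in cats.completeness_counts.items()},
            **{f"contamination_{k}": v for k, v in cats.contamination_counts.items()},
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def pairwise_ari(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Adjusted Rand index between two label sequences (scikit-learn)."""
    return float(adjusted_rand_score(list(labels_a), list(labels_b)))


def brute_force_ari(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Pair-counting ARI by explicit enumeration of all item pairs.

    Independent small-n oracle for :func:`pairwise_ari`; O(n^2), intended
    for tests only.
    """
    a, b = list(labels_a), list(labels_b)
    n = len(a)
    pairs = list(combinations(range(n), 2))
    if not pairs:
        return 1.0
    same_a = np.array([a[i] == a[j] for i, j in pairs])
    same_b = np.array([b[i] == b[j] for i, j in pairs])
    n11 = int((same_a & same_b).sum())
    n00 = int((~same_a & ~same_b).sum())
    n10 = int((same_a & ~same_b).sum())
    n01 = int((~same_a & same_b).sum())
    total = len(pairs)
    index = n11
    expected = (n11 + n10) * (n11 + n01) / total
    maximum = ((n11 + n10) + (n11 + n01)) / 2
    if maximum == expected:
        return 1.0
    return (index - expected) / (maximum - expected)


def compare_binnings(
    assignments: BinAssignmentTable, method_a: str, method_b: str
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate two binnings and score their agreement.

    Returns (bins x bins shared-contig contingency table, adjusted Rand
    index).  Only contigs assigned by *both* methods enter either
    quantity, so consensus agreement is not diluted by differing
    unbinned fractions.
    """
    col_a = assignments.column(method_a)
    col_b = assignments.column(method_b)
    both = (col_a != UNBINNED) & (col_b != UNBINNED)
    a, b = col_a[both], col_b[both]
    table = pd.crosstab(a, b)
    table.index.name = method_a
    table.columns.name = method_b
    ari = pairwise_ari(a.tolist(), b.tolist()) if both.any() else float("nan")
    return table, ari
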