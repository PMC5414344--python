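"""Per-contig variables: GC content, k-mer frequency profiles, DNA-RPKM.

Composition-based binning rests on two signals: oligonucleotide usage
(tetra- or penta-nucleotide frequencies, k = 4 or 5) which is roughly
constant along a genome, and co-abundance of contigs across samples.
This module computes both families of variables and assembles them into a
single contigs x variables :class:`FeatureMatrix` whose columns are tagged
by kind (``abundance``, ``gc``, ``tnf``, ``pnf``) so downstream clustering
and ordination can slice by kind.

K-mer profiles are strand-collapsed ("canonical") by default: a k-mer and
its reverse complement are merged under the lexicographically smaller
label, because assembled contigs have arbitrary strand.  That yields 136
canonical tetramers (16 palindromes + 120 complement pairs) and 512
canonical pentamers (no odd-length palindromes).  A flag restores the raw
256/1024 k-mer space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import BinrefError
from .io import ContigSet, CoverageTable

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Recognised variable kinds, in the column order of a feature matrix.
VARIABLE_KINDS = ("abundance", "gc", "tnf", "pnf")

_KIND_BY_K = {4: "tnf", 5: "pnf"}


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_content(sequence: str) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T) of a sequence.

    Ambiguity codes are excluded from numerator and denominator.  Returns
    NaN when no unambiguous base is present; raises on an empty sequence.
    """
    if not sequence:
        raise BinrefError("gc_content of an empty sequence is undefined")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return math.nan
    return gc / (gc + at)


@lru_cache(maxsize=None)
def kmer_labels(k: int, canonical: bool = True) -> tuple[str, ...]:
    """Ordered k-mer labels: all 4**k words, or canonical representatives.

    Canonical labels are the lexicographically smaller of each
    {k-mer, reverse complement} pair, in lexicographic order.
    """
    words = ["".join(p) for p in product("ACGT", repeat=k)]
    if not canonical:
        return tuple(words)
    return tuple(sorted({min(w, reverse_complement(w)) for w in words}))


@lru_cache(maxsize=None)
def _canonical_fold(k: int) -> np.ndarray:
    """Map raw k-mer index -> index into the canonical label vector."""
    raw = kmer_labels(k, canonical=False)
    canon = kmer_labels(k, canonical=True)
    lookup = {label: i for i, label in enumerate(canon)}
    return np.array(
        [lookup[min(w, reverse_complement(w))] for w in raw], dtype=np.int64
    )


_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def kmer_counts(sequence: str, k: int = 4, canonical: bool = True) -> np.ndarray:
    """Sliding-window k-mer counts (step 1) over one sequence.

    Windows containing any non-ACGT character are skipped entirely.
    Returns an integer vector aligned with :func:`kmer_labels`.
    """
    if k not in (4, 5):
        raise BinrefError(f"k must be 4 or 5, got {k}")
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n_labels = len(kmer_labels(k, canonical))
    if codes.size < k:
        return np.zeros(n_labels, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = windows[valid] @ powers
    counts = np.bincount(idx, minlength=4**k)
    if canonical:
        counts = np.bincount(
            _canonical_fold(k), weights=counts, minlength=n_labels
        ).astype(np.int64)
    return counts


def kmer_frequencies(
    sequence: str, k: int = 4, canonical: bool = True
) -> np.ndarray:
    """Relative k-mer frequencies: counts divided by valid window count.

    A sequence with no valid window yields an all-zero vector.
    """
    counts = kmer_counts(sequence, k=k, canonical=canonical)
    total = counts.sum()
    if total == 0:
        return counts.astype(float)
    return counts / total


def kmer_count_matrix(
    contigs: ContigSet | Iterable, k: int = 4, canonical: bool = True
) -> pd.DataFrame:
    """Contigs x k-mers integer count matrix (input to correspondence analysis)."""
    labels = kmer_labels(k, canonical)
    rows = {c.id: kmer_counts(c.sequence, k=k, canonical=canonical) for c in contigs}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(labels))


def kmer_frequency_matrix(
    contigs: ContigSet | Iterable, k: int = 4, canonical: bool = True
) -> pd.DataFrame:
    """Contigs x k-mers relative-frequency matrix."""
    counts = kmer_count_matrix(contigs, k=k, canonical=canonical)
    totals = counts.sum(axis=1)
    freq = counts.div(totals.where(totals > 0, 1), axis=0)
    return freq


def dna_rpkm(read_count, contig_length, total_mapped) -> float | np.ndarray:
    """Reads per kilobase of contig per million mapped reads.

    ``read_count / (contig_length/1000) / (total_mapped/1e6)``; accepts
    scalars or aligned arrays.  Zero length or zero total is an error.
    """
    length = np.asarray(contig_length, dtype=float)
    total = np.asarray(total_mapped, dtype=float)
    if (length <= 0).any():
        raise BinrefError("contig_length must be positive for DNA-RPKM")
    if (total <= 0).any():
        raise BinrefError("total_mapped must be positive for DNA-RPKM")
    result = np.asarray(read_count, dtype=float) / (length / 1e3) / (total / 1e6)
    return float(result) if result.ndim == 0 else result


def coverage_to_rpkm(coverage: CoverageTable, lengths: pd.Series) -> CoverageTable:
    """Convert a raw-count coverage table to DNA-RPKM using contig lengths.

    Per-sample totals are the column sums of the count table (reads mapped
    in that sample).
    """
    if coverage.units == "dna_rpkm":
        return coverage
    counts = coverage.data
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise BinrefError("missing contig lengths for RPKM conversion")
    totals = counts.sum(axis=0)
    values = dna_rpkm(
        counts.values,
        lengths.values[:, None],
        totals.values[None, :],
    )
    return CoverageTable(
        data=pd.DataFrame(values, index=counts.index, columns=counts.columns),
        units="dna_rpkm",
        low_sample_warning=coverage.low_sample_warning,
    )


@dataclass
class FeatureMatrix:
    """Contigs x variables table with a kind tag per column.

    ``kinds`` is aligned with ``data.columns`` and takes values from
    :data:`VARIABLE_KINDS`.
    """

    data: pd.DataFrame
    kinds: pd.Series  # index = columns of data

    def columns_of_kind(self, *kinds: str) -> list[str]:
        wanted = set(kinds)
        return [c for c in self.data.columns if self.kinds[c] in wanted]

    def slice(self, columns: Sequence[str]) -> "FeatureMatrix":
        cols = list(columns)
        return FeatureMatrix(data=self.data[cols], kinds=self.kinds[cols])

    def to_csv(self, path) -> None:
        """Write contigs x variables CSV with kind tags in a second header row."""
        out = self.data.copy()
        out.columns = pd.MultiIndex.from_arrays(
            [self.data.columns, self.kinds.values], names=["variable", "kind"]
        )
        out.to_csv(path, index_label="contig")


def build_feature_matrix(
    contigs: ContigSet,
    coverage: CoverageTable | None = None,
    include: Sequence[str] = ("abundance", "gc", "tnf"),
    canonical: bool = True,
) -> FeatureMatrix:
    """Assemble the working feature matrix for clustering and selection.

    Column order is abundances (input sample order), then gc, then k-mer
    frequencies in label order.  Contigs missing from the coverage table
    are zero-filled.  ``include`` must name at least one kind from
    :data:`VARIABLE_KINDS`.
    """
    include = tuple(include)
    if not include:
        raise BinrefError("include must name at least one variable kind")
    unknown = [kind for kind in include if kind not in VARIABLE_KINDS]
    if unknown:
        raise BinrefError(f"unknown variable kind(s): {unknown}")
    ids = contigs.ids
    blocks: list[pd.DataFrame] = []
    kinds: list[str] = []
    if "abundance" in include:
        if coverage is None:
            raise BinrefError("abundance variables requested without a coverage table")
        abund = coverage.data.reindex(ids).fillna(0.0)
        blocks.append(abund)
        kinds.extend(["abundance"] * abund.shape[1])
    if "gc" in include:
        gc = pd.DataFrame(
            {"gc": [gc_content(c.sequence) for c in contigs]}, index=ids
        )
        blocks.append(gc)
        kinds.append("gc")
    for kind_k, kind_name in _KIND_BY_K.items():
        if kind_name in include:
            freq = kmer_frequency_matrix(contigs, k=kind_k, canonical=canonical)
            blocks.append(freq.reindex(ids))
            kinds.extend([kind_name] * freq.shape[1])
    data = pd.concat(blocks, axis=1)
    return FeatureMatrix(data=data, kinds=pd.Series(kinds, index=data.columns))
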