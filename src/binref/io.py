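"""Readers and writers for the four prescribed inputs and refined-bin outputs.

A refinement run consumes up to four files:

1. a co-assembly FASTA with every contig of the co-assembled metagenome;
2. a per-sample contig coverage (abundance) CSV, DNA-RPKM or raw counts;
3. an essential single-copy gene (ESCG) CSV mapping contigs to predicted
   marker genes, either long form (one row per predicted occurrence) or a
   wide count matrix — the dialect is auto-detected;
4. an optional bin-assignment CSV with one column per automated binner.

All tables are keyed by contig id (the FASTA header token before the first
whitespace), so row order never influences downstream numbers.  Outputs are
one FASTA per refined bin plus a summary CSV, and a versioned JSON session
state that any front end (or :func:`binref.refinement.replay`) can consume.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import FastaError, TableError

logger = logging.getLogger(__name__)

#: Sentinel label for contigs without a bin assignment.
UNBINNED = "unbinned"

#: IUPAC nucleotide one-letter codes accepted in contig sequences.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

#: Minimum number of coverage samples required by correlation clustering.
MIN_CLUSTERING_SAMPLES = 5

#: Schema version written into exported session-state JSON documents.
SESSION_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig: unique id, upper-case sequence, length in nt."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class ContigSet:
    """Ordered, id-keyed collection of :class:`ContigRecord`.

    Ids are unique; iteration preserves input (FASTA) order.
    """

    def __init__(self, records: Iterable[ContigRecord] = ()):  # noqa: D107
        self._records: dict[str, ContigRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ContigRecord) -> None:
        if record.id in self._records:
            raise FastaError(f"duplicate contig id: {record.id!r}")
        if record.length == 0:
            raise FastaError(f"empty sequence for contig {record.id!r}")
        self._records[record.id] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ContigRecord]:
        return iter(self._records.values())

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._records

    def __getitem__(self, contig_id: str) -> ContigRecord:
        return self._records[contig_id]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def lengths(self) -> pd.Series:
        """Contig lengths (nt) indexed by contig id."""
        return pd.Series({r.id: r.length for r in self}, dtype=int)


@dataclass
class CoverageTable:
    """Per-sample contig abundances (contigs x samples), values >= 0.

    ``units`` declares whether values are DNA-RPKM or raw read counts.
    ``low_sample_warning`` is set when fewer samples are present than
    correlation clustering requires (five).
    """

    data: pd.DataFrame
    units: str = "dna_rpkm"
    low_sample_warning: bool = False

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ESCGTable:
    """Copy counts of essential single-copy genes per contig.

    ``counts`` is contigs x genes with non-negative integer entries;
    ``universe_size`` is the declared size of the marker panel (109 by
    default — a domain-level bacterial single-copy set) and is the
    denominator for completeness/contamination percentages even when fewer
    genes were actually predicted.  Genes outside a declared universe are
    kept under ``extra_genes`` and excluded from quality statistics.
    """

    counts: pd.DataFrame
    universe_size: int = 109
    extra_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return [g for g in self.counts.columns if g not in set(self.extra_genes)]


@dataclass
class BinAssignmentTable:
    """Contig -> bin label, one column per binning method.

    Labels are opaque strings; unassigned contigs carry the sentinel
    ``"unbinned"``.  Every contig appears exactly once (the index).
    """

    data: pd.DataFrame

    @property
    def methods(self) -> list[str]:
        return list(self.data.columns)

    @property
    def contig_ids(self) -> list[str]:
        return list(self.data.index)

    def column(self, method: str) -> pd.Series:
        if method not in self.data.columns:
            raise TableError(f"unknown binning method: {method!r}")
        return self.data[method]

    def add_column(self, method: str, labels: pd.Series) -> None:
        """Append (or overwrite) a method column, unbinned-filling gaps."""
        self.data[method] = labels.reindex(self.data.index).fillna(UNBINNED)

    def bins(self, method: str) -> dict[str, list[str]]:
        """Mapping bin label -> contig ids, excluding ``unbinned``."""
        col = self.column(method)
        out: dict[str, list[str]] = {}
        for cid, label in col.items():
            if label != UNBINNED:
                out.setdefault(str(label), []).append(cid)
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_contigs(path: str | Path) -> ContigSet:
    """Read a co-assembly FASTA into a :class:`ContigSet`.

    The contig id is the header token before the first whitespace;
    multi-line sequences are concatenated and upper-cased.  Duplicate ids,
    empty sequences and non-IUPAC characters are hard errors.
    """
    contigs = ContigSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for pos, base in enumerate(seq):
            if base not in IUPAC_DNA:
                raise FastaError(
                    f"non-IUPAC character {base!r} at position {pos + 1} "
                    f"of contig {rec.id!r}"
                )
        contigs.add(ContigRecord(id=rec.id, sequence=seq))
    return contigs


def _read_keyed_csv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableError(f"cannot parse CSV {path}: {exc}") from exc
    df.index = df.index.astype(str)
    return df


def read_coverage(path: str | Path, units: str = "dna_rpkm") -> CoverageTable:
    """Read a per-sample coverage CSV (first column contig id, header row).

    Non-numeric or negative cells are errors naming the offending
    row/column.  Fewer than five sample columns sets
    ``low_sample_warning`` (correlation clustering needs at least five).
    """
    raw = _read_keyed_csv(path)
    numeric = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.isna().any():
            bad = raw.index[converted.isna()][0]
            raise TableError(
                f"non-numeric coverage value {raw.loc[bad, col]!r} "
                f"at contig {bad!r}, sample {col!r}"
            )
        numeric[col] = converted.astype(float)
    if (numeric.values < 0).any():
        stacked = numeric.stack()
        bad_row, bad_col = stacked.index[stacked.values < 0][0]
        raise TableError(
            f"negative coverage value at contig {bad_row!r}, sample {bad_col!r}"
        )
    low = numeric.shape[1] < MIN_CLUSTERING_SAMPLES
    if low:
        warnings.warn(
            f"coverage table has {numeric.shape[1]} samples, below the "
            f"correlation-clustering minimum of {MIN_CLUSTERING_SAMPLES}",
            stacklevel=2,
        )
    return CoverageTable(data=numeric, units=units, low_sample_warning=low)


def read_escg(
    path: str | Path,
    universe: list[str] | None = None,
    universe_size: int = 109,
) -> ESCGTable:
    """Read an ESCG CSV in either long or wide dialect.

    Long form has one row per predicted gene occurrence (contig, gene);
    duplicate rows aggregate into copy counts.  Wide form is a contig x
    gene count matrix.  The dialect is auto-detected: a table whose
    non-key columns are all numeric is wide, otherwise long.

    When a ``universe`` of gene ids is declared, genes outside it are
    retained under the ``extra`` namespace with a warning and excluded
    from quality statistics.
    """
    raw = _read_keyed_csv(path)
    wide = raw.shape[1] >= 1 and all(
        pd.to_numeric(raw[c], errors="coerce").notna().all() for c in raw.columns
    )
    if wide and raw.shape[1] >= 1:
        counts = raw.apply(pd.to_numeric).astype(int)
    else:
        if raw.shape[1] < 1:
            raise TableError("ESCG long-form CSV needs a gene column")
        gene_col = raw.columns[0]
        long = raw[gene_col].astype(str)
        counts = (
            pd.crosstab(long.index, long)
            .rename_axis(index=None, columns=None)
            .astype(int)
        )
    if (counts.values < 0).any():
        raise TableError("negative ESCG copy count")
    extra: list[str] = []
    if universe is not None:
        universe_size = len(universe)
        extra = [g for g in counts.columns if g not in set(universe)]
        if extra:
            warnings.warn(
                f"{len(extra)} gene id(s) outside the declared universe kept "
                f"under the 'extra' namespace: {extra[:5]}",
                stacklevel=2,
            )
        ordered = [g for g in universe if g in counts.columns] + extra
        counts = counts[ordered]
    return ESCGTable(counts=counts, universe_size=universe_size, extra_genes=extra)


def read_assignments(path: str | Path) -> BinAssignmentTable:
    """Read a binning CSV (one column per method); blanks map to unbinned."""
    raw = _read_keyed_csv(path)
    if raw.shape[1] < 1:
        raise TableError("assignment CSV needs at least one method column")
    data = raw.astype(str).replace({"": UNBINNED, "nan": UNBINNED, "NA": UNBINNED})
    return BinAssignmentTable(data=data)


def cross_check_contigs(
    contigs: ContigSet, table_index: Iterable[str], what: str = "table"
) -> list[str]:
    """Return ids present in a table but absent from the contig set.

    Missing-from-table contigs are the caller's business (treated as
    all-zero rows); unknown ids are warned about and returned.
    """
    unknown = [cid for cid in table_index if cid not in contigs]
    if unknown:
        warnings.warn(
            f"{len(unknown)} contig id(s) in {what} absent from the "
            f"co-assembly: {unknown[:5]}",
            stacklevel=2,
        )
    return unknown


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_bins(
    assignments: BinAssignmentTable,
    method: str,
    contigs: ContigSet,
    outdir: str | Path,
) -> pd.DataFrame:
    """Write one FASTA per bin of ``method`` plus a summary CSV.

    Unbinned contigs go to ``unbinned.fasta``.  Returns the summary table
    (bin, n_contigs, total_nt, gc).  Re-reading the written files
    reproduces the partition and sequences exactly.
    """
    from .features import gc_content  # local import avoids a cycle

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise TableError(f"cannot create output directory {outdir}: {exc}") from exc

    col = assignments.column(method)
    groups = assignments.bins(method)
    rows = []
    for label in sorted(groups):
        members = groups[label]
        _write_fasta(outdir / f"{label}.fasta", contigs, members)
        concat = "".join(contigs[cid].sequence for cid in members)
        rows.append(
            {
                "bin": label,
                "n_contigs": len(members),
                "total_nt": sum(contigs[cid].length for cid in members),
                "gc": round(gc_content(concat), 4),
            }
        )
    unbinned = [cid for cid in col.index if col[cid] == UNBINNED and cid in contigs]
    if unbinned:
        _write_fasta(outdir / "unbinned.fasta", contigs, unbinned)
    summary = pd.DataFrame(rows, columns=["bin", "n_contigs", "total_nt", "gc"])
    summary.to_csv(outdir / "bin_summary.csv", index=False)
    return summary


def _write_fasta(path: Path, contigs: ContigSet, ids: Iterable[str]) -> None:
    records = [
        SeqRecord(Seq(contigs[cid].sequence), id=cid, description="") for cid in ids
    ]
    SeqIO.write(records, str(path), "fasta")


def write_coverage(coverage: CoverageTable, path: str | Path) -> None:
    coverage.data.to_csv(path, index_label="contig")


def write_assignments(assignments: BinAssignmentTable, path: str | Path) -> None:
    assignments.data.to_csv(path, index_label="contig")


def write_escg_long(escg: ESCGTable, path: str | Path) -> None:
    """Write an ESCG table in the long (occurrence-row) dialect."""
    rows = []
    for cid, counts in escg.counts.iterrows():
        for gene, n in counts.items():
            rows.extend([{"contig": cid, "gene": gene}] * int(n))
    pd.DataFrame(rows, columns=["contig", "gene"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# session state
# ---------------------------------------------------------------------------

def export_state(session, path: str | Path | None = None) -> dict:
    """Serialise a refinement session to a versioned JSON-able document.

    Includes the feature-matrix slice the session works on, the full
    assignment table, the current working set, tags and the audit log —
    everything a front end needs to resume, and enough for
    :func:`binref.refinement.replay` to reproduce the refined column.
    """
    state = {
        "schema_version": SESSION_SCHEMA_VERSION,
        "contig_ids": list(session.assignments.data.index),
        "working_set": sorted(session.working_set),
        "features": {
            "columns": list(session.features.data.columns),
            "kinds": list(session.features.kinds),
            "values": session.features.data.values.tolist(),
            "index": list(session.features.data.index),
        }
        if session.features is not None
        else None,
        "assignments": {
            m: session.assignments.data[m].tolist()
            for m in session.assignments.methods
        },
        "tags": dict(session.tags),
        "audit_log": list(session.audit_log),
    }
    if path is not None:
        Path(path).write_text(json.dumps(state, indent=2))
    return state


def import_state(source: str | Path | Mapping) -> dict:
    """Load a session-state document from a path or mapping, checking schema."""
    if isinstance(source, (str, Path)):
        state = json.loads(Path(source).read_text())
    else:
        state = dict(source)
    version = state.get("schema_version")
    if version != SESSION_SCHEMA_VERSION:
        raise TableError(
            f"unsupported session schema version {version!r} "
            f"(expected {SESSION_SCHEMA_VERSION})"
        )
    return state
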