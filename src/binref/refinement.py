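"""Scriptable bin refinement: selections, keep/remove, assignment edits.

This is the headless analogue of brushing axes in a parallel-coordinates
view: a :class:`Selection` is a conjunction of predicates — numeric
intervals on feature variables and/or bin-label sets on assignment
columns — resolved against the session's current *working set*.  Keeping
or removing a selection narrows the working set without ever deleting
contigs from the underlying tables; assignment edits live in a dedicated
``refined`` column, leaving every input binning immutable.

Every mutating operation appends an event to an append-only audit log;
:func:`replay` re-applies a log to the initial state and reproduces the
final assignments exactly, which makes a refinement session a
reproducible artefact rather than a sequence of mouse gestures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from hashlib import sha256
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import BinrefError
from .features import FeatureMatrix
from .io import UNBINNED, BinAssignmentTable, ESCGTable
from .quality import BinQuality, escg_stats

#: Name of the editable assignment column.
REFINED = "refined"


@dataclass(frozen=True)
class IntervalPredicate:
    """variable value within a closed numeric interval."""

    variable: str
    low: float
    high: float


@dataclass(frozen=True)
class BinPredicate:
    """contig assigned to one of a set of bin labels by a method."""

    method: str
    labels: frozenset[str]


Predicate = IntervalPredicate | BinPredicate


@dataclass
class Selection:
    """Resolved contig selection: predicates plus the matching id set."""

    predicates: tuple[Predicate, ...]
    ids: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.ids)


def _predicate_from_spec(spec) -> Predicate:
    """Accept (variable, low, high) / (method, labelset) tuples, dicts or
    ready predicates — convenience for scripted sessions and JSON."""
    if isinstance(spec, (IntervalPredicate, BinPredicate)):
        return spec
    if isinstance(spec, Mapping):
        if "variable" in spec:
            return IntervalPredicate(spec["variable"], float(spec["low"]), float(spec["high"]))
        if "method" in spec:
            return BinPredicate(spec["method"], frozenset(spec["labels"]))
        raise BinrefError(f"cannot interpret predicate {spec!r}")
    if len(spec) == 3:
        return IntervalPredicate(str(spec[0]), float(spec[1]), float(spec[2]))
    if len(spec) == 2:
        return BinPredicate(str(spec[0]), frozenset(spec[1]))
    raise BinrefError(f"cannot interpret predicate {spec!r}")


def _predicate_to_json(pred: Predicate) -> dict:
    if isinstance(pred, IntervalPredicate):
        return {"variable": pred.variable, "low": pred.low, "high": pred.high}
    return {"method": pred.method, "labels": sorted(pred.labels)}


class RefinementSession:
    """Stateful refinement of a bin assignment table.

    Parameters
    ----------
    assignments
        Input binnings; never modified except for the ``refined`` column.
    features
        Optional feature matrix backing interval predicates.
    escg
        Optional ESCG table; when present, :meth:`assign` returns live
        completeness/contamination feedback for the edited bin.
    source_method
        Binning column used to seed the ``refined`` column (default:
        start all-unbinned).
    """

    def __init__(
        self,
        assignments: BinAssignmentTable,
        features: FeatureMatrix | None = None,
        escg: ESCGTable | None = None,
        source_method: str | None = None,
    ) -> None:
        self.assignments = assignments
        self.features = features
        self.escg = escg
        self.source_method = source_method
        if source_method is not None:
            seed = assignments.column(source_method).copy()
        else:
            seed = pd.Series(UNBINNED, index=assignments.data.index, dtype=object)
        self.assignments.data[REFINED] = seed
        self.working_set: set[str] = set(assignments.data.index)
        self.tags: dict[str, str] = {}
        self.audit_log: list[dict] = []

    # -- internal -----------------------------------------------------------

    def _log(self, op: str, args: dict, affected: int) -> None:
        self.audit_log.append(
            {
                "index": len(self.audit_log),
                "timestamp": datetime.now(timezone.utc).isoformat(),
                "op": op,
                "args": args,
                "affected": affected,
            }
        )

    def _resolve(self, predicates: Sequence) -> frozenset[str]:
        ids = set(self.working_set)
        for spec in predicates:
            pred = _predicate_from_spec(spec)
            if isinstance(pred, IntervalPredicate):
                if self.features is None or pred.variable not in self.features.data.columns:
                    raise BinrefError(f"unknown variable: {pred.variable!r}")
                col = self.features.data[pred.variable]
                hit = set(col.index[(col >= pred.low) & (col <= pred.high)])
            else:
                col = self.assignments.column(pred.method)
                hit = set(col.index[col.isin(pred.labels)])
            ids &= hit
        return frozenset(ids)

    # -- operations ---------------------------------------------------------

    def select(self, predicates: Sequence = ()) -> Selection:
        """Conjunction of predicates over the current working set.

        An empty predicate list selects the whole working set; the
        returned count is the live "data counter".
        """
        preds = tuple(_predicate_from_spec(p) for p in predicates)
        return Selection(predicates=preds, ids=self._resolve(preds))

    def keep(self, selection: Selection) -> set[str]:
        """Restrict the working set to the selection."""
        self.working_set = set(selection.ids)
        self._log(
            "keep",
            {"ids": sorted(selection.ids)},
            affected=len(selection.ids),
        )
        return self.working_set

    def remove(self, selection: Selection) -> set[str]:
        """Drop the selection from the working set."""
        self.working_set -= set(selection.ids)
        self._log(
            "remove",
            {"ids": sorted(selection.ids)},
            affected=len(selection.ids),
        )
        return self.working_set

    def assign(self, selection: Selection, bin_label: str) -> BinQuality | None:
        """Assign every selected contig to ``bin_label`` in ``refined``.

        Overwrites previous refined labels (single membership is
        preserved by construction).  Returns live ESCG statistics of the
        bin when an ESCG table is attached.
        """
        if not selection.ids:
            raise BinrefError("cannot assign an empty selection")
        col = self.assignments.data[REFINED]
        col.loc[list(selection.ids)] = bin_label
        self._log(
            "assign",
            {"ids": sorted(selection.ids), "bin": bin_label},
            affected=len(selection.ids),
        )
        if self.escg is None:
            return None
        members = col.index[col == bin_label]
        quality = escg_stats(members, self.escg)
        quality.label = bin_label
        return quality

    def unassign(self, selection: Selection) -> None:
        """Return every selected contig to ``unbinned`` in ``refined``."""
        if not selection.ids:
            raise BinrefError("cannot unassign an empty selection")
        self.assignments.data.loc[list(selection.ids), REFINED] = UNBINNED
        self._log(
            "unassign",
            {"ids": sorted(selection.ids)},
            affected=len(selection.ids),
        )

    def tag(self, bin_label: str, text: str) -> None:
        """Attach free-text notes to a refined bin."""
        self.tags[bin_label] = text
        self._log("tag", {"bin": bin_label, "text": text}, affected=0)

    def refined_column(self) -> pd.Series:
        return self.assignments.data[REFINED].copy()

    def refined_hash(self) -> str:
        """Order-independent digest of the refined column, for replay checks."""
        col = self.assignments.data[REFINED].sort_index()
        payload = "\n".join(f"{i}\t{v}" for i, v in col.items())
        return sha256(payload.encode()).hexdigest()


def replay(
    assignments: BinAssignmentTable,
    audit_log: Iterable[Mapping],
    features: FeatureMatrix | None = None,
    escg: ESCGTable | None = None,
    source_method: str | None = None,
) -> RefinementSession:
    """Re-run an audit log against a fresh session.

    Events carry resolved contig ids, so replay is deterministic
    regardless of feature availability.  A malformed event raises,
    naming its index; a truncated log simply yields the intermediate
    state at the truncation point.
    """
    session = RefinementSession(
        assignments, features=features, escg=escg, source_method=source_method
    )
    for i, event in enumerate(audit_log):
        try:
            op = event["op"]
            args = event["args"]
            if op in ("keep", "remove", "assign", "unassign"):
                ids = frozenset(args["ids"])
                sel = Selection(predicates=(), ids=ids)
            if op == "keep":
                session.keep(sel)
            elif op == "remove":
                session.remove(sel)
            elif op == "assign":
                session.assign(sel, args["bin"])
            elif op == "unassign":
                session.unassign(sel)
            elif op == "tag":
                session.tag(args["bin"], args["text"])
            else:
                raise BinrefError(f"unknown operation {op!r}")
        except (KeyError, TypeError) as exc:
            raise BinrefError(f"corrupted audit event at index {i}: {exc}") from exc
    return session


def session_from_state(
    state: Mapping,
    features: FeatureMatrix | None = None,
) -> RefinementSession:
    """Rebuild a session from an exported state document (see
    :func:`binref.io.export_state`): assignments are restored verbatim
    and the audit log replayed onto nothing is *not* needed — the state
    already holds the final column."""
    index = pd.Index(state["contig_ids"])
    data = pd.DataFrame(
        {m: pd.Series(vals, index=index) for m, vals in state["assignments"].items()}
    )
    refined = data[REFINED].copy() if REFINED in data else None
    table = BinAssignmentTable(data=data)
    session = RefinementSession(table, features=features)
    if refined is not None:
        session.assignments.data[REFINED] = refined
    session.working_set = set(state.get("working_set", index))
    session.tags = dict(state.get("tags", {}))
    session.audit_log = list(state.get("audit_log", []))
    return session
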