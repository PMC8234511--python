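"""Process mining of post-discharge care pathways.

An event log records timestamped care events per case (one case per
discharged patient): the discharge itself, monitoring contacts (primary
care GP, outpatient specialty clinic, accident & emergency), and a single
terminal event (readmission, death, or administrative end of follow-up).
From a log truncated to a 30- or 90-day horizon this module builds a
directly-follows process map — edges weighted by the number of moves
between activities with the median transition time in days — and
quantifies "unmonitored poor outcomes": readmissions or deaths with no
recorded care contact between discharge and the event.

Same-day events are ordered by activity priority (discharge, then
monitoring, then terminal events) to break timestamp ties.  Medians of an
even number of durations use the midpoint convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITIES",
    "MONITORING",
    "TERMINAL",
    "ProcessMap",
    "UnmonitoredStats",
    "validate_event_log",
    "truncate_to_horizon",
    "directly_follows",
    "unmonitored_outcome_stats",
    "read_event_log",
]

DISCHARGE = "discharge"
MONITORING = ("gp_monitoring", "outpatient_clinic", "accident_emergency")
TERMINAL = ("readmission", "death", "end_follow_up")
ACTIVITIES = (DISCHARGE, *MONITORING, *TERMINAL)

_PRIORITY = {DISCHARGE: 0, **{a: 1 for a in MONITORING}, **{a: 2 for a in TERMINAL}}


def _sorted_log(log: pd.DataFrame) -> pd.DataFrame:
    log = log.copy()
    log["timestamp"] = pd.to_datetime(log["timestamp"])
    log["_prio"] = log["activity"].map(_PRIORITY)
    log = log.sort_values(["case_id", "timestamp", "_prio"], kind="stable")
    return log.drop(columns="_prio").reset_index(drop=True)


def validate_event_log(log: pd.DataFrame) -> pd.DataFrame:
    """Check log structure; returns the canonically sorted log.

    Each case must start with exactly one discharge, events must be
    time-ordered (enforced by sorting with the tie-break priority), and no
    event may follow a terminal event.
    """
    required = {"case_id", "activity", "timestamp"}
    missing = required - set(log.columns)
    if missing:
        raise ValueError(f"event log is missing columns {sorted(missing)}")
    unknown = set(log["activity"].unique()) - set(ACTIVITIES)
    if unknown:
        raise ValueError(f"unknown activities {sorted(unknown)}; expected {ACTIVITIES}")
    log = _sorted_log(log)
    for cid, grp in log.groupby("case_id", sort=False):
        acts = grp["activity"].tolist()
        if acts.count(DISCHARGE) != 1 or acts[0] != DISCHARGE:
            raise ValueError(f"case {cid!r} must begin with exactly one discharge event")
        terminal_pos = [i for i, a in enumerate(acts) if a in TERMINAL]
        if terminal_pos and terminal_pos[0] != len(acts) - 1:
            raise ValueError(f"case {cid!r} has events after its terminal event")
    return log


def truncate_to_horizon(log: pd.DataFrame, horizon: int) -> pd.DataFrame:
    """Restrict each case to ``horizon`` days after discharge.

    Events beyond discharge + horizon are dropped; a case left without a
    terminal event receives ``end_follow_up`` exactly at the horizon
    boundary.
    """
    if len(log) == 0:
        return log.copy()
    log = validate_event_log(log)
    pieces = []
    for cid, grp in log.groupby("case_id", sort=False):
        cutoff = grp["timestamp"].iloc[0] + pd.Timedelta(days=horizon)
        kept = grp[grp["timestamp"] <= cutoff]
        if kept["activity"].iloc[-1] not in TERMINAL:
            kept = pd.concat(
                [
                    kept,
                    pd.DataFrame(
                        {"case_id": [cid], "activity": ["end_follow_up"], "timestamp": [cutoff]}
                    ),
                ],
                ignore_index=True,
            )
        pieces.append(kept)
    return pd.concat(pieces, ignore_index=True)


@dataclass(frozen=True)
class EdgeStats:
    n: int
    median_days: float


@dataclass
class ProcessMap:
    """Directly-follows graph: activity visit counts and weighted edges."""

    nodes: dict[str, int] = field(default_factory=dict)
    edges: dict[tuple[str, str], EdgeStats] = field(default_factory=dict)
    n_cases: int = 0

    def to_edge_table(self) -> pd.DataFrame:
        rows = [
            {"from": a, "to": b, "n": s.n, "median_days": s.median_days}
            for (a, b), s in sorted(self.edges.items(), key=lambda kv: -kv[1].n)
        ]
        return pd.DataFrame(rows, columns=["from", "to", "n", "median_days"])

    def top_k_edges(self, k: int) -> "ProcessMap":
        """Keep only the k most frequent edges (path filtering for display;
        no fidelity to any particular commercial tool's heuristics is
        claimed)."""
        keep = dict(sorted(self.edges.items(), key=lambda kv: -kv[1].n)[:k])
        return ProcessMap(nodes=dict(self.nodes), edges=keep, n_cases=self.n_cases)

    def to_dot(self) -> str:
        """Graphviz description for rendering a process-map diagram."""
        lines = ["digraph care_pathways {", "  rankdir=LR;"]
        for node, count in self.nodes.items():
            lines.append(f'  "{node}" [label="{node}\\n{count}"];')
        for (a, b), s in self.edges.items():
            lines.append(f'  "{a}" -> "{b}" [label="{s.n} ({s.median_days:g} d)"];')
        lines.append("}")
        return "\n".join(lines)


def directly_follows(log: pd.DataFrame) -> ProcessMap:
    """Build the directly-follows process map of a terminal-complete log.

    Each consecutive pair of events within a case contributes one edge
    occurrence; the edge time annotation is the median inter-event duration
    in days.  Node weights are visit counts, so flow is conserved: for
    every non-terminal activity, outgoing edge counts sum to its visits.
    """
    log = validate_event_log(log)
    durations: dict[tuple[str, str], list[float]] = {}
    nodes: dict[str, int] = {}
    n_cases = log["case_id"].nunique()
    for _, grp in log.groupby("case_id", sort=False):
        acts = grp["activity"].to_numpy()
        times = grp["timestamp"].to_numpy()
        for a in acts:
            nodes[a] = nodes.get(a, 0) + 1
        for i in range(len(acts) - 1):
            key = (acts[i], acts[i + 1])
            dt = (times[i + 1] - times[i]) / np.timedelta64(1, "D")
            durations.setdefault(key, []).append(float(dt))
    edges = {
        key: EdgeStats(n=len(vals), median_days=float(np.median(vals)))
        for key, vals in durations.items()
    }
    return ProcessMap(nodes=nodes, edges=edges, n_cases=int(n_cases))


@dataclass(frozen=True)
class UnmonitoredStats:
    """Unmonitored poor outcomes: count, fraction of poor-outcome cases, and
    median days from discharge to the outcome (absent when undefined)."""

    n_unmonitored: int
    n_poor_outcomes: int
    fraction: float | None
    median_days: float | None


def unmonitored_outcome_stats(
    log: pd.DataFrame, ae_is_monitoring: bool = True
) -> UnmonitoredStats:
    """Quantify poor outcomes reached without any intervening care contact.

    A case counts as an unmonitored poor outcome when its terminal event is
    a readmission or death and no monitoring event is recorded between
    discharge and that terminal event.  Whether an accident & emergency
    attendance counts as "monitoring" is configurable (it does by default);
    set ``ae_is_monitoring=False`` to treat A&E attendances as part of the
    unmonitored route back into hospital.
    """
    log = validate_event_log(log)
    monitoring = set(MONITORING) if ae_is_monitoring else {"gp_monitoring", "outpatient_clinic"}
    n_poor = 0
    unmonitored_days: list[float] = []
    for _, grp in log.groupby("case_id", sort=False):
        acts = grp["activity"].tolist()
        if acts[-1] not in ("readmission", "death"):
            continue
        n_poor += 1
        if not any(a in monitoring for a in acts[1:-1]):
            dt = (grp["timestamp"].iloc[-1] - grp["timestamp"].iloc[0]) / pd.Timedelta(days=1)
            unmonitored_days.append(float(dt))
    return UnmonitoredStats(
        n_unmonitored=len(unmonitored_days),
        n_poor_outcomes=n_poor,
        fraction=(len(unmonitored_days) / n_poor) if n_poor else None,
        median_days=float(np.median(unmonitored_days)) if unmonitored_days else None,
    )


def read_event_log(path) -> pd.DataFrame:
    """Read a delimited event log (case_id, activity, timestamp ISO 8601)."""
    log = pd.read_csv(path)
    return validate_event_log(log)
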