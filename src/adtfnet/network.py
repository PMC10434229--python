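"""Network timeline summaries: edge events, onset ordering, flow-RT coupling.

The significant-edge mask is reduced to maximal runs of consecutive
significant time points per directed edge; runs shorter than a persistence
threshold are discarded. Edges are then ranked by onset (ties merged within
a tolerance) and reciprocal pairs with overlapping activity are rendered
with the bidirectional label, giving the ordered connection steps of the
network timeline. Per-subject flow summaries are related to mean reaction
times by the Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .surrogates import SignificantNetwork


@dataclass
class EdgeEvent:
    source: int
    target: int
    onset: float
    offset: float
    mean_flow: float

    def label(self, names: list[str] | None = None) -> str:
        s = names[self.source] if names else str(self.source)
        t = names[self.target] if names else str(self.target)
        return f"{s}->{t}"


@dataclass
class OrderingSummary:
    """Edge sets ranked by onset; rank 1 is the earliest connection step."""

    ordered_steps: list[list[str]]
    onsets: list[float]
    window: tuple[float, float]


@dataclass
class FlowRTResult:
    edge: str
    r: float
    p: float
    n: int


def extract_edge_events(
    network: SignificantNetwork,
    observed: np.ndarray | None = None,
    min_duration: float = 0.02,
    window: tuple[float, float] | None = None,
) -> list[EdgeEvent]:
    """Maximal significant runs per directed edge, as events.

    ``observed`` (n, n, T) supplies the mean flow while active; defaults to
    the network's group-median flow. Runs shorter than ``min_duration``
    seconds are dropped. The event offset is the time of the last
    significant sample of the run.
    """
    times = network.times
    mask = network.mask
    flows = network.observed_median if observed is None else observed
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        times, mask, flows = times[sel], mask[:, :, sel], flows[:, :, sel]
    if times.size == 0:
        raise ValueError("the reporting window contains no time points")
    n = mask.shape[0]
    events: list[EdgeEvent] = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            row = mask[i, j]
            if not row.any():
                continue
            padded = np.concatenate([[False], row, [False]])
            change = np.flatnonzero(np.diff(padded.astype(int)))
            for start, stop in zip(change[::2], change[1::2]):
                onset, offset = times[start], times[stop - 1]
                if offset - onset < min_duration:
                    continue
                events.append(
                    EdgeEvent(
                        source=j, target=i, onset=float(onset), offset=float(offset),
                        mean_flow=float(flows[i, j, start:stop].mean()),
                    )
                )
    events.sort(key=lambda e: (e.onset, e.source, e.target))
    return events


def derive_ordering(
    events: list[EdgeEvent],
    tie_tol: float = 0.04,
    node_names: list[str] | None = None,
    window: tuple[float, float] = (0.2, 0.9),
) -> OrderingSummary:
    """Rank edges by onset, merging onsets closer than ``tie_tol`` seconds.

    Reciprocal events (i->j and j->i in the same rank group with overlapping
    activity) are merged into one bidirectional ``i<->j`` label.
    """
    if not events:
        return OrderingSummary([], [], window)
    ordered = sorted(events, key=lambda e: e.onset)
    groups: list[list[EdgeEvent]] = [[ordered[0]]]
    for ev in ordered[1:]:
        if ev.onset - groups[-1][0].onset <= tie_tol:
            groups[-1].append(ev)
        else:
            groups.append([ev])
    steps, onsets = [], []
    for group in groups:
        labels: list[str] = []
        used = set()
        for k, ev in enumerate(group):
            if k in used:
                continue
            partner = None
            for k2 in range(k + 1, len(group)):
                ev2 = group[k2]
                if k2 in used:
                    continue
                reciprocal = ev2.source == ev.target and ev2.target == ev.source
                overlap = min(ev.offset, ev2.offset) > max(ev.onset, ev2.onset)
                if reciprocal and overlap:
                    partner = k2
                    break
            if partner is not None:
                used.add(partner)
                a, b = sorted((ev.source, ev.target))
                sa = node_names[a] if node_names else str(a)
                sb = node_names[b] if node_names else str(b)
                labels.append(f"{sa}<->{sb}")
            else:
                labels.append(ev.label(node_names))
        steps.append(sorted(labels))
        onsets.append(float(min(ev.onset for ev in group)))
    return OrderingSummary(ordered_steps=steps, onsets=onsets, window=window)


def correlate_flow_rt(
    flows: np.ndarray, rts: np.ndarray, edge: str = ""
) -> FlowRTResult:
    """Pearson correlation between per-subject flow and mean reaction time.

    Two-sided p-value from the t distribution with n - 2 degrees of freedom.
    """
    flows = np.asarray(flows, dtype=float)
    rts = np.asarray(rts, dtype=float)
    if flows.shape != rts.shape or flows.ndim != 1:
        raise ValueError("flows and rts must be matched 1-D subject vectors")
    if flows.size < 3:
        raise ValueError("need at least 3 subjects")
    if flows.std() == 0 or rts.std() == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(flows, rts)
    return FlowRTResult(edge=edge, r=float(res.statistic), p=float(res.pvalue), n=flows.size)


def network_table(
    network: SignificantNetwork, node_names: list[str] | None = None
) -> pd.DataFrame:
    """Long-format edge table: one row per directed edge and time point."""
    n, _, T = network.mask.shape
    names = node_names or [str(i) for i in range(n)]
    rows = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for t in range(T):
                rows.append(
                    (
                        names[j], names[i], network.times[t],
                        network.observed_median[i, j, t],
                        network.per_edge_threshold[i, j, t],
                        network.p_group[i, j, t],
                        bool(network.mask[i, j, t]),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["source", "target", "time_s", "observed", "threshold",
                 "p_group", "significant"],
    )
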