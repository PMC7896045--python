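"""Compute-graph memory scheduling: Group Execution and Group Prefetch.

Training a network on an input far larger than accelerator memory is
possible when device memory is backed by host memory, but naive on-demand
paging thrashes: concurrently executing operations together demand more
intermediate-tensor space than the device holds, and pages ping-pong over
a slow link.  Two planning passes curb this:

* **Group Execution** — topologically sort the operation graph, then greedily
  cut the sequence into maximal contiguous groups whose summed
  intermediate-tensor footprints fit the memory budget.  Control
  dependencies serialise the groups, so concurrency exists only inside a
  group and the working set stays within budget.
* **Group Prefetch** — while group g executes, the data of group g+1 is
  brought in by explicit copy (fast, overlappable) instead of being paged
  on demand (slow, serialising).

A small analytic simulator compares the two transfer modes given per-group
compute times and link rates; published measurements on PCIe put on-demand
paging around 3.6 GB/s versus 10.3 GB/s for explicit copy, which are the
model defaults.
"""

from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

__all__ = [
    "OpNode",
    "GroupPlan",
    "SwapModel",
    "toposort",
    "plan_groups",
    "add_control_and_prefetch",
    "simulate_transfer",
    "plan_from_graph",
]

GB = 1e9


@dataclass(frozen=True)
class OpNode:
    id: str
    deps: tuple = ()
    intermediate_bytes: int = 0

    def __post_init__(self):
        if self.intermediate_bytes < 0:
            raise ValueError("intermediate_bytes must be >= 0")


@dataclass
class GroupPlan:
    groups: List[List[str]]
    budget_bytes: int
    group_bytes: List[int] = field(default_factory=list)
    control_deps: List[Tuple[str, str]] = field(default_factory=list)
    prefetch_ops: List[Dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "budget_bytes": self.budget_bytes,
                "groups": self.groups,
                "group_bytes": self.group_bytes,
                "control_deps": [list(e) for e in self.control_deps],
                "prefetch_ops": self.prefetch_ops,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroupPlan":
        doc = json.loads(text)
        return cls(
            groups=[list(g) for g in doc["groups"]],
            budget_bytes=doc["budget_bytes"],
            group_bytes=list(doc["group_bytes"]),
            control_deps=[tuple(e) for e in doc["control_deps"]],
            prefetch_ops=list(doc["prefetch_ops"]),
        )


@dataclass(frozen=True)
class SwapModel:
    ondemand_rate: float = 3.6 * GB   # bytes/s, on-demand page migration
    explicit_rate: float = 10.3 * GB  # bytes/s, explicit async copy
    overlap: bool = True

    def __post_init__(self):
        if self.ondemand_rate <= 0 or self.explicit_rate <= 0:
            raise ValueError("transfer rates must be positive")


def toposort(nodes: Sequence[OpNode]) -> List[OpNode]:
    """Deterministic Kahn topological sort; ties broken by smallest id."""
    by_id = {n.id: n for n in nodes}
    if len(by_id) != len(nodes):
        raise ValueError("duplicate op ids")
    indeg = {n.id: 0 for n in nodes}
    out = {n.id: [] for n in nodes}
    for n in nodes:
        for d in n.deps:
            if d not in by_id:
                raise ValueError(f"op {n.id!r} depends on unknown op {d!r}")
            indeg[n.id] += 1
            out[d].append(n.id)
    heap = [i for i, d in indeg.items() if d == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        i = heapq.heappop(heap)
        order.append(by_id[i])
        for j in sorted(out[i]):
            indeg[j] -= 1
            if indeg[j] == 0:
                heapq.heappush(heap, j)
    if len(order) != len(nodes):
        remaining = {i for i, d in indeg.items() if d > 0}
        culprit = min(remaining)
        dep = next(d for d in by_id[culprit].deps if d in remaining)
        raise ValueError(
            f"dependency cycle detected involving edge {dep!r} -> {culprit!r}"
        )
    return order


def plan_groups(sequence: Sequence[OpNode], budget_bytes: int) -> GroupPlan:
    """Greedy maximal-prefix grouping under the memory budget.

    Each group is the longest prefix of the remaining sequence whose summed
    intermediate bytes stay within ``budget_bytes``.  A single op larger
    than the budget forms its own (overflowing) group with a warning — it
    cannot be split at this level.
    """
    if budget_bytes <= 0:
        raise ValueError("budget_bytes must be positive")
    groups: List[List[str]] = []
    group_bytes: List[int] = []
    current: List[str] = []
    current_bytes = 0
    for op in sequence:
        b = op.intermediate_bytes
        if current and current_bytes + b > budget_bytes:
            groups.append(current)
            group_bytes.append(current_bytes)
            current, current_bytes = [], 0
        if b > budget_bytes:
            warnings.warn(
                f"op {op.id!r} alone exceeds the memory budget "
                f"({b} > {budget_bytes}); scheduling it as an overflowing "
                "singleton group"
            )
            groups.append([op.id])
            group_bytes.append(b)
            continue
        current.append(op.id)
        current_bytes += b
    if current:
        groups.append(current)
        group_bytes.append(current_bytes)
    return GroupPlan(groups=groups, budget_bytes=budget_bytes,
                     group_bytes=group_bytes)


def add_control_and_prefetch(plan: GroupPlan) -> GroupPlan:
    """Serialise groups with control edges and schedule one prefetch per
    upcoming group, issued during the preceding group."""
    plan.control_deps = []
    plan.prefetch_ops = []
    for g in range(len(plan.groups) - 1):
        plan.control_deps.append(
            (plan.groups[g][-1], plan.groups[g + 1][0])
        )
        plan.prefetch_ops.append(
            {
                "target_group": g + 1,
                "issued_during_group": g,
                "bytes": plan.group_bytes[g + 1],
            }
        )
    return plan


def simulate_transfer(plan: GroupPlan, swap: SwapModel,
                      compute_time_per_group: Sequence[float]) -> Dict:
    """Analytic wall-time of the plan under both transfer modes.

    On-demand: each group's data is paged in at ``ondemand_rate``,
    serialised with its compute.  Prefetch: the first group's data loads
    up-front at ``explicit_rate``; thereafter group g's compute overlaps
    the explicit-copy prefetch of group g+1, so each slot costs
    ``max(compute_g, prefetch_{g+1})`` (no overlap: they add).
    """
    ct = list(compute_time_per_group)
    if len(ct) != len(plan.groups):
        raise ValueError("need one compute time per group")
    total_bytes = float(sum(plan.group_bytes))

    ondemand_time = sum(
        c + b / swap.ondemand_rate for c, b in zip(ct, plan.group_bytes)
    )

    prefetch_time = plan.group_bytes[0] / swap.explicit_rate if ct else 0.0
    for g, c in enumerate(ct):
        nxt = (plan.group_bytes[g + 1] / swap.explicit_rate
               if g + 1 < len(ct) else 0.0)
        if swap.overlap:
            prefetch_time += max(c, nxt)
        else:
            prefetch_time += c + nxt
    return {
        "ondemand": {"total_time": float(ondemand_time),
                     "bytes_moved": total_bytes},
        "prefetch": {"total_time": float(prefetch_time),
                     "bytes_moved": total_bytes},
    }


def plan_from_graph(nodes: Sequence[OpNode], budget_bytes: int) -> GroupPlan:
    """toposort + group + control/prefetch in one call."""
    return add_control_and_prefetch(
        plan_groups(toposort(nodes), budget_bytes)
    )
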