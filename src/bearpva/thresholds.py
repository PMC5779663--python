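"""Scenario enumeration and demographic-threshold extraction.

A grown classification tree on short-term monitoring statistics
(5-year means of abundance, apparent survival and growth rate) partitions
the predictor space into *scenarios*: root-to-leaf conjunctions of
threshold conditions, each with the persistence probability observed in
its leaf. A scenario is *reliable* when that probability reaches a target
(0.95 by default). The headline monitoring trigger is the smallest lower
bound on 5-year mean apparent survival among reliable scenarios whose
conditions involve survival alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .citree import ConditionalTree, TreeNode


@dataclass(frozen=True)
class Condition:
    """One split condition along a path: ``var <= threshold`` or ``var > threshold``."""

    var: str
    op: str  # "<=" or ">"
    threshold: float

    def matches(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value > self.threshold

    def __str__(self) -> str:
        return f"{self.var} {self.op} {self.threshold:.6g}"


@dataclass(frozen=True)
class ScenarioRule:
    """A root-to-leaf path with its leaf persistence probability and support."""

    conditions: tuple[Condition, ...]
    persistence: float
    support: int

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(c.var for c in self.conditions)

    def matches_row(self, row) -> bool:
        return all(c.matches(float(row[c.var])) for c in self.conditions)

    def __str__(self) -> str:
        conds = " AND ".join(str(c) for c in self.conditions) or "(always)"
        return f"{conds}  ->  persistence {self.persistence:.3f} (n={self.support})"


def enumerate_scenarios(tree: ConditionalTree) -> list[ScenarioRule]:
    """One :class:`ScenarioRule` per leaf, in left-to-right leaf order.

    The rules partition the predictor space: every point satisfies exactly
    one rule, and rule supports sum to the training size.
    """
    out: list[ScenarioRule] = []

    def _walk(node: TreeNode, conds: tuple[Condition, ...]) -> None:
        if node.is_leaf:
            out.append(
                ScenarioRule(
                    conditions=conds,
                    persistence=node.extant_fraction,
                    support=node.n,
                )
            )
            return
        _walk(node.left, conds + (Condition(node.var, "<=", node.threshold),))
        _walk(node.right, conds + (Condition(node.var, ">", node.threshold),))

    _walk(tree.root, ())
    return out


def reliable_scenarios(
    scenarios: list[ScenarioRule],
    min_persistence: float = 0.95,
) -> list[ScenarioRule]:
    """Scenarios with persistence >= ``min_persistence``, best first.

    An empty result is a legitimate finding (no monitoring state of the
    tree guarantees the target persistence), not an error.
    """
    keep = [s for s in scenarios if s.persistence >= min_persistence]
    return sorted(keep, key=lambda s: -s.persistence)


def min_survival_threshold(
    scenarios: list[ScenarioRule],
    survival_var: str = "phibar5",
) -> float | None:
    """Minimum survival lower bound among survival-only scenarios.

    A scenario qualifies when every condition on its path references
    ``survival_var`` and at least one of them is a lower bound
    (``survival_var > c``); its threshold is the largest such lower bound
    (the binding one). Returns the minimum over qualifying scenarios, or
    ``None`` when there is no survival-only scenario — e.g. when every
    reliable path also constrains abundance or growth rate.

    Pass the *reliable* subset to obtain the monitoring trigger.
    """
    bounds: list[float] = []
    for s in scenarios:
        if not s.conditions or s.variables != {survival_var}:
            continue
        lower = [c.threshold for c in s.conditions if c.op == ">"]
        if lower:
            bounds.append(max(lower))
    return min(bounds) if bounds else None


def route_rows(scenarios: list[ScenarioRule], table) -> np.ndarray:
    """Index of the (unique) scenario matched by each row of ``table``.

    Raises if any row matches zero or multiple scenarios — i.e. if the
    rules do not partition the space, which for rules enumerated from one
    tree would indicate a bug.
    """
    n = len(table)
    assignment = np.full(n, -1, dtype=np.int64)
    for j, rule in enumerate(scenarios):
        mask = np.ones(n, dtype=bool)
        for c in rule.conditions:
            vals = np.asarray(table[c.var], dtype=float)
            mask &= (vals <= c.threshold) if c.op == "<=" else (vals > c.threshold)
        if np.any(assignment[mask] != -1):
            raise ValueError(f"rows matched by multiple scenarios (rule {j})")
        assignment[mask] = j
    if np.any(assignment == -1):
        raise ValueError("some rows matched no scenario")
    return assignment


def scenarios_to_dict(scenarios: list[ScenarioRule]) -> list[dict]:
    return [
        {
            "conditions": [
                {"var": c.var, "op": c.op, "threshold": c.threshold} for c in s.conditions
            ],
            "persistence": s.persistence,
            "support": s.support,
        }
        for s in scenarios
    ]


def scenarios_from_dict(payload: list[dict]) -> list[ScenarioRule]:
    return [
        ScenarioRule(
            conditions=tuple(
                Condition(c["var"], c["op"], float(c["threshold"])) for c in s["conditions"]
            ),
            persistence=float(s["persistence"]),
            support=int(s["support"]),
        )
        for s in payload
    ]


def render_tree(tree: ConditionalTree) -> str:
    """Plain-text indented rendering of a tree, leaves annotated with persistence."""
    lines: list[str] = []

    def _walk(node: TreeNode, prefix: str, label: str) -> None:
        if node.is_leaf:
            lines.append(
                f"{prefix}{label}leaf: n={node.n}, persistence={node.extant_fraction:.3f}"
            )
            return
        lines.append(f"{prefix}{label}split on {node.var} at {node.threshold:.6g} (n={node.n})")
        _walk(node.left, prefix + "  ", f"[{node.var} <= {node.threshold:.6g}] ")
        _walk(node.right, prefix + "  ", f"[{node.var} > {node.threshold:.6g}] ")

    _walk(tree.root, "", "")
    return "\n".join(lines)
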