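"""Configurable START-family primary-triage decision engine.

A triage algorithm (ASAV, START, mSTART, ...) is represented as a small
decision tree read from a YAML document.  Each internal node tests exactly
one clinical finding (e.g. ability to walk, respiratory rate, radial pulse)
and routes to a child node or to a leaf triage category; edges may be
annotated with one of the two life-saving interventions the algorithm family
knows (bleeding control, oropharyngeal tube).  Keeping the tree declarative
means every clinical cut-off lives in one reviewable config file and the
same engine executes any algorithm of the family.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "TriageCategory",
    "Intervention",
    "Predicate",
    "Edge",
    "DecisionNode",
    "DecisionTree",
    "TriageDecision",
    "TreeSpecError",
    "MissingFindingError",
    "load_tree",
    "load_bundled_tree",
    "apply_algorithm",
]


class TriageCategory(enum.Enum):
    """The four primary-triage categories (tag colors)."""

    RED = "RED"        # I   - immediate treatment and/or transport
    YELLOW = "YELLOW"  # II  - delayed treatment and transport
    GREEN = "GREEN"    # III - minor injuries
    DEAD = "DEAD"      # black

    @property
    def urgency(self) -> int:
        """Ordering used by the over/under-triage taxonomy (RED highest)."""
        return _URGENCY[self]


_URGENCY = {
    TriageCategory.RED: 3,
    TriageCategory.YELLOW: 2,
    TriageCategory.GREEN: 1,
    TriageCategory.DEAD: 0,
}


class Intervention(enum.Enum):
    BLEEDING_CONTROL = "BLEEDING_CONTROL"
    OROPHARYNGEAL_TUBE = "OROPHARYNGEAL_TUBE"


class TreeSpecError(ValueError):
    """Structural problem in a tree config (cycle, gap, bad node...)."""


class MissingFindingError(KeyError):
    """A vignette lacks a finding the traversed path needs."""

    def __init__(self, finding_key: str, node_id: str):
        super().__init__(finding_key)
        self.finding_key = finding_key
        self.node_id = node_id

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"vignette is missing finding {self.finding_key!r} required at node {self.node_id!r}"


# --------------------------------------------------------------------------
# Finding domains and predicates


@dataclass(frozen=True)
class FindingDomain:
    """Declared domain of one finding: bool, enum of tokens, or int range."""

    key: str
    kind: str                      # "bool" | "enum" | "int"
    values: tuple[Any, ...] = ()   # enum tokens (bool: (False, True))
    lo: int | None = None          # int range, inclusive
    hi: int | None = None


@dataclass(frozen=True)
class Predicate:
    """Total-checkable predicate over one finding domain.

    Categorical/bool findings use an explicit match set; numeric findings use
    a half-open interval [lo, hi) on the declared range.
    """

    match: frozenset | None = None
    lo: float | None = None
    hi: float | None = None

    def __call__(self, value: Any) -> bool:
        if self.match is not None:
            return value in self.match
        ok = True
        if self.lo is not None:
            ok = ok and value >= self.lo
        if self.hi is not None:
            ok = ok and value < self.hi
        return ok

    def describe(self) -> str:
        if self.match is not None:
            return "in {" + ", ".join(map(str, sorted(self.match, key=str))) + "}"
        lo = "-inf" if self.lo is None else str(self.lo)
        hi = "+inf" if self.hi is None else str(self.hi)
        return f"in [{lo}, {hi})"


@dataclass(frozen=True)
class Edge:
    predicate: Predicate
    category: TriageCategory | None = None   # leaf outcome
    next_node: str | None = None             # or child node id
    intervention: Intervention | None = None


@dataclass(frozen=True)
class DecisionNode:
    id: str
    finding_key: str
    edges: tuple[Edge, ...]


@dataclass
class DecisionTree:
    name: str
    root: str
    nodes: dict[str, DecisionNode]
    findings: dict[str, FindingDomain]
    # categories reachable from each node (filled at validation time);
    # used by the cohort simulator to bias wrong-branch choices.
    subtree_categories: dict[str, frozenset[TriageCategory]] = field(default_factory=dict)

    @property
    def leaf_categories(self) -> frozenset[TriageCategory]:
        return self.subtree_categories[self.root]

    def edge_categories(self, edge: Edge) -> frozenset[TriageCategory]:
        if edge.category is not None:
            return frozenset({edge.category})
        return self.subtree_categories[edge.next_node]


@dataclass(frozen=True)
class TriageDecision:
    """Outcome of running one vignette through the algorithm."""

    category: TriageCategory
    interventions: frozenset[Intervention]
    path: tuple[str, ...]
    tag: str | None

    @staticmethod
    def tag_for(category: TriageCategory) -> str | None:
        # Green patients are not tagged; dead patients get a black band.
        if category is TriageCategory.GREEN:
            return None
        if category is TriageCategory.DEAD:
            return "black"
        return category.value.lower()


# --------------------------------------------------------------------------
# Loading and validation


def _parse_domain(key: str, spec: Mapping[str, Any]) -> FindingDomain:
    kind = spec.get("type")
    if kind == "bool":
        return FindingDomain(key, "bool", values=(False, True))
    if kind == "enum":
        vals = spec.get("values")
        if not vals:
            raise TreeSpecError(f"finding {key!r}: enum domain needs non-empty 'values'")
        return FindingDomain(key, "enum", values=tuple(vals))
    if kind == "int":
        lo, hi = spec.get("min"), spec.get("max")
        if lo is None or hi is None or hi < lo:
            raise TreeSpecError(f"finding {key!r}: int domain needs valid 'min'/'max'")
        return FindingDomain(key, "int", lo=int(lo), hi=int(hi))
    raise TreeSpecError(f"finding {key!r}: unknown domain type {kind!r}")


def _parse_predicate(node_id: str, dom: FindingDomain, when: Any) -> Predicate:
    if dom.kind in ("bool", "enum"):
        if isinstance(when, Mapping) and "in" in when:
            vals = when["in"]
        else:
            vals = [when]
        bad = [v for v in vals if v not in dom.values]
        if bad:
            raise TreeSpecError(
                f"node {node_id!r}: predicate values {bad} outside domain of {dom.key!r}"
            )
        return Predicate(match=frozenset(vals))
    if not isinstance(when, Mapping) or not ({"ge", "lt"} & set(when)):
        raise TreeSpecError(
            f"node {node_id!r}: numeric finding {dom.key!r} needs a ge/lt predicate"
        )
    return Predicate(lo=when.get("ge"), hi=when.get("lt"))


def _check_totality(node: DecisionNode, dom: FindingDomain) -> None:
    """Edges must partition the finding's declared domain."""
    if dom.kind in ("bool", "enum"):
        seen: list[Any] = []
        for e in node.edges:
            seen.extend(e.predicate.match)
        if len(seen) != len(set(seen)):
            raise TreeSpecError(f"node {node.id!r}: overlapping predicates on {dom.key!r}")
        missing = set(dom.values) - set(seen)
        if missing:
            raise TreeSpecError(
                f"node {node.id!r}: predicates on {dom.key!r} do not cover {sorted(map(str, missing))}"
            )
    else:
        # integer range: every point must match exactly one edge
        for v in range(dom.lo, dom.hi + 1):
            hits = sum(e.predicate(v) for e in node.edges)
            if hits != 1:
                raise TreeSpecError(
                    f"node {node.id!r}: value {v} of {dom.key!r} matched by {hits} edges (want 1)"
                )


def load_tree(spec: Mapping[str, Any] | str) -> DecisionTree:
    """Build and validate a :class:`DecisionTree` from a config document.

    ``spec`` is a mapping (already-parsed YAML) or a YAML string.  Validation
    rejects cycles, unreachable nodes, dangling child references,
    non-exhaustive or overlapping predicates, and nodes carrying more than
    one intervention annotation.
    """
    if isinstance(spec, str):
        spec = yaml.safe_load(spec)
    name = spec.get("name", "unnamed")
    raw_findings = spec.get("findings") or {}
    if not raw_findings:
        raise TreeSpecError("tree config declares no findings")
    findings = {k: _parse_domain(k, v) for k, v in raw_findings.items()}

    raw_nodes = spec.get("nodes") or []
    if not raw_nodes:
        raise TreeSpecError("tree config declares no nodes")
    nodes: dict[str, DecisionNode] = {}
    for rn in raw_nodes:
        nid = rn.get("id")
        if not nid or nid in nodes:
            raise TreeSpecError(f"node id {nid!r} missing or duplicated")
        fkey = rn.get("finding")
        if fkey not in findings:
            raise TreeSpecError(f"node {nid!r}: unknown finding {fkey!r}")
        dom = findings[fkey]
        edges = []
        n_interventions = 0
        for re_ in rn.get("edges") or []:
            pred = _parse_predicate(nid, dom, re_.get("when"))
            cat = re_.get("category")
            nxt = re_.get("next")
            if (cat is None) == (nxt is None):
                raise TreeSpecError(f"node {nid!r}: edge needs exactly one of 'category'/'next'")
            iv = re_.get("intervention")
            if iv is not None:
                n_interventions += 1
                iv = Intervention(iv)
            edges.append(
                Edge(
                    predicate=pred,
                    category=None if cat is None else TriageCategory(cat),
                    next_node=nxt,
                    intervention=iv,
                )
            )
        if not edges:
            raise TreeSpecError(f"node {nid!r}: no edges")
        if n_interventions > 1:
            raise TreeSpecError(f"node {nid!r}: more than one intervention annotation")
        nodes[nid] = DecisionNode(id=nid, finding_key=fkey, edges=tuple(edges))
        _check_totality(nodes[nid], dom)

    root = spec.get("root") or raw_nodes[0]["id"]
    if root not in nodes:
        raise TreeSpecError(f"root node {root!r} not defined")

    # child references, reachability, acyclicity
    for n in nodes.values():
        for e in n.edges:
            if e.next_node is not None and e.next_node not in nodes:
                raise TreeSpecError(f"node {n.id!r}: edge points to unknown node {e.next_node!r}")

    order: list[str] = []           # reverse-finish DFS order
    state: dict[str, int] = {}      # 0 visiting / 1 done
    def dfs(nid: str, stack: tuple[str, ...]) -> None:
        if nid in stack:
            raise TreeSpecError(f"cycle through node {nid!r}")
        if state.get(nid) == 1:
            return
        for e in nodes[nid].edges:
            if e.next_node is not None:
                dfs(e.next_node, stack + (nid,))
        state[nid] = 1
        order.append(nid)

    dfs(root, ())
    unreachable = set(nodes) - set(order)
    if unreachable:
        raise TreeSpecError(f"unreachable nodes: {sorted(unreachable)}")

    tree = DecisionTree(name=name, root=root, nodes=nodes, findings=findings)
    for nid in order:  # children precede parents
        cats: set[TriageCategory] = set()
        for e in nodes[nid].edges:
            if e.category is not None:
                cats.add(e.category)
            else:
                cats |= tree.subtree_categories[e.next_node]
        tree.subtree_categories[nid] = frozenset(cats)
    return tree


def load_bundled_tree(name: str) -> DecisionTree:
    """Load one of the algorithm configs shipped with the package
    (``"asav"`` or ``"start_demo"``)."""
    ref = importlib.resources.files("triagesim") / "configs" / f"{name}.yaml"
    return load_tree(ref.read_text())


# --------------------------------------------------------------------------
# Execution


def apply_algorithm(vignette: Mapping[str, Any] | Any, tree: DecisionTree) -> TriageDecision:
    """Run the algorithm on a vignette; pure and deterministic.

    ``vignette`` is a mapping of finding keys to values, or any object with a
    ``findings`` mapping attribute.  Interventions are exactly those
    annotated on the traversed edges.
    """
    findings = getattr(vignette, "findings", vignette)
    nid = tree.root
    path: list[str] = []
    interventions: set[Intervention] = set()
    while True:
        node = tree.nodes[nid]
        path.append(nid)
        if node.finding_key not in findings:
            raise MissingFindingError(node.finding_key, nid)
        value = findings[node.finding_key]
        edge = next((e for e in node.edges if e.predicate(value)), None)
        if edge is None:  # unreachable on a validated tree
            raise TreeSpecError(
                f"node {nid!r}: no edge matches {node.finding_key}={value!r}"
            )
        if edge.intervention is not None:
            interventions.add(edge.intervention)
        if edge.category is not None:
            return TriageDecision(
                category=edge.category,
                interventions=frozenset(interventions),
                path=tuple(path),
                tag=TriageDecision.tag_for(edge.category),
            )
        nid = edge.next_node


def enumerate_paths(tree: DecisionTree) -> Iterable[tuple[tuple[str, ...], TriageCategory]]:
    """Yield every root-to-leaf (path, category) pair (oracle helper)."""
    def walk(nid: str, path: tuple[str, ...]):
        node = tree.nodes[nid]
        for e in node.edges:
            if e.category is not None:
                yield path + (nid,), e.category
            else:
                yield from walk(e.next_node, path + (nid,))
    yield from walk(tree.root, ())
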