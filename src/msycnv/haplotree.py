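"""MSY haplogroup assignment along a hierarchical backbone tree.

Horse paternal lineages are classified by a small panel of Y variants
(29 SNVs and one short indel in the default panel), each defining one edge
of a rooted backbone tree whose nodes are haplogroups (HGs) and haplotypes
(HTs).  Genotyping in the lab proceeds sequentially: the Crown haplogroup
gate (marker rAX) is typed first, then only the markers informative for the
substructure the sample falls into.  Samples stopping at an internal node
carry not-yet-resolved haplotypes; untyped markers are imputed from the
root-to-node path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

MISSING = None  # sentinel for an untyped marker


class TreeConfigError(ValueError):
    """Malformed backbone configuration (cycles, orphans, duplicates...)."""


class InconsistentGenotypeError(ValueError):
    """Observed alleles contradict any single root-to-node path."""


class UnassignableError(ValueError):
    """The root gate marker was not typed; no placement is possible."""


@dataclass(frozen=True)
class MarkerDef:
    """One tree-defining variant: its edge and ancestral/derived alleles."""

    name: str
    edge: str  # child node whose parent edge the derived allele defines
    ancestral: str
    derived: str
    kind: str = "SNV"  # "SNV" or "indel"

    def __post_init__(self) -> None:
        if self.ancestral.lower() == self.derived.lower():
            raise TreeConfigError(f"marker {self.name}: ancestral == derived")


@dataclass(frozen=True)
class HTAssignment:
    """Placement of one male on the backbone."""

    node: str
    resolved: bool  # True when a leaf HT was reached
    imputed_profile: str
    path: tuple[str, ...]  # root .. node


class BackboneTree:
    """Rooted haplogroup hierarchy with marker-bearing edges."""

    def __init__(self, root: str, parent: Mapping[str, str], markers: Sequence[MarkerDef],
                 gate_marker: str | None = None, name: str = "backbone") -> None:
        self.name = name
        self.root = root
        self.parent = dict(parent)
        self.markers = list(markers)
        self.gate_marker = gate_marker
        self._validate()
        self.children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for child, par in self.parent.items():
            self.children[par].append(child)
        self.edge_markers: dict[str, list[MarkerDef]] = {n: [] for n in self.nodes}
        for m in self.markers:
            self.edge_markers[m.edge].append(m)
        self.marker_by_name = {m.name: m for m in self.markers}

    # -- structure ---------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return [self.root, *self.parent.keys()]

    def is_leaf(self, node: str) -> bool:
        return not self.children[node]

    def leaves(self) -> list[str]:
        return [n for n in self.nodes if self.is_leaf(n)]

    def path_to(self, node: str) -> tuple[str, ...]:
        """Node labels from the root down to ``node`` (inclusive)."""
        if node != self.root and node not in self.parent:
            raise KeyError(f"unknown node {node!r}")
        path = [node]
        seen = {node}
        while path[-1] != self.root:
            nxt = self.parent[path[-1]]
            if nxt in seen:  # unreachable after validation; defensive
                raise TreeConfigError("cycle detected")
            path.append(nxt)
            seen.add(nxt)
        return tuple(reversed(path))

    def path_markers(self, node: str) -> set[str]:
        """Names of markers whose derived allele lies on the root->node path."""
        return {
            m.name
            for edge_child in self.path_to(node)[1:]
            for m in self.edge_markers[edge_child]
        }

    def subtree_markers(self, node: str) -> set[str]:
        """Marker names on ``node``'s parent edge and every edge below it."""
        names = set() if node == self.root else {m.name for m in self.edge_markers[node]}
        for c in self.children[node]:
            names |= self.subtree_markers(c)
        return names

    def _validate(self) -> None:
        if self.root in self.parent:
            raise TreeConfigError("root must not have a parent")
        labels = self.nodes
        if len(set(labels)) != len(labels):
            raise TreeConfigError("duplicate node labels")
        known = set(labels)
        for child, par in self.parent.items():
            if par not in known:
                raise TreeConfigError(f"node {child!r} has unknown parent {par!r}")
        # reachability from root (rejects cycles / disconnected components)
        for node in self.parent:
            seen: set[str] = set()
            cur = node
            while cur != self.root:
                if cur in seen:
                    raise TreeConfigError(f"cycle involving {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TreeConfigError(f"marker(s) mapped to more than one edge: {dup}")
        for m in self.markers:
            if m.edge not in self.parent:
                raise TreeConfigError(
                    f"marker {m.name}: edge node {m.edge!r} missing or is the root"
                )
        bare = [n for n in self.parent if not any(m.edge == n for m in self.markers)]
        if bare:
            raise TreeConfigError(f"edges without markers: {sorted(bare)}")
        if self.gate_marker is not None and self.gate_marker not in names:
            raise TreeConfigError(f"gate marker {self.gate_marker!r} not in panel")

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "BackboneTree":
        try:
            root = cfg["root"]
            nodes = dict(cfg["nodes"])
            markers = [MarkerDef(**m) for m in cfg["markers"]]
        except (KeyError, TypeError) as exc:
            raise TreeConfigError(f"malformed backbone config: {exc}") from exc
        return cls(root=root, parent=nodes, markers=markers,
                   gate_marker=cfg.get("gate_marker"), name=cfg.get("name", "backbone"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BackboneTree":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, Mapping):
            raise TreeConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(cfg)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "root": self.root,
            "gate_marker": self.gate_marker,
            "nodes": dict(self.parent),
            "markers": [
                {"name": m.name, "edge": m.edge, "kind": m.kind,
                 "ancestral": m.ancestral, "derived": m.derived}
                for m in self.markers
            ],
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_backbone() -> BackboneTree:
    """The bundled condensed horse MSY backbone (see data/backbone.yaml)."""
    from importlib.resources import files

    return BackboneTree.from_yaml(str(files("msycnv.data") / "backbone.yaml"))


load_backbone = BackboneTree.from_yaml


# -- genotype handling -----------------------------------------------------

_DERIVED, _ANCESTRAL, _UNTYPED = "derived", "ancestral", "untyped"


def _allele_state(tree: BackboneTree, marker: str, allele: str | None) -> str:
    if allele is MISSING or (isinstance(allele, float) and pd.isna(allele)):
        return _UNTYPED
    m = tree.marker_by_name.get(marker)
    if m is None:
        raise KeyError(f"marker {marker!r} not in panel")
    a = str(allele).strip().lower()
    if a in ("", "missing", "nan", "."):
        return _UNTYPED
    if a == m.derived.lower():
        return _DERIVED
    if a == m.ancestral.lower():
        return _ANCESTRAL
    raise InconsistentGenotypeError(
        f"marker {marker}: observed allele {allele!r} is neither "
        f"ancestral ({m.ancestral}) nor derived ({m.derived})"
    )


def _edge_state(tree: BackboneTree, child: str, genotype: Mapping[str, str | None]) -> str:
    states = {
        _allele_state(tree, m.name, genotype.get(m.name, MISSING))
        for m in tree.edge_markers[child]
    }
    if _DERIVED in states and _ANCESTRAL in states:
        raise InconsistentGenotypeError(
            f"conflicting allele states among markers on edge to {child!r}"
        )
    if _DERIVED in states:
        return _DERIVED
    if _ANCESTRAL in states:
        return _ANCESTRAL
    return _UNTYPED


def next_markers(tree: BackboneTree, node: str) -> list[str]:
    """Markers to type next from ``node``: those on its child edges, in panel order."""
    if node != tree.root and node not in tree.parent:
        raise KeyError(f"unknown node {node!r}")
    child_set = set(tree.children[node])
    return [m.name for m in tree.markers if m.edge in child_set]


def assign_haplotype(
    genotype: Mapping[str, str | None], tree: BackboneTree
) -> HTAssignment:
    """Place a genotype on the backbone by hierarchical descent from the root.

    At each node the unique child edge observed in the derived state is
    followed; descent stops at a leaf, or at an internal node when every
    child edge is ancestral or untyped.  Derived alleles on two sibling
    edges, or off the final path, raise :class:`InconsistentGenotypeError`;
    an untyped gate marker raises :class:`UnassignableError`.
    """
    if tree.gate_marker is not None:
        gate = genotype.get(tree.gate_marker, MISSING)
        if _allele_state(tree, tree.gate_marker, gate) == _UNTYPED:
            raise UnassignableError(
                f"gate marker {tree.gate_marker!r} untyped; sample cannot be placed"
            )
    observed_derived = {
        m.name
        for m in tree.markers
        if _allele_state(tree, m.name, genotype.get(m.name, MISSING)) == _DERIVED
    }
    node = tree.root
    while not tree.is_leaf(node):
        derived = []
        for c in tree.children[node]:
            state = _edge_state(tree, c, genotype)
            below = bool(observed_derived & tree.subtree_markers(c))
            if state == _ANCESTRAL and observed_derived & (
                tree.subtree_markers(c) - {m.name for m in tree.edge_markers[c]}
            ):
                raise InconsistentGenotypeError(
                    f"derived alleles below {c!r} despite ancestral edge state"
                )
            # an untyped edge still counts as derived when markers deeper in
            # its subtree were observed derived (tree-consistent genotypes)
            if state == _DERIVED or (state == _UNTYPED and below):
                derived.append(c)
        if len(derived) > 1:
            raise InconsistentGenotypeError(
                f"derived alleles on sibling edges {sorted(derived)} below {node!r}"
            )
        if not derived:
            break
        node = derived[0]
    profile = impute_profile(node, tree, observed=genotype)
    return HTAssignment(
        node=node,
        resolved=tree.is_leaf(node),
        imputed_profile=profile,
        path=tree.path_to(node),
    )


def impute_profile(
    node: str, tree: BackboneTree, observed: Mapping[str, str | None] | None = None
) -> str:
    """Concatenated allele string over the full panel for a placement.

    Markers on the root->node path take their derived allele, all others the
    ancestral allele.  Observed genotypes are never overwritten: an observed
    allele contradicting the path raises :class:`InconsistentGenotypeError`.
    """
    on_path = tree.path_markers(node)
    alleles: list[str] = []
    for m in tree.markers:
        expected = m.derived if m.name in on_path else m.ancestral
        if observed is not None:
            state = _allele_state(tree, m.name, observed.get(m.name, MISSING))
            if state != _UNTYPED:
                seen = m.derived if state == _DERIVED else m.ancestral
                if seen != expected:
                    raise InconsistentGenotypeError(
                        f"marker {m.name}: observed {seen} contradicts placement "
                        f"at {node!r} (expected {expected})"
                    )
        alleles.append(expected)
    return "".join(alleles)


def genotype_from_long(df: pd.DataFrame, sample_id: str | None = None) -> dict[str, str | None]:
    """Build a genotype mapping from long-format calls (sample_id, marker, allele)."""
    sub = df if sample_id is None else df[df["sample_id"].astype(str) == str(sample_id)]
    out: dict[str, str | None] = {}
    for rec in sub.itertuples(index=False):
        allele = rec.allele
        out[str(rec.marker)] = None if pd.isna(allele) else str(allele)
    return out


def assign_table(genotypes: pd.DataFrame, tree: BackboneTree) -> pd.DataFrame:
    """Assign every sample in a long genotype table; one output row each."""
    rows = []
    for sid, sub in genotypes.groupby("sample_id", sort=True):
        g = genotype_from_long(sub)
        a = assign_haplotype(g, tree)
        hg = a.path[1] if len(a.path) > 1 else tree.root
        rows.append({
            "sample_id": sid,
            "hg": hg,
            "ht": a.node,
            "resolved": a.resolved,
            "imputed_profile": a.imputed_profile,
        })
    return pd.DataFrame(rows)


def ht_frequencies(assignments: Iterable[str | HTAssignment], tree: BackboneTree) -> pd.DataFrame:
    """Counts per tree node (zero-count nodes retained), in traversal order."""
    labels = [a.node if isinstance(a, HTAssignment) else str(a) for a in assignments]
    counts = pd.Series(labels).value_counts().to_dict()
    order: list[str] = []

    def _walk(node: str) -> None:
        order.append(node)
        for c in tree.children[node]:
            _walk(c)

    _walk(tree.root)
    unknown = set(counts) - set(order)
    if unknown:
        raise KeyError(f"assignments to unknown nodes: {sorted(unknown)}")
    return pd.DataFrame({"node": order, "count": [counts.get(n, 0) for n in order]})


def plot_ht_frequencies(freqs: pd.DataFrame, tree: BackboneTree, path: str | Path) -> None:
    """Frequency plot with circle radius proportional to the clustered count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    depth = {n: len(tree.path_to(n)) - 1 for n in tree.nodes}
    xs = {n: i for i, n in enumerate(freqs["node"])}
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(freqs)), 4))
    counts = freqs.set_index("node")["count"]
    for n in freqs["node"]:
        c = counts[n]
        ax.scatter(xs[n], -depth[n], s=40 * max(c, 0.2), alpha=0.7,
                   color="tab:blue" if c else "lightgray")
        ax.annotate(f"{n}\n{c}" if c else n, (xs[n], -depth[n]),
                    textcoords="offset points", xytext=(0, 8),
                    ha="center", fontsize=7)
    ax.set_axis_off()
    ax.set_title("MSY haplotype frequencies (circle area ∝ count)")
    fig.tight_layout()
    fig.savefig(str(path), format="svg")
    plt.close(fig)
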