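"""Lineage-sorting analytics over posterior samples of gene trees.

A tree sample (e.g. pooled MCMC runs after burn-in) is scored for how
often a named group of tips forms an exclusive clade once the tree is
rooted with the outgroup.  Rather than physically rerooting, every edge's
bipartition is polarized by the outgroup: the side not containing the
outgroup is a clade of the rooted tree.  Posterior support is the fraction
of sampled trees containing the clade; by the reporting convention used
here, support > 0.95 counts as monophyly, < 0.05 as paraphyly, anything
between is ambiguous.  The strict-majority consensus keeps exactly the
clades present in more than half the sample (50% exactly is excluded),
which are compatible by construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy

MONOPHYLY_SUPPORT = 0.95
PARAPHYLY_SUPPORT = 0.05


@dataclass
class TreeSample:
    """Rooted (via outgroup) tree sample with a tip-to-population map."""

    trees: list[dendropy.Tree]
    pop_map: dict[str, str]
    outgroup_label: str
    source_runs: list[str] = field(default_factory=list)
    _clade_cache: list[set[frozenset]] | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("tree sample is empty")
        tipsets = {frozenset(l.taxon.label for l in t.leaf_node_iter())
                   for t in self.trees}
        if len(tipsets) != 1:
            raise ValueError("all trees must share an identical tip set")
        (self.tip_set,) = tipsets
        if self.outgroup_label not in self.tip_set:
            raise ValueError("outgroup missing from the trees")

    @property
    def ingroup(self) -> frozenset:
        return frozenset(self.tip_set - {self.outgroup_label})

    def tips_for(self, population: str) -> frozenset:
        tips = frozenset(t for t, p in self.pop_map.items()
                         if p == population and t in self.tip_set)
        if not tips:
            raise ValueError(f"no tips mapped to population {population!r}")
        return tips

    def clade_sets(self) -> list[set[frozenset]]:
        if self._clade_cache is None:
            self._clade_cache = [
                rooted_clades(t, self.outgroup_label) for t in self.trees]
        return self._clade_cache


@dataclass(frozen=True)
class MonophylyReport:
    groups: tuple[str, ...]
    posterior_probability: float
    classification: str
    n_trees: int


def classify_support(p: float) -> str:
    if p > MONOPHYLY_SUPPORT:
        return "monophyly_supported"
    if p < PARAPHYLY_SUPPORT:
        return "paraphyly_supported"
    return "ambiguous"


# ---------------------------------------------------------------------------
# clade extraction
# ---------------------------------------------------------------------------

def rooted_clades(tree: dendropy.Tree, outgroup_label: str) -> set[frozenset]:
    """Non-trivial clades of the tree rooted on the outgroup's pendant edge.

    Each edge bipartition contributes the side not containing the
    outgroup; works identically for rooted and unrooted input.
    """
    leafsets: dict = {}
    all_tips: frozenset = frozenset()
    clades: set[frozenset] = set()
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            leafsets[nd] = frozenset([nd.taxon.label])
        else:
            leafsets[nd] = frozenset().union(
                *(leafsets[c] for c in nd.child_nodes()))
    all_tips = leafsets[tree.seed_node]
    if outgroup_label not in all_tips:
        raise ValueError("outgroup tip absent from tree")
    for nd, s in leafsets.items():
        if nd is tree.seed_node:
            continue
        clade = (all_tips - s) if outgroup_label in s else s
        clade = clade - {outgroup_label}
        if len(clade) >= 2:
            clades.add(clade)
    return clades


def is_monophyletic(tree: dendropy.Tree, group: Iterable[str],
                    outgroup_label: str) -> bool:
    """True iff exactly the group's tips form a clade of the rooted tree.

    A polytomy containing extra tips does not count; single-tip groups are
    trivially monophyletic.
    """
    group = frozenset(group)
    if not group:
        raise ValueError("group must be non-empty")
    tips = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = group - tips
    if missing:
        raise ValueError(f"tips absent from tree: {sorted(missing)}")
    if len(group) == 1:
        return True
    return group in rooted_clades(tree, outgroup_label)


def _resolve_group(sample: TreeSample, group) -> tuple[str, frozenset]:
    if isinstance(group, str):
        return group, sample.tips_for(group)
    tips = frozenset(group)
    missing = tips - sample.tip_set
    if missing:
        raise ValueError(f"tips absent from sample: {sorted(missing)}")
    return ",".join(sorted(tips)), tips


def posterior_monophyly(sample: TreeSample, group) -> MonophylyReport:
    """Posterior probability that a population (name or explicit tip set)
    is monophyletic across the tree sample."""
    name, tips = _resolve_group(sample, group)
    if len(tips) == 1:
        p = 1.0
    else:
        hits = sum(1 for cl in sample.clade_sets() if tips in cl)
        p = hits / len(sample.trees)
    return MonophylyReport((name,), p, classify_support(p),
                           len(sample.trees))


def reciprocal_monophyly(sample: TreeSample, group_a,
                         group_b) -> MonophylyReport:
    """Posterior probability that both groups are simultaneously
    monophyletic; groups must be disjoint."""
    name_a, tips_a = _resolve_group(sample, group_a)
    name_b, tips_b = _resolve_group(sample, group_b)
    if tips_a & tips_b:
        raise ValueError("groups overlap")
    hits = 0
    for cl in sample.clade_sets():
        ok_a = len(tips_a) == 1 or tips_a in cl
        ok_b = len(tips_b) == 1 or tips_b in cl
        hits += ok_a and ok_b
    p = hits / len(sample.trees)
    return MonophylyReport((name_a, name_b), p, classify_support(p),
                           len(sample.trees))


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def clade_frequencies(sample: TreeSample) -> dict[frozenset, float]:
    """Frequency of every non-trivial rooted clade across the sample."""
    counts: Counter = Counter()
    for cl in sample.clade_sets():
        counts.update(cl)
    n = len(sample.trees)
    return {c: k / n for c, k in counts.items()}


def majority_consensus(sample: TreeSample) -> dendropy.Tree:
    """Strict-majority (>50%) consensus of the rooted sample, with clade
    supports stored on node labels and ``.support`` attributes."""
    freqs = clade_frequencies(sample)
    ingroup = sample.ingroup
    majority = sorted((c for c, f in freqs.items() if f > 0.5),
                      key=len, reverse=True)
    if ingroup not in majority:
        majority.insert(0, ingroup)  # full ingroup clade: rooting guarantee

    tns = dendropy.TaxonNamespace(sorted(sample.tip_set))
    tree = dendropy.Tree(taxon_namespace=tns)
    node_for: dict[frozenset, dendropy.Node] = {}
    for clade in majority:
        nd = dendropy.Node()
        support = freqs.get(clade, 1.0)
        nd.support = support
        nd.label = f"{support:.3f}"
        parent = None
        best = None
        for other, other_nd in node_for.items():
            if clade < other and (best is None or len(other) < len(best)):
                best, parent = other, other_nd
        (parent or tree.seed_node).add_child(nd)
        node_for[clade] = nd
    for tip in sorted(sample.tip_set):
        leaf = dendropy.Node(taxon=tns.get_taxon(tip))
        if tip == sample.outgroup_label:
            tree.seed_node.add_child(leaf)
            continue
        best = None
        parent = tree.seed_node
        for clade, nd in node_for.items():
            if tip in clade and (best is None or len(clade) < len(best)):
                best, parent = clade, nd
        parent.add_child(leaf)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def load_tree_sample(paths: Sequence, pop_map: dict[str, str],
                     outgroup_label: str, burnin: float = 0.10,
                     schema: str = "newick") -> TreeSample:
    """Load one or more posterior runs, discard the leading burn-in
    fraction of each run, and pool the rest."""
    if not (0 <= burnin < 1):
        raise ValueError("burnin must be in [0, 1)")
    tns = dendropy.TaxonNamespace()
    pooled: list[dendropy.Tree] = []
    runs: list[str] = []
    for path in paths:
        kw = {"preserve_underscores": True} if schema == "newick" else {}
        tl = dendropy.TreeList.get(path=str(path), schema=schema,
                                   taxon_namespace=tns, **kw)
        drop = int(len(tl) * burnin)
        pooled.extend(tl[drop:])
        runs.append(str(path))
    return TreeSample(trees=pooled, pop_map=dict(pop_map),
                      outgroup_label=outgroup_label, source_runs=runs)


def read_popmap(path) -> dict[str, str]:
    """Two-column TSV: sample <TAB> population."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tip, pop = line.split("\t")[:2]
            out[tip] = pop
    return out
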