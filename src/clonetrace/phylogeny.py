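"""Trunk/branch subclonal phylogeny from multi-sector presence matrices.

The reconstruction follows the classical perfect-phylogeny reading of a
multi-sector variant table: variants are sorted by the number of samples
they affect (descending), variants present in every sample form the
trunk, and branching points are added recursively so that samples
sharing a variant set hang below one edge carrying that set, until every
sample sits on its own leaf edge carrying its private variants.

Presence patterns that overlap without nesting cannot be realised on a
tree; such conflicting variants are attached greedily to the edge whose
leaf set is the largest subset of their carriers, and each assignment is
recorded in a conflict report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats

from .signature import fisher_exact
from .variant_io import VariantMatrix

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    """A node of the clone tree; ``variants`` sit on the edge entering it."""

    samples: frozenset[str]
    variants: list[str] = field(default_factory=list)
    children: list["TreeNode"] = field(default_factory=list)
    name: Optional[str] = None  # leaf sample id

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Conflict:
    variant: str
    carriers: frozenset[str]
    assigned_to: frozenset[str]


@dataclass
class PhyloTree:
    root: TreeNode
    conflicts: list[Conflict] = field(default_factory=list)

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def edge_variant_sets(self) -> dict[frozenset[str], list[str]]:
        return {n.samples: list(n.variants) for n in self.iter_nodes() if n.variants}

    def clades(self) -> set[frozenset[str]]:
        return {n.samples for n in self.iter_nodes()}

    def conflict_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.variant, ";".join(sorted(c.carriers)), ";".join(sorted(c.assigned_to)))
             for c in self.conflicts],
            columns=["variant", "carriers", "assigned_to"],
        )


@dataclass
class CloneExclusivityResult:
    vaf_sum: float
    tolerance: float
    exclusive: bool
    ratio: Optional[float]


def build_tree(matrix: VariantMatrix) -> PhyloTree:
    """Reconstruct the trunk/branch tree from a presence matrix.

    Deterministic: carrier sets are processed largest-first with
    lexicographic tie-breaking on variant keys, and children are ordered
    by sample label so samples from the same sector group together
    (cosmetic only -- topology is unaffected).
    """
    samples = frozenset(matrix.samples)
    if not samples or not matrix.variants:
        raise ValueError("matrix must contain at least one variant and one sample")

    groups: dict[frozenset[str], list[str]] = {}
    for vk in matrix.variants:
        carriers = matrix.carriers(vk)
        if not carriers:
            warnings.warn(f"variant {vk} present in no sample at threshold "
                          f"{matrix.presence_threshold}; left off the tree")
            continue
        groups.setdefault(carriers, []).append(vk)
    for vs in groups.values():
        vs.sort()

    # largest carrier sets first; ties broken by the sorted sample tuple
    ordered = sorted(groups, key=lambda s: (-len(s), tuple(sorted(s))))

    root = TreeNode(samples=samples, variants=list(groups.get(samples, [])))
    deferred: list[tuple[str, frozenset[str]]] = []

    for carrier_set in ordered:
        if carrier_set == samples:
            continue  # trunk, already placed
        node = root
        while True:
            nxt = next((c for c in node.children if carrier_set <= c.samples), None)
            if nxt is None:
                break
            node = nxt
        overlapping = [c for c in node.children
                       if c.samples & carrier_set and not c.samples <= carrier_set]
        if overlapping:
            for vk in groups[carrier_set]:
                deferred.append((vk, carrier_set))
            continue
        new = TreeNode(samples=carrier_set, variants=list(groups[carrier_set]))
        keep, move = [], []
        for c in node.children:
            (move if c.samples <= carrier_set else keep).append(c)
        new.children = move
        node.children = keep + [new]

    # terminate every sample on its own leaf edge
    for sid in sorted(samples):
        node = root
        while True:
            nxt = next((c for c in node.children if sid in c.samples), None)
            if nxt is None:
                break
            node = nxt
        if node.samples == frozenset({sid}):
            node.name = sid
        else:
            node.children.append(TreeNode(samples=frozenset({sid}), name=sid))

    tree = PhyloTree(root=root)

    # greedy placement of conflicting variants on the maximal compatible edge
    if deferred:
        nodes = list(tree.iter_nodes())
        for vk, carrier_set in deferred:
            candidates = [n for n in nodes if n.samples <= carrier_set]
            best = max(candidates, key=lambda n: (len(n.samples), tuple(sorted(n.samples))))
            best.variants.append(vk)
            tree.conflicts.append(Conflict(vk, carrier_set, best.samples))
            logger.warning("conflicting presence pattern for %s (carriers %s); "
                           "attached to edge %s", vk, sorted(carrier_set),
                           sorted(best.samples))

    _sort_children(root)
    return tree


def _sort_children(node: TreeNode) -> None:
    node.children.sort(key=lambda c: min(c.samples))
    for c in node.children:
        _sort_children(c)


def tree_to_newick(tree: PhyloTree) -> str:
    """Serialize as Newick; branch lengths carry the variant count per edge.

    Sample names have spaces replaced by underscores so the output parses
    with standard Newick readers.
    """
    def render(node: TreeNode) -> str:
        if node.is_leaf:
            label = (node.name or "").replace(" ", "_")
            return f"{label}:{len(node.variants)}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{len(node.variants)}"

    if tree.root.is_leaf:  # degenerate single-sample tree
        return f"({render(tree.root)});"
    return render(tree.root) + ";"


def reciprocal_vaf_test(vaf_a: float, vaf_b: float, tolerance: float = 0.02) -> CloneExclusivityResult:
    """Test whether two variants behave as mutually exclusive clones.

    Two heterozygous mutations occupying complementary clonal populations
    have cellular-prevalence VAFs summing to 1; the test flags the pair
    exclusive when |vaf_a + vaf_b - 1| <= tolerance.
    """
    for v in (vaf_a, vaf_b):
        if not 0.0 <= v <= 1.0:
            raise ValueError("VAFs must lie in [0, 1]")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    s = float(vaf_a + vaf_b)
    return CloneExclusivityResult(
        vaf_sum=s,
        tolerance=tolerance,
        exclusive=bool(abs(s - 1.0) <= tolerance),
        ratio=float(vaf_a / vaf_b) if vaf_b > 0 else None,
    )


def clone_ratio_summary(
    matrix: VariantMatrix,
    variant_a: str,
    variant_b: str,
    group_by: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group ratio of mean VAFs of two clone-marking variants.

    Returns one row per group with mean VAFs, the ratio a/b and a rounded
    integer label "k:1".  A group in which a variant was never observed
    gets NaN, not zero.
    """
    for vk in (variant_a, variant_b):
        if vk not in matrix.vaf.index:
            raise KeyError(f"variant {vk} not in matrix")
    rows = []
    groups = sorted(set(group_by.values()))
    for g in groups:
        members = [s for s in matrix.samples if group_by.get(s) == g]
        va = matrix.vaf.loc[variant_a, members].dropna()
        vb = matrix.vaf.loc[variant_b, members].dropna()
        mean_a = va.mean() if len(va) else np.nan
        mean_b = vb.mean() if len(vb) else np.nan
        ratio = mean_a / mean_b if mean_b and not np.isnan(mean_a) and not np.isnan(mean_b) else np.nan
        label = f"{round(ratio)}:1" if np.isfinite(ratio) else ""
        rows.append((g, mean_a, mean_b, ratio, label))
    return pd.DataFrame(rows, columns=["group", "mean_vaf_a", "mean_vaf_b",
                                       "ratio", "ratio_label"]).set_index("group")


def select_discriminating_snvs(
    presence_counts_group_a: Mapping[str, tuple[int, int]],
    presence_counts_group_b: Mapping[str, tuple[int, int]],
    alpha: float = 0.02,
) -> set[str]:
    """Variants whose carrier counts differ between two sample groups.

    Counts are (carriers, non-carriers) per variant per group.  A variant
    is selected when the two-sided Fisher exact p (hypergeometric
    definition, :func:`clonetrace.signature.fisher_exact`) is < alpha.
    """
    selected = set()
    for vk, (a, b) in presence_counts_group_a.items():
        if vk not in presence_counts_group_b:
            continue
        c, d = presence_counts_group_b[vk]
        if a + b == 0 or c + d == 0:
            raise ValueError(f"variant {vk}: empty group")
        # alpha >= 1 means "no filtering" (p is never strictly below 1 for
        # a maximally balanced table, but every variant must then pass)
        if alpha >= 1 or fisher_exact(a, b, c, d) < alpha:
            selected.add(vk)
    return selected


def presence_counts(matrix: VariantMatrix, sample_ids: Sequence[str]) -> dict[str, tuple[int, int]]:
    """(carriers, non-carriers) per variant within a sample group."""
    sub = matrix.present[list(sample_ids)]
    return {vk: (int(sub.loc[vk].sum()), len(sample_ids) - int(sub.loc[vk].sum()))
            for vk in matrix.variants}


def hierarchical_cluster(
    presence: pd.DataFrame,
    linkage: str = "average",
    n_clusters: int = 2,
) -> tuple[np.ndarray, pd.Series]:
    """Cluster samples on Jaccard distance between presence vectors.

    ``presence`` is variants x samples boolean.  Returns the scipy linkage
    matrix and a flat cluster labelling cut at ``n_clusters``.  With
    all-identical samples a single cluster is returned with a warning.
    """
    if presence.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    x = presence.T.to_numpy(dtype=bool)
    dist = pdist(x, metric="jaccard")
    dist = np.nan_to_num(dist, nan=0.0)  # two all-false vectors are identical
    if np.all(dist == 0):
        warnings.warn("all samples identical on the selected variants; single cluster")
        z = hierarchy.linkage(dist, method=linkage)
        labels = pd.Series(1, index=presence.columns, name="cluster")
        return z, labels
    z = hierarchy.linkage(dist, method=linkage)
    flat = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return z, pd.Series(flat, index=presence.columns, name="cluster")


def colony_genotype_expectation(
    clone_fractions: Mapping[str, float],
    n_colonies: int,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Expected single-cell colony counts per genotype with exact binomial intervals.

    Given the clonal composition of a culture, plating ``n_colonies``
    single cells yields Binomial(n, fraction) colonies per genotype; the
    table reports the expectation and the central exact interval.
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    total = 0.0
    for g, f in clone_fractions.items():
        if f < 0:
            raise ValueError(f"negative fraction for genotype {g!r}")
        total += f
    if total > 1 + 1e-9:
        raise ValueError("clone fractions must sum to <= 1")
    rows = []
    for g, f in clone_fractions.items():
        lo, hi = stats.binom.interval(confidence, n_colonies, f)
        rows.append((g, f, f * n_colonies, int(lo), int(hi)))
    return pd.DataFrame(rows, columns=["genotype", "fraction", "expected_count",
                                       "ci_low", "ci_high"]).set_index("genotype")
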