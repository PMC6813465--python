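"""Accuracy metrics: per-taxon deviation, Pearson r, weighted UniFrac, ANOVA.

Observed taxon profiles are scored against the theoretical expectation
the mock recipe implies.  Per-taxon percentage deviation mirrors the
"Deviation (SD)" presentation: 100 * (obs - theor) / theor where both
sides are positive, flagged ND (expected, not detected) or D (detected,
not expected) otherwise.  Community-level accuracy uses Pearson
correlation over the union of taxa (absent taxa as 0) and raw weighted
UniFrac over a UPGMA tree built from alignment distances between taxon
representative sequences.  Across-mock differences are tested with
one-way ANOVA plus Tukey HSD grouping letters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skbio import TreeNode

from .mock_design import CompositionProfile
from .taxonomy import AnnotationParams, DEFAULT_PARAMS, pairwise_identity

__all__ = [
    "UNASSIGNED",
    "DeviationEntry",
    "AccuracyReport",
    "percentage_deviation",
    "pearson_accuracy",
    "build_taxon_tree",
    "weighted_unifrac",
    "compare_groups",
    "GroupComparison",
]

#: Profile key holding undetermined read mass; excluded from all metrics.
UNASSIGNED = "Unassigned"


@dataclass(frozen=True)
class DeviationEntry:
    taxon: str
    theoretical: float
    observed: float
    deviation: float | None  # percent; None when flagged
    flag: str | None  # None | "ND" | "D"


def _metric_keys(profile: CompositionProfile) -> dict[str, float]:
    return {k: v for k, v in profile.abundances.items() if k != UNASSIGNED}


def percentage_deviation(
    observed: CompositionProfile, theoretical: CompositionProfile
) -> dict[str, DeviationEntry]:
    """Per-taxon percentage deviation of observed from theoretical.

    Covers the union of taxa.  deviation = 100 * (obs - theor) / theor
    when both are positive; ND when expected but absent, D when present
    but unexpected.
    """
    obs = _metric_keys(observed)
    theor = _metric_keys(theoretical)
    out: dict[str, DeviationEntry] = {}
    for taxon in sorted(set(obs) | set(theor)):
        o = obs.get(taxon, 0.0)
        t = theor.get(taxon, 0.0)
        if t > 0 and o > 0:
            out[taxon] = DeviationEntry(taxon, t, o, 100.0 * (o - t) / t, None)
        elif t > 0:
            out[taxon] = DeviationEntry(taxon, t, o, None, "ND")
        elif o > 0:
            out[taxon] = DeviationEntry(taxon, t, o, None, "D")
        else:
            out[taxon] = DeviationEntry(taxon, t, o, 0.0, None)
    return out


def pearson_accuracy(
    observed: CompositionProfile, theoretical: CompositionProfile
) -> float | None:
    """Pearson r between profiles over the union of taxa (absent = 0).

    Returns None when undefined: fewer than 3 taxa in the union, or zero
    variance in either vector.
    """
    obs = _metric_keys(observed)
    theor = _metric_keys(theoretical)
    taxa = sorted(set(obs) | set(theor))
    if len(taxa) < 3:
        return None
    x = np.array([theor.get(t, 0.0) for t in taxa])
    y = np.array([obs.get(t, 0.0) for t in taxa])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# UPGMA tree + weighted UniFrac


def build_taxon_tree(
    representatives: dict[str, str],
    params: AnnotationParams = DEFAULT_PARAMS,
) -> TreeNode:
    """UPGMA tree over taxa from pairwise alignment distances.

    Distance between two taxa is 1 - identity/100 of their representative
    sequences under global alignment.  The result is ultrametric with
    leaf names equal to taxon names; merge ties break lexicographically
    on cluster names (the smallest member name) so tree construction is
    deterministic.
    """
    names = sorted(representatives)
    if len(names) != len(set(names)):
        raise ValueError("duplicate taxa")
    if len(names) < 2:
        raise ValueError("need at least 2 taxa")
    dist: dict[frozenset[str], float] = {}
    for a, b in itertools.combinations(names, 2):
        d = 1.0 - pairwise_identity(representatives[a], representatives[b], params) / 100.0
        dist[frozenset((a, b))] = d

    # cluster state: name -> (size, height, node); cluster name = min member
    clusters: dict[str, tuple[int, float, TreeNode]] = {
        n: (1, 0.0, TreeNode(name=n)) for n in names
    }
    cdist = {frozenset(p): d for p, d in dist.items()}
    while len(clusters) > 1:
        pair = min(
            itertools.combinations(sorted(clusters), 2),
            key=lambda p: (cdist[frozenset(p)], p),
        )
        a, b = sorted(pair)
        d = cdist[frozenset(pair)]
        size_a, h_a, node_a = clusters[a]
        size_b, h_b, node_b = clusters[b]
        height = d / 2.0
        node_a.length = height - h_a
        node_b.length = height - h_b
        merged = TreeNode(children=[node_a, node_b])
        for other in clusters:
            if other in (a, b):
                continue
            da = cdist[frozenset((a, other))]
            db = cdist[frozenset((b, other))]
            cdist[frozenset((a, other))] = (size_a * da + size_b * db) / (
                size_a + size_b
            )
        del clusters[b]
        clusters[a] = (size_a + size_b, height, merged)
    (root,) = (c[2] for c in clusters.values())
    root.length = None
    return root


def weighted_unifrac(
    profile_a: CompositionProfile,
    profile_b: CompositionProfile,
    tree: TreeNode,
    normalized: bool = False,
) -> float:
    """Raw weighted UniFrac distance between two profiles on a shared tree.

    Sum over branches of branch length times |A_b - B_b|, where A_b is
    the profile-A abundance fraction descending from the branch.  The
    normalized variant divides by the same sum with |.| replaced by
    (A_b + B_b).  Taxa with nonzero abundance must be tree leaves.
    """
    leaves = {leaf.name for leaf in tree.tips()}
    masses = []
    for profile in (profile_a, profile_b):
        mass = _metric_keys(profile)
        missing = {t for t, v in mass.items() if v > 0} - leaves
        if missing:
            raise ValueError(f"taxa missing from tree: {sorted(missing)}")
        masses.append(mass)
    a_mass, b_mass = masses

    distance = 0.0
    denominator = 0.0
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._wu = (a_mass.get(node.name, 0.0), b_mass.get(node.name, 0.0))
        else:
            node._wu = tuple(
                sum(child._wu[i] for child in node.children) for i in (0, 1)
            )
        length = node.length or 0.0
        distance += length * abs(node._wu[0] - node._wu[1])
        denominator += length * (node._wu[0] + node._wu[1])
    for node in tree.postorder(include_self=False):
        del node._wu
    if normalized:
        return distance / denominator if denominator > 0 else 0.0
    return distance


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class GroupComparison:
    f_statistic: float
    p_value: float
    letters: dict[str, str]  # group -> Tukey HSD grouping letters


def compare_groups(values: dict[str, list[float]], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA plus Tukey HSD grouping letters across mocks.

    Groups sharing a letter do not differ significantly at ``alpha``.
    Degenerate input (all values identical) yields F = 0, p = 1 and a
    single shared letter.
    """
    names = sorted(values)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for name in names:
        if len(values[name]) < 2:
            raise ValueError(f"group {name!r} needs >= 2 replicates")
    flat = [v for name in names for v in values[name]]
    if len(set(flat)) == 1:
        return GroupComparison(0.0, 1.0, {n: "a" for n in names})

    f_stat, p = stats.f_oneway(*(values[n] for n in names))

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = np.array(flat, dtype=float)
    groups = np.array([n for n in names for _ in values[n]])
    tukey = pairwise_tukeyhsd(data, groups, alpha=alpha)
    # non-significance graph -> maximal cliques -> letters
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(names)
    for (g1, g2), reject in zip(
        itertools.combinations(tukey.groupsunique, 2), tukey.reject
    ):
        if not reject:
            graph.add_edge(str(g1), str(g2))
    cliques = sorted(nx.find_cliques(graph), key=lambda c: sorted(c))
    letters: dict[str, str] = {n: "" for n in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for member in clique:
            letters[member] += letter
    letters = {n: "".join(sorted(l)) for n, l in letters.items()}
    return GroupComparison(float(f_stat), float(p), letters)


@dataclass
class AccuracyReport:
    """Full accuracy report for one mock: per-taxon deviation statistics
    over replicates plus per-replicate Pearson r and weighted UniFrac."""

    mock_name: str
    deviations: dict[str, list[DeviationEntry]]  # taxon -> per-replicate entries
    pearson_r: dict[str, float | None]  # replicate -> r
    unifrac: dict[str, float]  # replicate -> distance

    def deviation_summary(self) -> dict[str, tuple[float | str, float]]:
        """Per taxon: (mean deviation or flag, SD over replicates).

        A taxon flagged in every replicate reports the flag; otherwise the
        mean/SD run over the replicates where the deviation is defined.
        """
        out: dict[str, tuple[float | str, float]] = {}
        for taxon, entries in self.deviations.items():
            vals = [e.deviation for e in entries if e.deviation is not None]
            if vals:
                out[taxon] = (float(np.mean(vals)), float(np.std(vals, ddof=0)))
            else:
                flags = {e.flag for e in entries if e.flag}
                out[taxon] = ("/".join(sorted(flags)) or "ND", 0.0)
        return out
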