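"""Cross-site community structure: shared OTUs, partitions and beta diversity.

Valid NrfA proteins from all sites are clustered greedily at >90% identity
(most abundant sequence founds each cluster, CD-HIT style) into a single
OTU-by-site count table.  OTUs are classified per site as dominant (>1% of
the site's valid sequences), low-abundance (0.1-1%] or rare (<=0.1%], and
marked endemic (present at exactly one site) or cosmopolitan (present at
all sites).  Between-site structure is summarised with a neighbour-joining
tree over OTU representatives, weighted normalized UniFrac distances, and
principal coordinates analysis; a heat-map matrix of dominant OTUs is
exported for plotting.
"""

from __future__ import annotations

import itertools
import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from ._alignment import identity
from .read_processing import SiteLibrary

__all__ = [
    "OTUTable",
    "AbundanceClasses",
    "cluster_cross_site",
    "classify_abundance",
    "endemic_and_dominant_percentages",
    "nj_tree",
    "bootstrap_support",
    "weighted_normalized_unifrac",
    "unifrac_matrix",
    "PCoAResult",
    "pcoa",
    "heatmap_matrix",
]


@dataclass
class OTUTable:
    """OTU x site count matrix with representative sequences."""

    counts: pd.DataFrame  # index: otu_id, columns: site_id
    representatives: dict[str, str]  # otu_id -> representative protein

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if set(self.counts.index) != set(self.representatives):
            raise ValueError("representatives must cover exactly the OTU ids")

    @property
    def site_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def relative(self) -> pd.DataFrame:
        """Site-relative fractions."""
        return self.counts / self.site_totals

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "rep_seq", [self.representatives[o] for o in out.index])
        out.to_csv(path, sep="\t", index_label="otu_id")


def cluster_cross_site(
    libraries: dict[str, SiteLibrary], identity_threshold: float = 0.90
) -> OTUTable:
    """Greedy incremental clustering of all sites' proteins at >90% identity.

    Sequences are processed by descending total count (ties: longer first,
    then lexicographic); each joins the first existing cluster whose
    representative it matches at strictly more than ``identity_threshold``
    (alignment identity over columns, terminal gaps excluded), otherwise it
    founds a new cluster.  Per-site counts accumulate into the table.
    """
    if not 0.0 < identity_threshold < 1.0:
        raise ValueError("identity_threshold must be in (0, 1)")
    if not libraries:
        raise ValueError("no site libraries given")
    sites = list(libraries)
    per_seq: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for site, lib in libraries.items():
        for protein, count, _ in lib.proteins:
            per_seq[protein][site] += count
    ordered = sorted(
        per_seq, key=lambda s: (-sum(per_seq[s].values()), -len(s), s)
    )
    reps: list[str] = []
    cluster_counts: list[defaultdict] = []
    for seq in ordered:
        joined = False
        for k, rep in enumerate(reps):
            if identity(seq, rep) > identity_threshold:
                for site, c in per_seq[seq].items():
                    cluster_counts[k][site] += c
                joined = True
                break
        if not joined:
            reps.append(seq)
            counts = defaultdict(int)
            for site, c in per_seq[seq].items():
                counts[site] += c
            cluster_counts.append(counts)
    otu_ids = [f"OTU{k + 1}" for k in range(len(reps))]
    frame = pd.DataFrame(
        [[cluster_counts[k].get(site, 0) for site in sites] for k in range(len(reps))],
        index=otu_ids,
        columns=sites,
    )
    return OTUTable(counts=frame, representatives=dict(zip(otu_ids, reps)))


@dataclass
class AbundanceClasses:
    """Per-(OTU, site) abundance class plus endemic/cosmopolitan flags."""

    classes: pd.DataFrame  # strings: dominant | low_abundance | rare | absent
    endemic: set[str]
    cosmopolitan: set[str]

    def dominant_anywhere(self) -> list[str]:
        mask = (self.classes == "dominant").any(axis=1)
        return list(self.classes.index[mask])


def classify_abundance(
    table: OTUTable,
    dominant_threshold: float = 0.01,
    rare_threshold: float = 0.001,
) -> AbundanceClasses:
    """Apply the dominant / low-abundance / rare partition per site.

    dominant: site fraction strictly > 1%; rare: 0 < fraction <= 0.1%;
    low_abundance: in between (0.1% < f <= 1%); absent: zero count.
    An OTU exactly at 1% is low-abundance, not dominant.
    """
    totals = table.site_totals
    if (totals <= 0).any():
        raise ValueError("all site totals must be > 0")
    frac = table.relative()
    classes = pd.DataFrame("absent", index=frac.index, columns=frac.columns)
    classes[(frac > 0) & (frac <= rare_threshold)] = "rare"
    classes[(frac > rare_threshold) & (frac <= dominant_threshold)] = "low_abundance"
    classes[frac > dominant_threshold] = "dominant"
    present = (table.counts > 0).sum(axis=1)
    endemic = set(table.counts.index[present == 1])
    cosmopolitan = set(table.counts.index[present == len(frac.columns)])
    return AbundanceClasses(classes=classes, endemic=endemic, cosmopolitan=cosmopolitan)


def endemic_and_dominant_percentages(
    table: OTUTable, classes: AbundanceClasses
) -> pd.DataFrame:
    """Per-site percent of sequences in dominant OTUs and in endemic OTUs.

    Denominator is the site's valid-sequence total; reported to one decimal.
    """
    totals = table.site_totals
    rows = {}
    for site in table.counts.columns:
        dominant = classes.classes[site] == "dominant"
        pct_dom = 100.0 * table.counts.loc[dominant, site].sum() / totals[site]
        endem = table.counts.index.isin(classes.endemic)
        pct_end = 100.0 * table.counts.loc[endem, site].sum() / totals[site]
        rows[site] = {"pct_dominant": round(pct_dom, 1), "pct_endemic": round(pct_end, 1)}
    return pd.DataFrame(rows).T.rename_axis("site_id")


def nj_tree(dm: DistanceMatrix, midpoint_root: bool = True) -> TreeNode:
    """Saitou-Nei neighbour joining.

    Negative branch lengths are clamped to zero with the deficit moved onto
    the sister branch (their sum stays equal to the joined distance).  The
    tree is midpoint-rooted by default, as UniFrac needs a root.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbour joining needs >= 3 labels")
    d = dm.data.astype(float).copy()
    nodes = [TreeNode(name=lbl) for lbl in labels]
    n = len(nodes)
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = dij / 2.0 + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj -= li
            li = 0.0
        if lj < 0:
            li -= lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        new_d = 0.5 * (d[i, active] + d[j, active] - dij)
        d[i, active] = new_d
        d[active, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)
    a, b = active
    final = max(d[a, b], 0.0)
    nodes[a].length = final / 2.0
    nodes[b].length = final / 2.0
    tree = TreeNode(children=[nodes[a], nodes[b]])
    if midpoint_root:
        tree = tree.root_at_midpoint()
    return tree


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial leaf bipartitions, canonicalized by the smaller side."""
    all_tips = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            other = all_tips - side
            parts.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return parts


def _pdist_from_columns(cols: np.ndarray, labels: list[str]) -> DistanceMatrix:
    n = cols.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(cols[i] != cols[j])
    return DistanceMatrix(d, labels)


def bootstrap_support(
    sequences: dict[str, str],
    n_reps: int = 1000,
    threshold: float = 50.0,
    seed: int = 0,
) -> dict[frozenset, float]:
    """Column-resampling bootstrap of the NJ topology.

    ``sequences`` must be aligned (equal length).  Returns percent support
    per non-trivial bipartition of the full-data tree; bipartitions below
    ``threshold`` map to None (reported unlabeled).
    """
    labels = sorted(sequences)
    if len(labels) < 4:
        raise ValueError("bootstrap needs >= 4 sequences")
    lengths = {len(sequences[lbl]) for lbl in labels}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    cols = np.array([list(sequences[lbl]) for lbl in labels])
    n_cols = cols.shape[1]
    base_tree = nj_tree(_pdist_from_columns(cols, labels), midpoint_root=False)
    base_parts = _bipartitions(base_tree)
    hits = {part: 0 for part in base_parts}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        take = rng.integers(0, n_cols, size=n_cols)
        rep_tree = nj_tree(_pdist_from_columns(cols[:, take], labels), midpoint_root=False)
        rep_parts = _bipartitions(rep_tree)
        for part in base_parts:
            if part in rep_parts:
                hits[part] += 1
    return {
        part: (100.0 * k / n_reps if 100.0 * k / n_reps >= threshold else None)
        for part, k in hits.items()
    }


def weighted_normalized_unifrac(
    tree: TreeNode, counts_a: dict[str, float], counts_b: dict[str, float]
) -> float:
    """Weighted normalized UniFrac distance in [0, 1].

    u = sum over branches of  b_i * |A_i/A_T - B_i/B_T|, where A_i is the
    count subtended by branch i, normalized by D = sum over leaves of
    d_j * (A_j/A_T + B_j/B_T) with d_j the root-to-leaf distance.
    """
    leaves = [t.name for t in tree.tips()]
    total_a = sum(counts_a.get(l, 0.0) for l in leaves)
    total_b = sum(counts_b.get(l, 0.0) for l in leaves)
    if total_a <= 0 or total_b <= 0:
        raise ValueError("each community needs at least one positive count")
    rel_a: dict[int, float] = {}
    rel_b: dict[int, float] = {}
    u = 0.0
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            a = counts_a.get(node.name, 0.0) / total_a
            b = counts_b.get(node.name, 0.0) / total_b
        else:
            a = sum(rel_a[id(c)] for c in node.children)
            b = sum(rel_b[id(c)] for c in node.children)
        rel_a[id(node)], rel_b[id(node)] = a, b
        if node.parent is not None and node.length is not None:
            u += node.length * abs(a - b)
    denom = 0.0
    for tip in tree.tips():
        depth = tip.accumulate_to_ancestor(tree)
        a = counts_a.get(tip.name, 0.0) / total_a
        b = counts_b.get(tip.name, 0.0) / total_b
        denom += depth * (a + b)
    if denom == 0:
        return 0.0
    return u / denom


def unifrac_matrix(tree: TreeNode, table: OTUTable) -> DistanceMatrix:
    """All-pairs weighted normalized UniFrac over the table's sites."""
    sites = list(table.counts.columns)
    d = np.zeros((len(sites), len(sites)))
    for i, j in itertools.combinations(range(len(sites)), 2):
        d[i, j] = d[j, i] = weighted_normalized_unifrac(
            tree,
            table.counts[sites[i]].to_dict(),
            table.counts[sites[j]].to_dict(),
        )
    return DistanceMatrix(d, sites)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # sites x axes
    percent_variance: np.ndarray  # per retained (positive) axis
    eigenvalues: np.ndarray  # all eigenvalues, descending

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "%variance\t"
                + "\t".join(f"{v:.2f}" for v in self.percent_variance)
                + "\n"
            )
            self.coordinates.to_csv(fh, sep="\t", index_label="site_id")


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Principal coordinates analysis by Gower double-centering.

    Negative eigenvalues (non-Euclidean input) are dropped from both the
    axes and the percent-variance denominator, and reported in
    ``eigenvalues`` for inspection.
    """
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)
    percent = 100.0 * lam / lam.sum() if lam.size else np.array([])
    frame = pd.DataFrame(
        coords,
        index=list(dm.ids),
        columns=[f"PC{k + 1}" for k in range(coords.shape[1])],
    )
    return PCoAResult(coordinates=frame, percent_variance=percent, eigenvalues=eigvals)


def heatmap_matrix(table: OTUTable, classes: AbundanceClasses) -> pd.DataFrame:
    """Site-relative percent abundance of every OTU dominant in >= 1 site.

    Cells below 1% are retained (an OTU dominant somewhere is shown at every
    site, however small its share there).
    """
    dominant = classes.dominant_anywhere()
    if not dominant:
        warnings.warn("no dominant OTUs; heat-map matrix is empty", stacklevel=2)
        return pd.DataFrame(columns=table.counts.columns)
    return 100.0 * table.relative().loc[dominant]
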