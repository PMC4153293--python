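"""Per-site alpha diversity of NrfA protein fragments.

Distances are p-distances (fraction of differing aligned columns) passed
through Kimura's protein correction d = -ln(1 - p - 0.2 p^2); OTUs are
furthest-neighbour (complete-linkage) clusters at a protein-distance cutoff,
0.1 being the sub-genus working definition calibrated on a labelled
reference pool.  Richness and diversity are summarised with Chao1, ACE,
Shannon entropy (nats) and Pielou's evenness, plus analytic
(hypergeometric) rarefaction.

By default estimators are fed unique-sequence-variant counts per OTU (one
count per distinct dereplicated protein), reducing redundancy the same way
the amplicon literature does; read-weighted counts are available via the
``weights`` argument of :func:`otu_counts`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio import DistanceMatrix

from ._alignment import p_distance
from .synthetic_data import ReferencePool

__all__ = [
    "p_distance",
    "kimura_protein_distance",
    "build_distance_matrix",
    "OTUAssignment",
    "cluster_furthest_neighbor",
    "otu_counts",
    "chao1",
    "ace",
    "shannon",
    "pielou_evenness",
    "rarefaction_curve",
    "DiversityEstimates",
    "diversity_estimates",
    "calibrate_cutoff",
    "write_phylip",
    "read_phylip",
]

#: distance reported when p is beyond the Kimura transform's domain
KIMURA_CAP = 10.0


def kimura_protein_distance(p: float, cap: float = KIMURA_CAP) -> float:
    """Kimura's multiple-hit correction for protein p-distances."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        return cap
    return min(-math.log(arg), cap)


def build_distance_matrix(
    sequences: dict[str, str],
    correction: str = "kimura",
    engine: str = "edlib",
    cap: float = KIMURA_CAP,
) -> DistanceMatrix:
    """Pairwise protein distance matrix (``correction``: "kimura" or "p")."""
    ids = list(sequences)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(sequences[ids[i]], sequences[ids[j]], engine=engine)
            d[i, j] = d[j, i] = (
                kimura_protein_distance(p, cap=cap) if correction == "kimura" else p
            )
    return DistanceMatrix(d, ids)


@dataclass
class OTUAssignment:
    """Partition of sequence ids into OTUs at a distance cutoff."""

    cutoff: float
    clusters: list[list[str]]
    representatives: list[str]

    @property
    def n_otus(self) -> int:
        return len(self.clusters)


def cluster_furthest_neighbor(
    dm: DistanceMatrix, cutoff: float, counts: dict[str, int] | None = None
) -> OTUAssignment:
    """Complete-linkage clustering cut so within-OTU max distance <= cutoff.

    Agglomerative: repeatedly merge the closest pair of clusters under the
    complete-linkage (maximum) distance until the closest pair exceeds the
    cutoff.  Labels are processed in sorted order and the first minimum in
    row-major order is merged, so ties resolve to the lexicographically
    smallest pair.  The representative of each OTU is its highest-count
    member (ties to the lexicographically smallest id).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    order = sorted(dm.ids)
    d = dm.filter(order).data.copy()
    n = len(order)
    members: list[list[str] | None] = [[lbl] for lbl in order]
    work = d.copy()
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    while active.sum() > 1:
        sub = np.where(active[:, None] & active[None, :], work, np.inf)
        flat = int(np.argmin(sub))
        i, j = divmod(flat, n)
        if sub[i, j] > cutoff:
            break
        if i > j:
            i, j = j, i
        members[i] = members[i] + members[j]  # type: ignore[operator]
        members[j] = None
        merged = np.maximum(work[i], work[j])
        work[i, :] = merged
        work[:, i] = merged
        work[i, i] = np.inf
        active[j] = False
    clusters = [sorted(m) for m in members if m is not None]
    clusters.sort(key=lambda c: c[0])
    reps = []
    for cluster in clusters:
        if counts:
            reps.append(sorted(cluster, key=lambda x: (-counts.get(x, 0), x))[0])
        else:
            reps.append(cluster[0])
    # furthest-neighbour guarantee, asserted on every output
    lookup = {lbl: k for k, lbl in enumerate(order)}
    for cluster in clusters:
        idx = [lookup[x] for x in cluster]
        if len(idx) > 1 and d[np.ix_(idx, idx)].max() > cutoff + 1e-12:
            raise AssertionError("within-cluster distance exceeds cutoff")
    return OTUAssignment(cutoff=cutoff, clusters=clusters, representatives=reps)


def otu_counts(
    assignment: OTUAssignment, weights: dict[str, int] | None = None
) -> list[int]:
    """Per-OTU counts: unique-variant counts, or read-weighted if given."""
    if weights is None:
        return [len(c) for c in assignment.clusters]
    return [sum(weights.get(x, 0) for x in c) for c in assignment.clusters]


def _check_counts(counts) -> np.ndarray:
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(arr < 1):
        raise ValueError("counts must be >= 1")
    return arr


def chao1(counts) -> float:
    """Chao1 richness: S + n1^2 / (2 n2); bias-corrected form when n2 = 0."""
    arr = _check_counts(counts)
    s_obs = arr.size
    n1 = int(np.sum(arr == 1))
    n2 = int(np.sum(arr == 2))
    if n2 == 0:
        return s_obs + n1 * (n1 - 1) / 2.0
    return s_obs + n1 * n1 / (2.0 * n2)


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator (falls back to Chao1 when C = 0)."""
    arr = _check_counts(counts)
    rare = arr[arr <= rare_cutoff]
    s_abund = int(np.sum(arr > rare_cutoff))
    s_rare = rare.size
    if s_rare == 0:
        return float(arr.size)
    n_rare = rare.sum()
    f1 = int(np.sum(rare == 1))
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return chao1(counts)
    i = np.arange(1, rare_cutoff + 1)
    fi = np.array([np.sum(rare == k) for k in i])
    gamma2 = max(
        s_rare * float(np.sum(i * (i - 1) * fi)) / (c_ace * n_rare * (n_rare - 1)) - 1.0,
        0.0,
    )
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma2


def shannon(counts) -> float:
    """Shannon entropy H in nats."""
    arr = _check_counts(counts)
    p = arr / arr.sum()
    return float(-np.sum(p * np.log(p)))


def pielou_evenness(h: float, s_obs: int) -> float | None:
    """J = H / ln(S); undefined (None) below two OTUs."""
    if s_obs < 2:
        return None
    return h / math.log(s_obs)


def rarefaction_curve(counts, depths) -> list[float]:
    """Expected OTU count at each subsampling depth (hypergeometric)."""
    arr = _check_counts(counts)
    total = int(arr.sum())

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = []
    for n in depths:
        if n > total:
            raise ValueError(f"depth {n} exceeds total count {total}")
        expected = 0.0
        for ni in arr:
            if total - ni >= n:
                expected += 1.0 - math.exp(log_choose(total - ni, n) - log_choose(total, n))
            else:
                expected += 1.0
        out.append(expected)
    return out


@dataclass(frozen=True)
class DiversityEstimates:
    s_obs: int
    chao1: float
    ace: float
    shannon_h: float
    evenness_j: float | None


def diversity_estimates(counts) -> DiversityEstimates:
    h = shannon(counts)
    s = len(list(counts))
    return DiversityEstimates(
        s_obs=s,
        chao1=chao1(counts),
        ace=ace(counts),
        shannon_h=h,
        evenness_j=pielou_evenness(h, s),
    )


def calibrate_cutoff(pool: ReferencePool, cutoffs) -> pd.DataFrame:
    """Cluster a genus/species-labelled pool over a cutoff grid.

    Returns one row per cutoff with the OTU count next to the pool's genus
    and species counts, flagging the smallest cutoff whose OTU count falls
    between them (the sub-genus working cutoff) and the cutoff whose OTU
    count is closest to the genus count (genus level).
    """
    if not pool.entries:
        raise ValueError("pool is empty")
    if any(not e.genus or not e.species for e in pool.entries):
        raise ValueError("pool must carry genus/species labels")
    sequences = {e.id: e.protein for e in pool.entries}
    n_genera = len({e.genus for e in pool.entries})
    n_species = len({e.species for e in pool.entries})
    dm = build_distance_matrix(sequences)
    rows = []
    for cutoff in cutoffs:
        assignment = cluster_furthest_neighbor(dm, cutoff)
        rows.append(
            {
                "cutoff": cutoff,
                "n_otus": assignment.n_otus,
                "n_genera": n_genera,
                "n_species": n_species,
            }
        )
    table = pd.DataFrame(rows).sort_values("cutoff", ignore_index=True)
    table["sub_genus"] = False
    between = table.index[
        (table.n_otus > table.n_genera) & (table.n_otus <= table.n_species)
    ]
    if len(between):
        table.loc[between[0], "sub_genus"] = True
    table["genus_level"] = False
    table.loc[(table.n_otus - table.n_genera).abs().idxmin(), "genus_level"] = True
    return table


def write_phylip(dm: DistanceMatrix, path: str | Path, lower: bool = False) -> None:
    """PHYLIP distance matrix writer (square, or lower-triangle)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, label in enumerate(dm.ids):
            row = dm.data[i, :i] if lower else dm.data[i]
            fh.write(label.ljust(10) + " ".join(f"{x:.6f}" for x in row) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    lines = Path(path).read_text().strip().splitlines()
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    d = np.zeros((n, n))
    for i, row in enumerate(rows):
        if len(row) == n:  # square
            d[i] = row
        else:  # lower triangle
            d[i, : len(row)] = row
            d[: len(row), i] = row
    return DistanceMatrix(d, labels)
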