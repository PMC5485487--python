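"""Sample clustering: correlation distance, Ward agglomeration, bootstrap
node support, Newick export.

Ward semantics
--------------
The agglomeration applies Lance–Williams updates to *squared* input
dissimilarities (the "squared-input" Ward variant, equivalent to hclust's
``ward.D2`` on the same matrix); merge heights are the square roots of the
updated squared distances.  Ties on the minimal merge cost are broken by
the lexicographically lowest pair of cluster ids, where leaves are numbered
0..n-1 in input order and internal nodes n, n+1, ... in merge order, so the
result is deterministic.

Bootstrap support
-----------------
Node support is the plain bootstrap probability: the percentage of
taxon-resampled profiles whose dendrogram contains the same set of leaves
under some node.  No multiscale-bootstrap correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .community_profile import AbundanceProfile
from .errors import ValidationError


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample ids")
        if np.any(np.abs(self.values - self.values.T) > 1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise ValidationError("distances must be non-negative")


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: nodes ``left`` < ``right`` joined at
    ``height``.  Node ids: leaves 0..n-1, internal nodes n..2n-2."""

    left: int
    right: int
    height: float


@dataclass
class Dendrogram:
    sample_ids: list[str]
    merges: list[Merge]
    support: list[float] | None = None  # BP per internal node, 0..100

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.merges) != n - 1:
            raise ValidationError(f"{n} leaves require {n - 1} merges")
        if self.support is not None and len(self.support) != n - 1:
            raise ValidationError("one support value per internal node required")

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    def leaf_sets(self) -> list[frozenset[str]]:
        """Set of leaf sample ids under each internal node, in merge order."""
        n = self.n_leaves
        sets: dict[int, frozenset[str]] = {
            i: frozenset([s]) for i, s in enumerate(self.sample_ids)
        }
        out = []
        for k, m in enumerate(self.merges):
            sets[n + k] = sets[m.left] | sets[m.right]
            out.append(sets[n + k])
        return out

    def heights(self) -> list[float]:
        return [m.height for m in self.merges]


def correlation_distance(profile: AbundanceProfile) -> DistanceMatrix:
    """Pairwise 1 - Pearson correlation between sample columns (over taxa);
    values lie in [0, 2].  A sample with zero variance across taxa has no
    defined correlation and is reported as an error by name."""
    x = profile.percentages
    if x.shape[1] < 2:
        raise ValidationError("need at least 2 samples to compute distances")
    sd = x.std(axis=0)
    flat = np.where(sd == 0)[0]
    if flat.size:
        raise ValidationError(
            f"sample {profile.sample_ids[flat[0]]!r} has zero variance across taxa"
        )
    r = np.corrcoef(x, rowvar=False)
    d = 1.0 - r
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(profile.sample_ids), d)


def ward_linkage(d: DistanceMatrix) -> Dendrogram:
    """Agglomerate by the minimum-variance criterion via Lance–Williams
    updates on squared distances; deterministic under the lowest-pair
    tie-break."""
    n = len(d.sample_ids)
    if n < 2:
        raise ValidationError("need at least 2 samples to cluster")
    d2 = {
        (i, j): d.values[i, j] ** 2
        for i in range(n)
        for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[Merge] = []
    next_id = n
    while len(active) > 1:
        best = None
        best_cost = np.inf
        for a_pos, i in enumerate(active):
            for j in active[a_pos + 1 :]:
                cost = d2[(i, j)]
                if cost < best_cost:
                    best_cost = cost
                    best = (i, j)
        i, j = best  # lowest (i, j) among minima: scan order guarantees it
        height = float(np.sqrt(max(best_cost, 0.0)))
        merges.append(Merge(i, j, height))
        ni, nj = sizes[i], sizes[j]
        new_d2 = {}
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2[(min(i, k), max(i, k))]
            djk = d2[(min(j, k), max(j, k))]
            dij = d2[(i, j)]
            # Lance-Williams, Ward coefficients, on squared distances
            val = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            new_d2[k] = val
        active = [k for k in active if k not in (i, j)] + [next_id]
        sizes[next_id] = ni + nj
        for k, val in new_d2.items():
            d2[(min(k, next_id), max(k, next_id))] = val
        next_id += 1
    return Dendrogram(list(d.sample_ids), merges)


def bootstrap_support(
    profile: AbundanceProfile, n_boot: int, seed: int
) -> Dendrogram:
    """Attach bootstrap probabilities to the full-data dendrogram.

    Taxa (rows) are resampled with replacement ``n_boot`` times; each
    node's BP is the percentage of bootstrap dendrograms containing the
    same set of leaves.  Replicates where some sample column degenerates to
    zero variance are skipped and excluded from the denominator (rare for
    realistic profiles).
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if len(profile.taxon_labels) < 2:
        raise ValidationError("bootstrap needs at least 2 taxa to resample")
    base = ward_linkage(correlation_distance(profile))
    targets = base.leaf_sets()
    hits = np.zeros(len(targets))
    rng = np.random.default_rng(seed)
    n_taxa = len(profile.taxon_labels)
    used = 0
    for _ in range(n_boot):
        rows = rng.integers(0, n_taxa, size=n_taxa)
        x = profile.percentages[rows, :]
        sd = x.std(axis=0)
        if np.any(sd == 0):
            continue
        r = np.corrcoef(x, rowvar=False)
        dvals = np.clip(1.0 - r, 0.0, 2.0)
        np.fill_diagonal(dvals, 0.0)
        dvals = (dvals + dvals.T) / 2.0
        tree = ward_linkage(DistanceMatrix(list(profile.sample_ids), dvals))
        found = set(tree.leaf_sets())
        for t_idx, target in enumerate(targets):
            if target in found:
                hits[t_idx] += 1
        used += 1
    if used == 0:
        raise ValidationError("all bootstrap replicates were degenerate")
    support = [100.0 * h / used for h in hits]
    return Dendrogram(list(base.sample_ids), list(base.merges), support)


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def to_newick(tree: Dendrogram) -> str:
    """Serialize to Newick: branch lengths are height differences between a
    node and its parent; bootstrap probabilities, when present, appear as
    internal node labels."""
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, m in enumerate(tree.merges):
        node = n + k
        heights[node] = m.height
        children[node] = (m.left, m.right)

    def label(node: int) -> str:
        if node < n:
            name = tree.sample_ids[node]
            if any(c in name for c in " \t()[]:;,'"):
                return "'" + name.replace("'", "''") + "'"
            return name
        if tree.support is not None:
            return _fmt(tree.support[node - n])
        return ""

    def render(node: int, parent_height: float) -> str:
        branch = _fmt(max(parent_height - heights[node], 0.0))
        if node < n:
            return f"{label(node)}:{branch}"
        left, right = children[node]
        inner = ",".join(render(c, heights[node]) for c in (left, right))
        return f"({inner}){label(node)}:{branch}"

    root = n + len(tree.merges) - 1
    left, right = children[root]
    inner = ",".join(render(c, heights[root]) for c in (left, right))
    return f"({inner}){label(root)};"
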