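"""Robinson-Foulds tree space: pairwise distance matrices, classical
multidimensional scaling, hexagonal-bin occupancy, and within/between
marker-group summary statistics.

The embedding is classical (Torgerson) metric MDS: double-center the
squared distances, eigendecompose, keep the top-d positive components.
RF matrices are generally non-Euclidean, so negative eigenvalues can
appear; they are truncated to zero and their total magnitude reported
alongside a Kruskal-type stress.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .splits import leaf_labels, rf_distance, split_set
from .trees_io import TreeSet

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "GroupSummary",
    "pairwise_rf_matrix",
    "group_summary",
    "embed_cmds",
    "hexbin_counts",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix dimension must equal number of ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, row_id in enumerate(self.ids):
                row = "\t".join(f"{x:g}" for x in self.values[i])
                fh.write(f"{row_id}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        lines = Path(path).read_text().splitlines()
        ids = lines[0].split("\t")[1:]
        vals = np.array([[float(x) for x in ln.split("\t")[1:]]
                         for ln in lines[1:]])
        return cls(ids=ids, values=vals)


def pairwise_rf_matrix(ts: TreeSet) -> DistanceMatrix:
    """All-pairs unweighted RF distances; n(n-1)/2 unique computations.

    When every tree spans the same leaf set (the common case for the
    census-ready trees) split sets are computed once per tree.
    """
    trees = ts.trees
    ids = list(ts.analysis_ids)
    n = len(trees)
    d = np.zeros((n, n))
    leafsets = [leaf_labels(t) for t in trees]
    same = all(ls == leafsets[0] for ls in leafsets)
    if same:
        if len(leafsets[0]) < 4:
            raise ValueError("trees must span >= 4 taxa")
        ss = [split_set(t) for t in trees]
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = len(ss[i] ^ ss[j])
    else:
        for i, j in itertools.combinations(range(n), 2):
            try:
                d[i, j] = d[j, i] = rf_distance(trees[i], trees[j])
            except ValueError as exc:
                raise ValueError(
                    f"RF failed for pair ({ids[i]}, {ids[j]}): {exc}") from exc
    return DistanceMatrix(ids=ids, values=d)


@dataclass
class GroupSummary:
    """Within/between marker-group distance statistics.

    ``within_means`` maps each group to its mean pairwise distance (absent
    for groups of size < 2).  ``between_mean`` pools all across-group
    pairs; ``min_between`` is the smallest across-group distance — in the
    study design this is the distance between the most similar nuclear and
    mitochondrial topologies.  ``exceed_counts`` counts pairs *strictly*
    above the cutoff, per comparison type.
    """

    within_means: dict[str, float | None]
    between_mean: float
    min_between: float
    pair_counts: dict[str, int]
    exceed_counts: dict[str, int]
    cutoff: float

    def to_dict(self) -> dict:
        return {
            "within_means": self.within_means,
            "between_mean": self.between_mean,
            "min_between": self.min_between,
            "pair_counts": self.pair_counts,
            "exceed_counts": self.exceed_counts,
            "cutoff": self.cutoff,
        }


def group_summary(dm: DistanceMatrix, groups: Mapping[str, str],
                  cutoff: float = 0.0) -> GroupSummary:
    """Summarize a distance matrix by group membership (id -> group label)."""
    labels = [groups[i] for i in dm.ids]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("group summary needs >= 2 groups")
    n = len(dm.ids)
    within: dict[str, list[float]] = {g: [] for g in uniq}
    between: list[float] = []
    between_by_pair: dict[str, list[float]] = {}
    for i, j in itertools.combinations(range(n), 2):
        gi, gj = labels[i], labels[j]
        v = dm.values[i, j]
        if gi == gj:
            within[gi].append(v)
        else:
            between.append(v)
            key = "|".join(sorted((gi, gj)))
            between_by_pair.setdefault(key, []).append(v)
    if not between:
        raise ValueError("no across-group pairs")
    pair_counts = {f"within:{g}": len(v) for g, v in within.items()}
    pair_counts["between"] = len(between)
    pair_counts.update({f"between:{k}": len(v)
                        for k, v in between_by_pair.items()})
    exceed = {f"within:{g}": sum(1 for x in v if x > cutoff)
              for g, v in within.items()}
    exceed["between"] = sum(1 for x in between if x > cutoff)
    exceed.update({f"between:{k}": sum(1 for x in v if x > cutoff)
                   for k, v in between_by_pair.items()})
    return GroupSummary(
        within_means={g: (float(np.mean(v)) if v else None)
                      for g, v in within.items()},
        between_mean=float(np.mean(between)),
        min_between=float(np.min(between)),
        pair_counts=pair_counts,
        exceed_counts=exceed,
        cutoff=cutoff,
    )


@dataclass
class Embedding:
    ids: list[str]
    coordinates: np.ndarray
    stress: float
    negative_eigenvalue_mass: float = 0.0
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_tsv(self, path: str | Path,
               groups: Mapping[str, str] | None = None) -> None:
        dims = self.coordinates.shape[1]
        header = ["id", "group"] + [f"axis{k + 1}" for k in range(dims)]
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for i, tid in enumerate(self.ids):
                g = groups.get(tid, "") if groups else ""
                coords = "\t".join(f"{x:.10g}" for x in self.coordinates[i])
                fh.write(f"{tid}\t{g}\t{coords}\n")


def embed_cmds(dm: DistanceMatrix, dims: int = 2) -> Embedding:
    """Classical (Torgerson) metric MDS of a distance matrix.

    Deterministic up to isometry; the sign convention fixes each axis so
    its largest-magnitude coordinate is positive.  Stress is the Kruskal
    stress-1 of the embedded vs input distances.
    """
    n = len(dm.ids)
    if dims >= n:
        raise ValueError(f"dims ({dims}) must be < number of points ({n})")
    d2 = dm.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    neg_mass = float(-evals[evals < 0].sum())
    lam = np.clip(evals[:dims], 0.0, None)
    coords = evecs[:, :dims] * np.sqrt(lam)
    for k in range(dims):
        col = coords[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    emb_d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    denom = (dm.values ** 2).sum()
    stress = float(np.sqrt(((emb_d - dm.values) ** 2).sum() / denom)) if denom > 0 else 0.0
    return Embedding(ids=list(dm.ids), coordinates=coords, stress=stress,
                     negative_eigenvalue_mass=neg_mass, eigenvalues=evals)


def hexbin_counts(emb: Embedding, gridsize: int = 20
                  ) -> list[tuple[float, float, int]]:
    """Occupancy counts over a hexagonal tessellation of the 2-D embedding.

    Returns (center_x, center_y, count) for every occupied cell; counts sum
    to the number of embedded points.  Uses matplotlib's hexagonal binning.
    """
    if emb.coordinates.shape[1] != 2:
        raise ValueError("hexagonal binning requires a 2-D embedding")
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x, y = emb.coordinates[:, 0], emb.coordinates[:, 1]
    fig, ax = plt.subplots()
    try:
        coll = ax.hexbin(x, y, gridsize=gridsize, mincnt=1)
        counts = coll.get_array()
        centers = coll.get_offsets()
    finally:
        plt.close(fig)
    out = [(float(cx), float(cy), int(c))
           for (cx, cy), c in zip(centers, counts)]
    total = sum(c for _, _, c in out)
    if total != len(emb.ids):  # matplotlib invariant; guards regressions
        raise RuntimeError("hexbin counts do not sum to number of points")
    return out
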