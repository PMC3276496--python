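"""Condition geometry in the (diversity, specialization) plane.

Each condition is a point (H_j, delta_j); pairwise Euclidean distances
between these points summarize how globally similar two transcriptomes
are, and a single-linkage sweep over the distance matrix gives a
deterministic reading of which conditions cluster together.  Distances
are computed on the raw axes (both in bits); a z-score standardization
mode exists behind a flag for sensitivity analysis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .infotheo import TranscriptomeStats

__all__ = [
    "DistanceMatrix",
    "embed",
    "euclidean_distances",
    "proximity_report",
    "plot_embedding",
]


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    condition_ids: list[str]
    d: pd.DataFrame

    def condensed(self) -> np.ndarray:
        return squareform(self.d.to_numpy(), checks=False)

    def lower_triangle(self) -> pd.DataFrame:
        """Render as a lower-triangle table (rows from the 2nd condition
        on, columns up to the second-to-last), blank above the diagonal."""
        ids = self.condition_ids
        out = pd.DataFrame(
            "", index=ids[1:], columns=ids[:-1], dtype=object
        )
        for i, row in enumerate(ids[1:], start=1):
            for col in ids[:i]:
                out.loc[row, col] = float(self.d.loc[row, col])
        return out

    def to_dict(self) -> dict:
        return {
            "condition_ids": self.condition_ids,
            "distances": {
                a: {b: float(self.d.loc[a, b]) for b in self.condition_ids}
                for a in self.condition_ids
            },
        }


def embed(stats: TranscriptomeStats) -> pd.DataFrame:
    """One 2-D point per condition: columns ``Hj`` and ``deltaj``."""
    return pd.DataFrame(
        {"Hj": stats.Hj, "deltaj": stats.deltaj},
        index=pd.Index(stats.condition_ids, name="condition"),
    )


def euclidean_distances(
    points: pd.DataFrame, standardize: bool = False
) -> DistanceMatrix:
    """Pairwise Euclidean distances between condition points.

    ``standardize=True`` z-scores each axis first (mean 0, sd 1 across
    conditions) so both axes contribute equally regardless of scale.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    x = points.to_numpy(float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    dmat = squareform(pdist(x, metric="euclidean"))
    ids = list(points.index)
    return DistanceMatrix(
        condition_ids=ids, d=pd.DataFrame(dmat, index=ids, columns=ids)
    )


def proximity_report(d: DistanceMatrix, cut: float | None = None) -> dict:
    """Nearest neighbours and single-linkage grouping of the conditions.

    Returns a dict with

    * ``nearest_neighbor``: for each condition, its closest other
      condition (ties broken by condition-id order) and the distance;
    * ``merge_order``: the single-linkage dendrogram as a list of
      (members_a, members_b, height) merges, sorted by height;
    * ``groups``: the clusters obtained by cutting the dendrogram at
      ``cut`` (default: just below the final merge height, i.e. the
      two-cluster split), each group sorted by condition-id order.
    """
    ids = d.condition_ids
    mat = d.d.to_numpy(float)
    nn = {}
    for i, a in enumerate(ids):
        row = mat[i].copy()
        row[i] = np.inf
        j = int(np.argmin(row))  # argmin takes the first minimum: id order
        nn[a] = {"neighbor": ids[j], "distance": float(row[j])}
    Z = linkage(d.condensed(), method="single")
    members: dict[int, list[str]] = {i: [ids[i]] for i in range(len(ids))}
    merges = []
    for k, (a, b, height, _) in enumerate(Z):
        ma, mb = members[int(a)], members[int(b)]
        merges.append(
            {"a": sorted(ma), "b": sorted(mb), "height": float(height)}
        )
        members[len(ids) + k] = ma + mb
    if cut is None:
        cut = float(Z[-1, 2]) * (1 - 1e-9) if len(Z) else 0.0
    labels = fcluster(Z, t=cut, criterion="distance")
    groups: dict[int, list[str]] = {}
    for cond, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(cond)
    return {
        "nearest_neighbor": nn,
        "merge_order": merges,
        "cut": float(cut),
        "groups": sorted(
            (sorted(g) for g in groups.values()), key=lambda g: (len(g), g)
        ),
    }


def plot_embedding(stats: TranscriptomeStats, path) -> None:
    """Scatter of conditions in the (Hj, deltaj) plane, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = embed(stats)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pts["Hj"], pts["deltaj"], s=40, color="tab:blue")
    for cond, row in pts.iterrows():
        ax.annotate(
            str(cond),
            (row["Hj"], row["deltaj"]),
            textcoords="offset points",
            xytext=(5, 3),
        )
    ax.set_xlabel(f"diversity Hj (log base {stats.log_base:g})")
    ax.set_ylabel(f"specialization deltaj (log base {stats.log_base:g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
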