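"""Quality-threshold (QT) co-expression clustering with a Pearson diameter.

QT clustering greedily extracts, one at a time, the largest candidate
cluster whose *diameter* — the maximum pairwise distance among members —
stays at or below a fixed quality threshold.  Unlike k-means it never forces
a gene into a cluster: genes that would stretch every candidate past the
diameter remain unassigned, and candidates smaller than the minimum size are
discarded rather than reported.

The distance is d(a, b) = 1 − r(a, b) with r the Pearson correlation, so a
diameter of 0.5 keeps all intra-cluster pairs at r ≥ 0.5.  Pearson distance
is invariant to per-gene affine rescaling with positive slope, so clustering
scaled log2 profiles or raw fold changes gives the same partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClusterAssignment", "pearson_distance", "qt_cluster"]


@dataclass
class ClusterAssignment:
    """Gene → cluster id (1-based, in extraction order) or None."""

    labels: dict
    clusters: list[list]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.labels), "cluster_id": [
                self.labels[g] if self.labels[g] is not None else "NA"
                for g in self.labels
            ]}
        )

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def unassigned(self) -> list:
        return [g for g, c in self.labels.items() if c is None]


def pearson_distance(a, b) -> float:
    """1 − Pearson correlation; 0 for identical shape, 2 for anti-correlated."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("profiles must be 1-D, equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson distance undefined for a constant profile")
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - r


def _distance_matrix(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant profile(s): scale/exclude before clustering")
    return 1.0 - np.corrcoef(values)


def _grow_candidate(seed: int, available: np.ndarray, dmat: np.ndarray,
                    diameter: float) -> list[int]:
    """Greedy growth from one seed; ties broken by input order."""
    members = [seed]
    cur_diam = 0.0
    maxdist = dmat[seed].copy()  # max distance of each gene to the members
    candidates = [g for g in available if g != seed]
    while candidates:
        best_g, best_nd = None, None
        for g in candidates:  # input order => first minimum wins ties
            nd = max(cur_diam, maxdist[g])  # diameter if g joined
            if best_nd is None or nd < best_nd - 1e-12:
                best_g, best_nd = g, nd
        if best_nd > diameter + 1e-12:
            break
        members.append(best_g)
        cur_diam = best_nd
        candidates.remove(best_g)
        maxdist = np.maximum(maxdist, dmat[best_g])
    return members


def qt_cluster(
    profiles: pd.DataFrame,
    diameter: float = 0.5,
    min_size: int = 4,
) -> ClusterAssignment:
    """Classic QT clustering of a gene × timepoint matrix.

    For every remaining gene as seed, a candidate cluster is grown by
    repeatedly adding the gene that least increases the diameter while the
    diameter stays ≤ the threshold; the largest candidate (ties: earliest
    seed) is extracted and the procedure repeats on the rest.  Candidates
    below ``min_size`` leave their members unassigned.  Deterministic: ties
    in growth are broken by input order.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if not isinstance(profiles, pd.DataFrame):
        profiles = pd.DataFrame(np.asarray(profiles, dtype=float))
    genes = list(profiles.index)
    if not genes:
        raise ValueError("need at least one gene")
    values = profiles.to_numpy(dtype=float)
    if values.shape[0] == 1:
        # a single gene forms a cluster only if min_size allows it
        ok = min_size <= 1
        return ClusterAssignment(
            labels={genes[0]: 1 if ok else None},
            clusters=[[genes[0]]] if ok else [],
        )
    dmat = _distance_matrix(values)

    labels = {g: None for g in genes}
    clusters: list[list] = []
    available = np.array(range(len(genes)))
    while available.size:
        best_members, best_seed = None, None
        for seed in available:
            cand = _grow_candidate(seed, available, dmat, diameter)
            if best_members is None or len(cand) > len(best_members):
                best_members, best_seed = cand, seed
        if len(best_members) < min_size:
            break  # nothing extractable any more; rest stays unassigned
        clusters.append([genes[i] for i in best_members])
        for i in best_members:
            labels[genes[i]] = len(clusters)
        available = np.array([i for i in available if i not in set(best_members)])
    return ClusterAssignment(labels=labels, clusters=clusters)
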