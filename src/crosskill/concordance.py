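"""Cross-species structure in the screen: clustering and concordance.

Hierarchical clustering of cell lines on their drug-response profiles tests
whether lines group by species; the per-compound correlation of killing
between the two species quantifies how far a response measured in one
species transfers to the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["cluster_cell_lines", "species_concordance",
           "ClusteringResult", "ConcordanceResult"]


@dataclass
class ClusteringResult:
    linkage: np.ndarray          # scipy linkage matrix (merge order, heights)
    labels: list                 # cell-line names, input order
    leaf_order: list             # names in dendrogram leaf order
    k2_assignment: pd.Series     # cluster id (1/2) per line at the k=2 cut
    species_purity: float
    degenerate: bool             # all-tied distances; order-dependent result
    metric: str
    method: str
    n_imputed: int

    def newick(self):
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            bl_l = node.dist - node.get_left().dist
            bl_r = node.dist - node.get_right().dist
            return f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"

        return walk(tree) + ";"

    def linkage_table(self):
        n = len(self.labels)
        return pd.DataFrame({
            "step": np.arange(1, n),
            "left": self.linkage[:, 0].astype(int),
            "right": self.linkage[:, 1].astype(int),
            "height": self.linkage[:, 2],
        })


def _purity(assignment, species):
    """Best species<->cluster mapping accuracy for a 2-cluster assignment."""
    sp = np.asarray(species)
    cl = np.asarray(assignment)
    species_names = pd.unique(sp)
    if len(species_names) != 2:
        # single species: purity trivially 1 when one cluster holds everything
        return float(len(pd.unique(cl)) == 1)
    a, b = species_names
    acc1 = np.mean(((cl == 1) & (sp == a)) | ((cl == 2) & (sp == b)))
    acc2 = np.mean(((cl == 1) & (sp == b)) | ((cl == 2) & (sp == a)))
    return float(max(acc1, acc2))


def cluster_cell_lines(matrix, metric="euclidean", linkage="average"):
    """Cluster cell lines by drug-response profile and score species purity.

    Flagged/missing entries are imputed with the compound mean (count
    recorded).  Species purity is evaluated on the k=2 dendrogram cut: 1.0
    means the two clades separate the species exactly.
    """
    if metric not in ("euclidean", "correlation"):
        raise ValueError("metric must be 'euclidean' or 'correlation'")
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    values = matrix.values
    if values.shape[0] < 2:
        raise ValueError("need at least 2 cell lines")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 compounds (profile degenerate)")
    X = values.to_numpy(float)
    n_imputed = int(np.isnan(X).sum())
    if n_imputed:
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)

    d = pdist(X, metric=metric)
    Z = hierarchy.linkage(d, method=linkage)
    degenerate = bool(np.allclose(d, d[0]))
    k2 = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    labels = list(values.index)
    leaf_order = [labels[i] for i in hierarchy.leaves_list(Z)]
    assignment = pd.Series(k2, index=values.index, name="cluster")
    purity = _purity(k2, matrix.species.reindex(values.index))
    return ClusteringResult(Z, labels, leaf_order, assignment, purity, degenerate,
                            metric, linkage, n_imputed)


@dataclass
class ConcordanceResult:
    table: pd.DataFrame      # per-compound killing in species A and B
    species_a: str
    species_b: str
    r: float
    r_squared: float
    p_value: float
    n_compounds: int

    def to_dict(self):
        return {"species_a": self.species_a, "species_b": self.species_b,
                "r": self.r, "r_squared": self.r_squared,
                "p_value": self.p_value, "n_compounds": self.n_compounds}


def species_concordance(matrix, species_a=None, species_b=None):
    """Per-compound killing correlation between two species.

    Uses the species-mean killing per compound when a species has several
    lines.  r is the Pearson correlation; the two-sided p-value comes from
    t = r * sqrt((n-2)/(1-r²)) on n-2 degrees of freedom.
    """
    species = matrix.species
    names = list(pd.unique(species))
    if species_a is None or species_b is None:
        if len(names) != 2:
            raise ValueError("specify species_a and species_b when not exactly 2 species")
        species_a, species_b = names
    prof_a = matrix.values.loc[species == species_a].mean(axis=0)
    prof_b = matrix.values.loc[species == species_b].mean(axis=0)
    both = pd.DataFrame({species_a: prof_a, species_b: prof_b}).dropna()
    n = len(both)
    if n < 3:
        raise ValueError("need at least 3 shared compounds")
    x = both[species_a].to_numpy(float)
    y = both[species_b].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a species profile: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    table = both.rename_axis("compound_id")
    return ConcordanceResult(table, species_a, species_b, r, r * r, p, n)
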