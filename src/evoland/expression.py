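"""Differential expression from replicate log2 ratios, transcriptome
distances, similarity trees and qPCR relative quantification.

Input is a matrix of log2(evolved / preadapted) expression ratios, genes by
samples, three biological replicates per genotype in the study design
(technical replicates are averaged upstream).  A gene is differentially
expressed (DEG) when |log2 ratio| >= 1 in at least two of three replicates,
with a direction; genes meeting both direction predicates are 'ambiguous'
and excluded from downstream concordance tallies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .landscape import normalize_gene

__all__ = [
    "ExpressionMatrix",
    "DEGSet",
    "DistanceMatrix",
    "QPCRMeasurement",
    "call_degs",
    "euclidean_distance",
    "distance_matrix",
    "similarity_tree",
    "pfaffl_ratio",
    "deg_set_comparisons",
]

DEG_THRESHOLD = 1.0
MIN_REPLICATES = 2


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2(evolved/preadapted) ratios.

    ``samples`` are (genotype, replicate) pairs; missing values are NaN and
    never zero-filled.
    """

    data: pd.DataFrame  # index: genes, columns: MultiIndex (genotype, replicate)

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValueError("columns must be a (genotype, replicate) MultiIndex")
        self.data.index = [normalize_gene(g) for g in self.data.index]

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    def replicates(self, genotype: str) -> pd.DataFrame:
        if genotype not in set(self.data.columns.get_level_values(0)):
            raise KeyError(f"genotype {genotype!r} absent from matrix")
        return self.data[genotype]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        """Read a TSV with genes as rows and 'genotype.replicate' columns."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        cols = []
        for c in df.columns:
            genotype, _, rep = str(c).rpartition(".")
            if not genotype:
                raise ValueError(f"column {c!r} is not 'genotype.replicate'")
            cols.append((genotype, int(rep)))
        df.columns = pd.MultiIndex.from_tuples(cols, names=["genotype", "replicate"])
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.columns = [f"{g}.{r}" for g, r in out.columns]
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


@dataclass
class DEGSet:
    """Up-/down-regulated gene sets for one genotype.

    ``ambiguous`` holds genes meeting both direction predicates; the three
    sets are pairwise disjoint.
    """

    genotype: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    ambiguous: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.up & self.down or self.up & self.ambiguous or self.down & self.ambiguous:
            raise ValueError("up/down/ambiguous sets must be disjoint")

    @property
    def all_degs(self) -> set[str]:
        return self.up | self.down | self.ambiguous

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "up", self.genotype) for g in sorted(self.up)]
        rows += [(g, "down", self.genotype) for g in sorted(self.down)]
        rows += [(g, "ambiguous", self.genotype) for g in sorted(self.ambiguous)]
        return pd.DataFrame(rows, columns=["gene", "direction", "genotype"])


def call_degs(
    matrix: ExpressionMatrix,
    genotype: str,
    threshold: float = DEG_THRESHOLD,
    min_replicates: int = MIN_REPLICATES,
) -> DEGSet:
    """Call DEGs for one genotype by the replicate-consistency rule.

    A gene is up when log2 >= threshold in at least ``min_replicates``
    replicates, down when log2 <= -threshold in at least that many; genes
    satisfying both are ambiguous.  NaN values never count toward the
    replicate quorum.
    """
    reps = matrix.replicates(genotype)
    up_n = (reps >= threshold).sum(axis=1)
    down_n = (reps <= -threshold).sum(axis=1)
    up_mask = up_n >= min_replicates
    down_mask = down_n >= min_replicates
    both = up_mask & down_mask
    return DEGSet(
        genotype=genotype,
        up=set(reps.index[up_mask & ~both]),
        down=set(reps.index[down_mask & ~both]),
        ambiguous=set(reps.index[both]),
    )


def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Euclidean distance between two transcriptomes of log2 ratios.

    Gene pairs with a missing value in either vector are dropped
    (complete-pairs policy); an empty overlap is an error.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must have equal length with aligned genes")
    keep = ~(np.isnan(p) | np.isnan(q))
    if not keep.any():
        raise ValueError("no complete gene pairs between the two transcriptomes")
    d = p[keep] - q[keep]
    return float(np.sqrt(np.sum(d * d)))


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    labels: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.distances = d


def distance_matrix(matrix: ExpressionMatrix) -> DistanceMatrix:
    """All pairwise Euclidean distances between samples of a matrix."""
    cols = [f"{g}.{r}" for g, r in matrix.data.columns]
    n = len(cols)
    d = np.zeros((n, n))
    vals = matrix.data.to_numpy(dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = euclidean_distance(vals[:, i], vals[:, j])
    return DistanceMatrix(labels=cols, distances=d)


def _to_newick(node: hierarchy.ClusterNode, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    parts = []
    for child in (node.left, node.right):
        length = (node.dist - child.dist) / 2 if not child.is_leaf() else node.dist / 2
        parts.append(f"{_to_newick(child, labels)}:{length:.6g}")
    return "(" + ",".join(parts) + ")"


def similarity_tree(distances: DistanceMatrix) -> str:
    """Average-linkage hierarchical clustering of a distance matrix, emitted
    as Newick text.

    Labels are sorted lexicographically before linkage so ties in merge
    distance break deterministically.
    """
    if len(distances.labels) < 2:
        raise ValueError("at least two labels required to build a tree")
    order = sorted(range(len(distances.labels)), key=lambda i: distances.labels[i])
    labels = [distances.labels[i] for i in order]
    d = distances.distances[np.ix_(order, order)]
    condensed = squareform(d, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    root = hierarchy.to_tree(link)
    return _to_newick(root, labels) + ";"


@dataclass(frozen=True)
class QPCRMeasurement:
    """Efficiency-corrected RT-qPCR measurement for the Pfaffl calculation.

    Efficiencies are per-cycle amplification factors (2 = perfect doubling);
    delta-Cq values are Cq(start) - Cq(evolved) in cycles, for the target
    gene and the normalization reference (ACT1 in the study).
    """

    target_efficiency: float
    reference_efficiency: float
    delta_cq_target: float
    delta_cq_reference: float

    def __post_init__(self) -> None:
        for name in ("target_efficiency", "reference_efficiency"):
            e = getattr(self, name)
            if not (1.0 < e <= 2.2):
                raise ValueError(f"{name} must be in (1, 2.2], got {e}")
        for name in ("delta_cq_target", "delta_cq_reference"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def pfaffl_ratio(m: QPCRMeasurement) -> float:
    """Pfaffl relative expression: E_t^dCq_target / E_ref^dCq_reference."""
    return (
        m.target_efficiency ** m.delta_cq_target
        / m.reference_efficiency ** m.delta_cq_reference
    )


def deg_set_comparisons(
    sets: Mapping[str, DEGSet]
) -> dict[str, dict[frozenset[str], set[str]]]:
    """Exclusive intersections of DEG sets across genotypes (UpSet counts).

    For each direction ('up', 'down') and every non-empty genotype subset,
    the genes present in exactly the genotypes of that subset.  Exclusive
    sets over all subsets partition each genotype's genes of that direction.
    """
    if len(sets) < 2:
        raise ValueError("at least two genotypes required")
    out: dict[str, dict[frozenset[str], set[str]]] = {}
    for direction in ("up", "down"):
        membership: dict[str, set[str]] = {}
        for genotype, degs in sets.items():
            for gene in getattr(degs, direction):
                membership.setdefault(gene, set()).add(genotype)
        exclusive: dict[frozenset[str], set[str]] = {}
        for gene, members in membership.items():
            exclusive.setdefault(frozenset(members), set()).add(gene)
        out[direction] = exclusive
    return out
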