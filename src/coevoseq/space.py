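"""Genotype space: squared-Hamming distances, PCoA embedding, lineage edges.

Genotypes are compared by Hamming distance over the dominant mutation
sites, counting only sites unmasked in *both* genotypes: the large deletion
separating a parasite class from the host contributes zero, so a parasite
that "perfectly matches" a host outside its deletion sits at distance 0.
The pairwise map is built from the matrix D of *squared* Hamming distances:
D is double-centered into the kernel K = −(1/2)·C·D·C (C = I − 11ᵀ/n), K is
eigendecomposed, and each genotype i is placed at

    (x_i, y_i) = (sqrt(λ1)·e1_i, −sqrt(λ2)·e2_i),

the classical principal-coordinate construction, so Euclidean separation in
the map approximates the (unsquared) Hamming distance. Within-class pairs
at Hamming distance 1 and cross-class pairs at masked distance 0 form the
edge sets used to draw lineage networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.base import BaseEstimator

from .calling import MASKED, Genotype


def genotype_distance(g1: Genotype, g2: Genotype) -> int:
    """Hamming distance over sites unmasked in both genotypes."""
    if len(g1.vector) != len(g2.vector):
        raise ValueError(
            f"genotypes defined over different site lists "
            f"({len(g1.vector)} vs {len(g2.vector)} entries)"
        )
    return sum(
        1
        for a, b in zip(g1.vector, g2.vector)
        if a != MASKED and b != MASKED and a != b
    )


@dataclass
class GenotypeDistanceMatrix:
    """Squared-Hamming distance matrix over a genotype list."""

    genotypes: list[Genotype]
    matrix: np.ndarray  # D, squared Hamming distances
    cross_class: np.ndarray  # boolean flag per pair

    @property
    def hamming(self) -> np.ndarray:
        """Unsquared Hamming distances (integer-valued)."""
        return np.sqrt(self.matrix)


def build_distance_matrix(genotypes: Sequence[Genotype]) -> GenotypeDistanceMatrix:
    """Full symmetric matrix of squared masked-Hamming distances."""
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("need at least one genotype")
    n = len(genotypes)
    vecs = np.array([g.vector for g in genotypes], dtype=np.int64)
    masked = vecs == MASKED
    labels = np.array([g.class_label for g in genotypes])
    # pairwise count of sites unmasked in both and differing
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = ~masked[i] & ~masked
        diff = (vecs[i] != vecs) & both
        d[i] = diff.sum(axis=1)
    cross = labels[:, None] != labels[None, :]
    return GenotypeDistanceMatrix(genotypes, (d * d).astype(float), cross)


@dataclass
class Embedding:
    """Principal-coordinate embedding of a genotype distance matrix."""

    kernel: np.ndarray
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns, matching eigenvalue order
    coordinates: np.ndarray  # (n, 2)
    negative_eigenvalue_mass: float
    second_axis_degenerate: bool = False


class SquaredHammingPCoA(BaseEstimator):
    """Principal coordinate analysis of a squared-Hamming distance matrix.

    Parameters
    ----------
    literal_eigenvalue_scaling : bool
        If True, scale axes by λ instead of sqrt(λ). The conventional
        square-root scaling (default) makes map distances reproduce the
        input dissimilarities when the matrix is Euclidean.
    flip_second_axis : bool
        Negate the second coordinate (a reflection; pairwise distances are
        unaffected).

    Attributes (after :meth:`fit`)
    ------------------------------
    kernel_ : ndarray
        K = −(1/2)·C·D·C, row and column sums zero.
    eigenvalues_, eigenvectors_ : ndarray
        Full spectrum, descending; eigenvector sign fixed so the first
        non-zero component is positive.
    embedding_ : ndarray of shape (n, 2)
    negative_eigenvalue_mass_ : float
        |sum of negative λ| / sum |λ| — squared-Hamming matrices need not be
        Euclidean, and this reports how non-Euclidean the input was.
    """

    def __init__(self, literal_eigenvalue_scaling: bool = False,
                 flip_second_axis: bool = True):
        self.literal_eigenvalue_scaling = literal_eigenvalue_scaling
        self.flip_second_axis = flip_second_axis

    def fit(self, D: np.ndarray | GenotypeDistanceMatrix, y=None
            ) -> "SquaredHammingPCoA":
        if isinstance(D, GenotypeDistanceMatrix):
            D = D.matrix
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be square")
        if not np.allclose(D, D.T):
            raise ValueError("D must be symmetric")
        if (D < 0).any():
            raise ValueError("D must be non-negative")
        n = D.shape[0]
        centering = np.eye(n) - np.full((n, n), 1.0 / n)
        kernel = -0.5 * centering @ D @ centering
        kernel = (kernel + kernel.T) / 2.0  # symmetrise against roundoff
        eigenvalues, eigenvectors = eigh(kernel)
        order = np.argsort(eigenvalues)[::-1]
        eigenvalues = eigenvalues[order]
        eigenvectors = eigenvectors[:, order]
        for k in range(n):  # deterministic sign: first nonzero component > 0
            col = eigenvectors[:, k]
            nz = np.nonzero(np.abs(col) > 1e-12)[0]
            if nz.size and col[nz[0]] < 0:
                eigenvectors[:, k] = -col

        def axis(k: int) -> tuple[np.ndarray, bool]:
            lam = eigenvalues[k] if n > k else 0.0
            if lam <= 0:
                return np.zeros(n), True
            scale = lam if self.literal_eigenvalue_scaling else np.sqrt(lam)
            return scale * eigenvectors[:, k], False

        x, _ = axis(0)
        y_coord, degenerate = axis(1)
        if self.flip_second_axis:
            y_coord = -y_coord
        total = np.abs(eigenvalues).sum()
        neg_mass = float(np.abs(eigenvalues[eigenvalues < 0]).sum() / total
                         ) if total > 0 else 0.0
        self.kernel_ = kernel
        self.eigenvalues_ = eigenvalues
        self.eigenvectors_ = eigenvectors
        self.embedding_ = np.column_stack([x, y_coord])
        self.negative_eigenvalue_mass_ = neg_mass
        self.second_axis_degenerate_ = degenerate
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        return self.fit(D).embedding_

    def as_embedding(self) -> Embedding:
        return Embedding(
            kernel=self.kernel_,
            eigenvalues=self.eigenvalues_,
            eigenvectors=self.eigenvectors_,
            coordinates=self.embedding_,
            negative_eigenvalue_mass=self.negative_eigenvalue_mass_,
            second_axis_degenerate=self.second_axis_degenerate_,
        )


def pcoa_embed(D: np.ndarray | GenotypeDistanceMatrix, **params) -> Embedding:
    """Functional wrapper over :class:`SquaredHammingPCoA`."""
    return SquaredHammingPCoA(**params).fit(D).as_embedding()


@dataclass
class EdgeSet:
    """Lineage edges: within-class Hamming-1 pairs, cross-class 0 pairs."""

    within: list[tuple[int, int]] = field(default_factory=list)
    cross: list[tuple[int, int]] = field(default_factory=list)
    genotypes: list[Genotype] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph()
        for i, g in enumerate(self.genotypes):
            graph.add_node(i, class_label=g.class_label, round=g.round,
                           frequency=g.frequency)
        graph.add_edges_from(self.within, kind="within")
        graph.add_edges_from(self.cross, kind="cross")
        return graph

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id1": i, "id2": j, "type": "within", "distance": 1}
            for i, j in self.within
        ] + [
            {"id1": i, "id2": j, "type": "cross", "distance": 0}
            for i, j in self.cross
        ]
        return pd.DataFrame(rows, columns=["id1", "id2", "type", "distance"])


def build_edges(
    genotypes: Sequence[Genotype],
    distance_matrix: GenotypeDistanceMatrix | None = None,
) -> EdgeSet:
    """Connect within-class pairs at Hamming 1 and cross-class pairs at 0.

    A cross-class zero-distance pair (perfect match ignoring the large
    deletion) is a candidate parasite-generation event: the parasite is one
    deletion away from that host genotype.
    """
    genotypes = list(genotypes)
    if distance_matrix is None:
        distance_matrix = build_distance_matrix(genotypes) if genotypes else None
    edges = EdgeSet(genotypes=genotypes)
    if distance_matrix is None:
        return edges
    if len(distance_matrix.genotypes) != len(genotypes):
        raise ValueError("distance matrix inconsistent with genotype list")
    hamming = distance_matrix.hamming
    n = len(genotypes)
    for i in range(n):
        for j in range(i + 1, n):
            same = genotypes[i].class_label == genotypes[j].class_label
            if same and hamming[i, j] == 1:
                edges.within.append((i, j))
            elif not same and hamming[i, j] == 0:
                edges.cross.append((i, j))
    return edges
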