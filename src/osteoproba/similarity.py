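"""Pairwise sample similarity from shared spectra, clustering and heatmap.

Two bone samples are compared through the peptide sequences their filtered
spectra identify: a spectrum of X counts as shared when any of its (equally
likely) peptide sequences also occurs among Y's identified sequences. The
similarity ratio is (x_shared + y_shared) / (X_T + Y_T) with X_T, Y_T the
samples' total distinct spectrum counts, which keeps samples with very
different spectral depth comparable without further normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .psm_io import SampleResult
from .substitution import strip_modifications

__all__ = ["SimilarityMatrix", "similarity_ratio", "build_matrix", "cluster", "render_heatmap"]


def _sequence_set(sample: SampleResult, strip_mods: bool) -> set[str]:
    peps = sample.peptides
    if strip_mods:
        return {strip_modifications(p) for p in peps}
    return set(peps)


def _shared_spectra(sample: SampleResult, other_sequences: set[str], strip_mods: bool) -> int:
    shared = 0
    for matches in sample.spectra().values():
        seqs = {m.peptide for m in matches}
        if strip_mods:
            seqs = {strip_modifications(s) for s in seqs}
        if seqs & other_sequences:
            shared += 1
    return shared


def similarity_ratio(x: SampleResult, y: SampleResult, strip_mods: bool = False) -> float:
    """(x_shared + y_shared) / (X_T + Y_T); 0 for empty samples (warned).

    Sequences are compared as exact peptide strings including modification
    annotations by default; ``strip_mods`` compares bare sequences instead.
    """
    xt, yt = x.n_spectra, y.n_spectra
    if xt + yt == 0:
        warnings.warn(f"samples {x.sample_id}, {y.sample_id} are both empty; ratio 0")
        return 0.0
    x_shared = _shared_spectra(x, _sequence_set(y, strip_mods), strip_mods)
    y_shared = _shared_spectra(y, _sequence_set(x, strip_mods), strip_mods)
    return (x_shared + y_shared) / (xt + yt)


@dataclass
class SimilarityMatrix:
    sample_ids: list[str]
    matrix: np.ndarray
    totals: list[int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match sample ids")


def build_matrix(samples: list[SampleResult], strip_mods: bool = False) -> SimilarityMatrix:
    """All-pairs symmetric similarity matrix with unit diagonal."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    n = len(samples)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = similarity_ratio(samples[i], samples[j], strip_mods)
    return SimilarityMatrix(
        sample_ids=[s.sample_id for s in samples],
        matrix=mat,
        totals=[s.n_spectra for s in samples],
    )


def cluster(matrix: SimilarityMatrix, method: str = "average") -> dict:
    """Agglomerative clustering on distance = 1 - similarity (UPGMA default).

    Returns the scipy linkage, a deterministic leaf order, and the dendrogram
    serialized as a Newick string.
    """
    dist = 1.0 - matrix.matrix
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=method)
    dendro = hierarchy.dendrogram(linkage, no_plot=True)
    leaf_order = [matrix.sample_ids[i] for i in dendro["leaves"]]
    return {
        "linkage": linkage,
        "leaf_order": leaf_order,
        "newick": _linkage_to_newick(linkage, matrix.sample_ids),
    }


def _linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, labels)
    return str(tree).strip()


def render_heatmap(
    matrix: SimilarityMatrix,
    path,
    taxonomy=None,
    taxa: dict[str, str] | None = None,
) -> None:
    """Clustered heatmap (darker = more similar) with an optional taxa bar.

    ``taxa`` maps sample_id to a taxon name used for the color bar; pass the
    cohort truth table's species or order column.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd
    import seaborn as sns

    df = pd.DataFrame(matrix.matrix, index=matrix.sample_ids, columns=matrix.sample_ids)
    row_colors = None
    if taxa:
        palette = sns.color_palette("husl", n_colors=len(set(taxa.values())))
        color_of = dict(zip(sorted(set(taxa.values())), palette))
        row_colors = pd.Series(
            {sid: color_of.get(taxa.get(sid)) for sid in matrix.sample_ids},
            name="taxon",
        )
    linkage = cluster(matrix)["linkage"]
    grid = sns.clustermap(
        df,
        row_linkage=linkage,
        col_linkage=linkage,
        cmap="YlOrRd",
        vmin=0.0,
        vmax=1.0,
        row_colors=row_colors,
        col_colors=row_colors,
    )
    grid.savefig(path, dpi=120)
    plt.close(grid.fig)
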