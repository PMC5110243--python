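"""PC1-derived gene signatures and threshold-fraction signature scoring.

In developing-neocortex single-cell data the first principal component of a
filtered reference matrix separates neural stem and progenitor cells
(NSPCs) from neurons. The NSPC signature is the ``n_top`` genes whose
expression correlates most positively with the PC1 cell scores, and the
neuron signature the ``n_top`` most anti-correlating genes. A cell is then
scored for either signature as the number of signature genes it expresses
above a log2-FPKM threshold, divided by the number of all genes it
expresses above that threshold.

The module also selects "informative" genes for downstream network and
trajectory analysis: for each of the first ``n_pcs`` principal components,
genes whose loading magnitude beats a permutation null at ``p_cut``, capped
at ``max_per_pc`` genes per component.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .expression_io import ExpressionMatrix

#: "expressed" threshold on the log2(FPKM+1) scale, after the study's usage
#: of expression greater than log2 FPKM of 5.
DEFAULT_SCORE_THRESHOLD = 5.0


@dataclass
class SignatureSet:
    """NSPC/neuron signature gene lists with their PC1 correlations.

    ``nspc_genes`` are sorted by descending correlation with PC1 and
    ``neuron_genes`` by ascending; the lists are disjoint.
    ``pc1_cell_scores`` are the (oriented) PC1 scores of the reference cells
    and ``pc1_loadings`` the oriented loading vector, kept so query cells
    can be projected onto the same axis.
    """

    nspc_genes: list[str]
    neuron_genes: list[str]
    pc1_gene_correlations: pd.Series
    pc1_cell_scores: pd.Series
    pc1_loadings: pd.Series
    reference_gene_means: pd.Series

    def __post_init__(self) -> None:
        if set(self.nspc_genes) & set(self.neuron_genes):
            raise ValueError("NSPC and neuron signatures overlap")

    def write_tsv(self, path: str | Path) -> None:
        rows = [(g, self.pc1_gene_correlations[g], "NSPC") for g in self.nspc_genes]
        rows += [(g, self.pc1_gene_correlations[g], "neuron") for g in self.neuron_genes]
        pd.DataFrame(rows, columns=["gene", "pc1_correlation", "signature"]).to_csv(
            path, sep="\t", index=False
        )


def _pc1(reference: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """PC1 cell scores and gene loadings; genes centered, not scaled."""
    x = reference.values.to_numpy(dtype=float)
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("constant matrix: PC1 undefined")
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(x)[:, 0]
    loadings = pca.components_[0]
    return scores, loadings


def pc1_signatures(
    reference: ExpressionMatrix,
    n_top: int = 100,
    orient_genes: list[str] | None = None,
) -> SignatureSet:
    """Derive NSPC and neuron signatures from PC1 of a reference matrix.

    The reference should already be gene-filtered and needs at least three
    cells. Each gene's Pearson correlation with the PC1 cell scores is
    computed; the top ``n_top`` genes form the NSPC signature and the bottom
    ``n_top`` the neuron signature.

    PCA sign is arbitrary, so the axis is oriented to make the NSPC
    (proliferative) direction positive: if ``orient_genes`` (a marker list)
    is given, scores are flipped so those genes' mean correlation is
    non-negative; otherwise the gene with the largest absolute correlation
    is made positive.
    """
    reference.require_log()
    if reference.n_cells < 3:
        raise ValueError("need at least 3 reference cells")
    if 2 * n_top > reference.n_genes:
        raise ValueError(
            f"n_top={n_top} too large for {reference.n_genes} genes "
            "(signatures must be disjoint)"
        )
    scores, loadings = _pc1(reference)
    x = reference.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    sc = scores - scores.mean()
    denom = np.sqrt((xc**2).sum(axis=0)) * np.sqrt((sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc.T @ sc) / denom
    corr = np.nan_to_num(corr, nan=0.0)

    if orient_genes is not None:
        idx = [reference.gene_ids.index(g) for g in orient_genes if g in reference.gene_ids]
        if not idx:
            raise ValueError("no orientation marker present in the reference")
        flip = corr[idx].mean() < 0
    else:
        flip = corr[np.argmax(np.abs(corr))] < 0
    if flip:
        corr, scores, loadings = -corr, -scores, -loadings

    corr_s = pd.Series(corr, index=reference.gene_ids)
    order = corr_s.sort_values(ascending=False, kind="stable")
    nspc = list(order.index[:n_top])
    neuron = list(order.index[::-1][:n_top])
    return SignatureSet(
        nspc_genes=nspc,
        neuron_genes=neuron,
        pc1_gene_correlations=corr_s,
        pc1_cell_scores=pd.Series(scores, index=reference.cell_ids),
        pc1_loadings=pd.Series(loadings, index=reference.gene_ids),
        reference_gene_means=reference.values.mean(axis=0),
    )


def signature_score(
    cell: pd.Series,
    sig: SignatureSet,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> tuple[float, float]:
    """(NSPC score, neuron score) for one cell's log2(FPKM+1) vector.

    Score = |signature genes expressed above threshold| / |all genes
    expressed above threshold|. When the cell expresses no gene above the
    threshold both scores are NaN (undefined), never zero.
    """
    above = set(cell.index[cell > threshold])
    if not above:
        return float("nan"), float("nan")
    nspc = len(above & set(sig.nspc_genes)) / len(above)
    neuron = len(above & set(sig.neuron_genes)) / len(above)
    return nspc, neuron


def score_cells(
    m: ExpressionMatrix,
    sig: SignatureSet,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Signature scores plus PC1 projection for every cell of a matrix.

    ``pc1_position`` projects each cell onto the reference PC1 axis using
    the genes shared with the reference, centered by the reference means.
    """
    m.require_log()
    shared = [g for g in sig.pc1_loadings.index if g in m.values.columns]
    rows = []
    for cell_id in m.cell_ids:
        vec = m.values.loc[cell_id]
        nspc, neuron = signature_score(vec, sig, threshold)
        if shared:
            centered = vec[shared] - sig.reference_gene_means[shared]
            pos = float(centered @ sig.pc1_loadings[shared])
        else:
            pos = float("nan")
        rows.append(
            {
                "cell_id": cell_id,
                "nspc_score": nspc,
                "neuron_score": neuron,
                "pc1_position": pos,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def select_informative_genes(
    m: ExpressionMatrix,
    n_pcs: int = 6,
    max_per_pc: int = 200,
    p_cut: float = 1e-3,
    n_perm: int = 999,
    seed: int = 0,
) -> list[str]:
    """Genes defining the first ``n_pcs`` principal components.

    For each component, a gene's statistic is the magnitude of the
    covariance between its (centered) expression and the component's cell
    scores — monotone in the loading magnitude. The null distribution comes
    from ``n_perm`` random permutations of the score vector; the empirical
    p-value is the fraction of permutations meeting or exceeding the
    observed statistic (p = k/n_perm, so with n_perm = 999 the event
    p < 1e-3 requires zero exceedances and has exactly probability 1e-3 for
    a null gene). Genes with p < ``p_cut`` are kept, at most ``max_per_pc``
    per component by descending statistic; the union is returned in matrix
    gene order.
    """
    m.require_log()
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if m.n_cells < n_pcs + 1:
        raise ValueError(f"need more than {n_pcs} cells, have {m.n_cells}")
    rng = np.random.default_rng(seed)
    x = m.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(x)  # cells x n_pcs, centered by construction

    selected: set[int] = set()
    n_cells = x.shape[0]
    for k in range(n_pcs):
        s = scores[:, k]
        obs = np.abs(xc.T @ s)
        # permuting a gene's values against fixed scores is equivalent to
        # permuting the score vector against fixed genes
        perm_scores = np.empty((n_cells, n_perm))
        for j in range(n_perm):
            perm_scores[:, j] = rng.permutation(s)
        null = np.abs(xc.T @ perm_scores)  # genes x n_perm
        exceed = (null >= obs[:, None]).sum(axis=1)
        pvals = exceed / n_perm
        passing = np.flatnonzero(pvals < p_cut)
        if len(passing) > max_per_pc:
            passing = passing[np.argsort(-obs[passing], kind="stable")][:max_per_pc]
        selected.update(passing.tolist())
    gene_ids = m.gene_ids
    return [gene_ids[i] for i in sorted(selected)]
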