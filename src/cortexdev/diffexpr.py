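"""Threshold-based differential expression calling and lineage partitions.

Differential expression between two cell groups is summarised per gene as a
signed z-score from a pluggable backend; the default backend converts a
two-sided, tie- and continuity-corrected rank-sum (Mann-Whitney) statistic
to a normal deviate, with positive z meaning higher expression in the first
group. Downstream calls are made not on p-values but on standard-deviation
thresholds over the z distribution itself: one SD for cell-type
(AP-vs-neuron) specificity and two SDs for between-species differences,
with the added requirement that a species call lands on a gene that is
cell-type specific on the matching axis.

Also here: the AP-specificity score (mean AP expression minus the larger of
the iPSC and endothelial means, log2 units) and the partition of
differentially expressed genes by evolutionary lineage (shared with mouse,
human-chimp ancestor, human-only, chimp-only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix

GENE_CLASSES = (
    "none",
    "AP-specific",
    "N-specific",
    "human-up-AP",
    "human-up-N",
    "chimp-up-AP",
    "chimp-up-N",
    "G2M-enriched",
)


@dataclass
class DEResult:
    """Per-gene signed z-scores for one comparison.

    Positive z = higher in group A (for species comparisons, A = human by
    convention, so positive = higher in human).
    """

    z: pd.Series  # gene -> z
    comparison: str
    backend: str

    def write_tsv(self, path) -> None:
        df = self.z.rename("z").to_frame()
        df["comparison"] = self.comparison
        df["backend"] = self.backend
        df.to_csv(path, sep="\t", index_label="gene")


def ranksum_z(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed rank-sum normal deviates per gene (columns).

    ``a`` and ``b`` are cells x genes blocks. z is (U - mu +/- 0.5) / sigma
    with the tie-corrected variance; genes with zero variance (e.g. all-zero
    in both groups) get z = 0.
    """
    na, nb = a.shape[0], b.shape[0]
    n = na + nb
    combined = np.vstack([a, b])
    ranks = stats.rankdata(combined, axis=0)
    r_a = ranks[:na].sum(axis=0)
    u = r_a - na * (na + 1) / 2.0
    mu = na * nb / 2.0

    tie_term = np.zeros(combined.shape[1])
    for g in range(combined.shape[1]):
        _, counts = np.unique(combined[:, g], return_counts=True)
        tie_term[g] = np.sum(counts.astype(float) ** 3 - counts)
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(var)

    diff = u - mu
    cc = np.where(diff > 0, -0.5, np.where(diff < 0, 0.5, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (diff + cc) / sigma
    return np.where(sigma > 0, z, 0.0)


#: Registered z-score backends: name -> f(a_block, b_block) -> z per gene.
BACKENDS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "ranksum": ranksum_z,
}


def de_zscores(
    group_a: Sequence[str],
    group_b: Sequence[str],
    m: ExpressionMatrix,
    comparison: str = "",
    backend: str = "ranksum",
) -> DEResult:
    """Per-gene signed DE z-scores between two disjoint cell groups."""
    m.require_log()
    a_ids, b_ids = list(group_a), list(group_b)
    overlap = set(a_ids) & set(b_ids)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("need at least 3 cells per group")
    missing = (set(a_ids) | set(b_ids)) - set(m.cell_ids)
    if missing:
        raise ValueError(f"cells absent from matrix: {sorted(missing)[:5]}")
    fn = BACKENDS[backend]
    a = m.values.loc[a_ids].to_numpy(dtype=float)
    b = m.values.loc[b_ids].to_numpy(dtype=float)
    z = fn(a, b)
    return DEResult(
        z=pd.Series(z, index=m.gene_ids, name="z"),
        comparison=comparison,
        backend=backend,
    )


@dataclass
class GeneClassCall:
    """Per-gene class labels plus the thresholds that produced them."""

    classes: pd.Series  # gene -> class
    thresholds: dict[str, float]

    def genes_in(self, *names: str) -> set[str]:
        return set(self.classes.index[self.classes.isin(names)])


def specificity_calls(
    z_celltype: DEResult,
    z_species: DEResult,
    k_type: float = 1.0,
    k_species: float = 2.0,
    z_cycle: DEResult | None = None,
) -> GeneClassCall:
    """Call gene classes from SD thresholds on the z distributions.

    Over the genes shared by both results: a gene is AP-specific when its
    cell-type z exceeds mean + ``k_type`` SD of the cell-type z
    distribution (N-specific for the mirror tail). A species call
    additionally requires the species z beyond mean +/- ``k_species`` SD
    *and* cell-type specificity on the matching axis; positive species z
    means higher in human. With ``z_cycle`` given, genes above its
    mean + ``k_type`` SD and not otherwise called are G2M-enriched.
    SDs use ddof=1; a degenerate (zero-SD) distribution produces no calls
    and a warning.
    """
    shared = z_celltype.z.index.intersection(z_species.z.index)
    if shared.empty:
        raise ValueError("no shared genes between the two comparisons")
    zt = z_celltype.z[shared]
    zs = z_species.z[shared]
    mt, st = float(zt.mean()), float(zt.std(ddof=1))
    ms, ss = float(zs.mean()), float(zs.std(ddof=1))
    thresholds = {
        "type_hi": mt + k_type * st,
        "type_lo": mt - k_type * st,
        "species_hi": ms + k_species * ss,
        "species_lo": ms - k_species * ss,
    }
    classes = pd.Series("none", index=shared, name="class")
    if st == 0 or ss == 0:
        warnings.warn("degenerate z distribution; no calls made", stacklevel=2)
        return GeneClassCall(classes=classes, thresholds=thresholds)

    ap = zt > thresholds["type_hi"]
    nn = zt < thresholds["type_lo"]
    classes[ap] = "AP-specific"
    classes[nn] = "N-specific"
    human_up = zs > thresholds["species_hi"]
    chimp_up = zs < thresholds["species_lo"]
    classes[ap & human_up] = "human-up-AP"
    classes[ap & chimp_up] = "chimp-up-AP"
    classes[nn & human_up] = "human-up-N"
    classes[nn & chimp_up] = "chimp-up-N"

    if z_cycle is not None:
        zc = z_cycle.z.reindex(shared)
        mc, sc = float(zc.mean()), float(zc.std(ddof=1))
        if sc > 0:
            g2m = (zc > mc + k_type * sc) & (classes == "none")
            classes[g2m] = "G2M-enriched"
            thresholds["cycle_hi"] = mc + k_type * sc
    return GeneClassCall(classes=classes, thresholds=thresholds)


def ap_specificity_score(
    mean_ap: pd.Series,
    mean_ipsc: pd.Series,
    mean_ec: pd.Series,
) -> pd.Series:
    """AP-restriction score: mean_AP - max(mean_iPSC, mean_EC), log2 units.

    Computed over the union of gene ids; a gene missing from any source is
    flagged with NaN rather than dropped.
    """
    genes = mean_ap.index.union(mean_ipsc.index).union(mean_ec.index)
    ap = mean_ap.reindex(genes)
    other = pd.concat([mean_ipsc.reindex(genes), mean_ec.reindex(genes)], axis=1).max(
        axis=1, skipna=False
    )
    return (ap - other).rename("ap_specificity")


def lineage_partition(
    calls_human: set[str],
    calls_chimp: set[str],
    calls_mouse: set[str],
) -> dict[str, float]:
    """Partition DE genes by evolutionary lineage, as proportions of H u C.

    shared-with-mouse = H n C n M; human-chimp-ancestor = (H n C) \\ M;
    human-only = H \\ (C u M); chimp-only = C \\ (H u M).
    """
    h, c, mo = set(calls_human), set(calls_chimp), set(calls_mouse)
    universe = h | c
    if not universe:
        raise ValueError("no human or chimpanzee calls to partition")
    n = len(universe)
    return {
        "shared-with-mouse": len(h & c & mo) / n,
        "human-chimp-ancestor": len((h & c) - mo) / n,
        "human-only": len(h - (c | mo)) / n,
        "chimp-only": len(c - (h | mo)) / n,
    }
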