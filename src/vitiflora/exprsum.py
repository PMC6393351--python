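"""Gene-level expression summaries, hierarchical clustering and hotspots.

Probe-level, RMA-normalized (log2) microarray values are collapsed to gene
level by averaging the probes that bind uniquely to each gene; genes served
only by cross-hybridizing probes are dropped rather than contaminated.
Hierarchical clustering reorders genes/samples as a clustermap would, and a
block-detection heuristic operationalizes the "expression hotspot": after a
robust per-gene z-transform, both dendrograms are cut at their largest
merge-height gap and every (gene cluster x sample cluster) block with mean
z at or above the threshold is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .probemap import ProbeClassification, ProbeGeneMap

__all__ = [
    "GeneExpressionMatrix",
    "HotspotReport",
    "summarize_by_gene",
    "cluster_expression",
    "detect_hotspots",
]


@dataclass
class GeneExpressionMatrix:
    """Genes x samples summarized expression plus probe provenance."""

    matrix: pd.DataFrame
    provenance: dict[str, list[str]]        # gene -> unique probes averaged
    dropped_genes: list[str]                # genes with zero unique probes


@dataclass
class HotspotReport:
    """Elevated (gene set x sample set) blocks, sorted by mean z descending."""

    blocks: list[dict[str, object]]
    parameters: dict[str, float] = field(default_factory=dict)


def summarize_by_gene(
    expr: pd.DataFrame,
    classification: ProbeClassification,
    pg_map: ProbeGeneMap,
) -> GeneExpressionMatrix:
    """Average each gene's uniquely-binding probes, per sample.

    ``expr`` is probes x samples.  Genes whose probes are all ambiguous (or
    absent from ``expr``) land in ``dropped_genes``; probes in ``expr`` that
    the classification has never seen are an error.
    """
    universe = (
        classification.unique
        | set(classification.ambiguous)
        | classification.unmapped
    )
    stray = [p for p in expr.index if p not in universe]
    if stray:
        raise ValueError(f"probes absent from the classification: {stray}")

    gene_probes: dict[str, list[str]] = {g: [] for g in pg_map.gene_ids}
    for h in pg_map.hits:
        if h.probe_id in classification.unique and h.probe_id in expr.index:
            gene_probes[h.gene_id].append(h.probe_id)

    rows, provenance, dropped = [], {}, []
    for gene in pg_map.gene_ids:
        probes = sorted(gene_probes[gene])
        if probes:
            rows.append(expr.loc[probes].mean(axis=0).rename(gene))
            provenance[gene] = probes
        else:
            dropped.append(gene)
    matrix = (
        pd.DataFrame(rows)
        if rows
        else pd.DataFrame(columns=expr.columns)
    )
    return GeneExpressionMatrix(matrix=matrix, provenance=provenance,
                                dropped_genes=dropped)


def _linkage(data: np.ndarray, labels: Sequence[str], metric: str,
             linkage_method: str) -> np.ndarray:
    if metric == "correlation":
        sd = data.std(axis=1)
        flat = [labels[i] for i in np.nonzero(sd == 0)[0]]
        if flat:
            raise ValueError(
                f"constant rows under correlation metric: {flat}"
            )
    dist = pdist(data, metric=metric)
    return hierarchy.linkage(dist, method=linkage_method)


def cluster_expression(
    matrix: pd.DataFrame,
    axis: str = "both",
    metric: str = "euclidean",
    linkage: str = "average",
) -> dict[str, object]:
    """Deterministic hierarchical clustering of rows and/or columns.

    Returns the reordered matrix plus the scipy linkage trees and leaf
    orders for each clustered axis.
    """
    if axis not in ("rows", "columns", "both"):
        raise ValueError(f"axis must be rows|columns|both, got {axis!r}")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    out: dict[str, object] = {}
    row_order = list(range(len(matrix.index)))
    col_order = list(range(len(matrix.columns)))
    if axis in ("rows", "both"):
        if len(matrix.index) < 2:
            raise ValueError("need >=2 rows to cluster rows")
        Z = _linkage(matrix.to_numpy(float), list(matrix.index), metric, linkage)
        row_order = list(hierarchy.leaves_list(Z))
        out["row_linkage"], out["row_order"] = Z, [matrix.index[i] for i in row_order]
    if axis in ("columns", "both"):
        if len(matrix.columns) < 2:
            raise ValueError("need >=2 columns to cluster columns")
        Z = _linkage(matrix.to_numpy(float).T, list(matrix.columns), metric, linkage)
        col_order = list(hierarchy.leaves_list(Z))
        out["col_linkage"], out["col_order"] = Z, [matrix.columns[i] for i in col_order]
    out["matrix"] = matrix.iloc[row_order, col_order]
    return out


def _robust_z(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scores against median/MAD (MAD scaled to sigma).

    Median/MAD keeps a hotspot confined to a minority of samples from
    inflating its own baseline; rows with zero MAD get z = 0.
    """
    vals = matrix.to_numpy(float)
    med = np.median(vals, axis=1, keepdims=True)
    mad = np.median(np.abs(vals - med), axis=1, keepdims=True) * 1.4826
    z = np.zeros_like(vals)
    np.divide(vals - med, mad, out=z, where=mad > 0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def _corr_dist(data: np.ndarray) -> np.ndarray:
    """Condensed correlation distance; zero-variance vectors count as
    uncorrelated (distance 1) instead of propagating NaN."""
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    # symmetrize against fp asymmetry before condensing
    return (dist + dist.T)[np.triu_indices(len(dist), 1)] / 2.0


def _gap_cut(Z: np.ndarray, n: int) -> np.ndarray:
    """Flat clusters from cutting the dendrogram at its largest height gap."""
    heights = Z[:, 2]
    if len(heights) < 2:
        return hierarchy.fcluster(Z, t=max(2, n), criterion="maxclust")
    gaps = np.diff(heights)
    i = int(np.argmax(gaps))
    k = len(heights) - i  # clusters remaining below the gap
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def _refine_block(
    zc: np.ndarray,
    gene_idx: np.ndarray,
    samp_idx: np.ndarray,
    t: float,
    min_genes: int,
    min_samples: int,
) -> tuple[tuple[int, ...], tuple[int, ...], float] | None:
    """Sharpen a candidate block to the mean-threshold fixed point.

    Alternately re-selects the samples whose z over the block's genes
    clears the threshold and the genes whose z over those samples does,
    until stable.  Dendrogram cuts find the neighbourhood; this step trims
    diluting rows/columns and re-admits ones the cut misplaced.  Membership
    requires the threshold both in mean and in a majority of a candidate's
    cells, so a single lucky cell cannot drag a background row or sample
    into a block.
    """

    def _select(sub: np.ndarray) -> set[int]:
        means = sub.mean(axis=1)
        majority = (sub >= t).mean(axis=1) >= 0.5
        return set(np.nonzero((means >= t) & majority)[0])

    genes, samples = set(gene_idx), set(samp_idx)
    for _ in range(25):
        gi = np.fromiter(sorted(genes), dtype=int)
        new_samples = _select(zc[gi, :].T)
        if not new_samples:
            return None
        si = np.fromiter(sorted(new_samples), dtype=int)
        new_genes = _select(zc[:, si])
        if not new_genes:
            return None
        if new_genes == genes and new_samples == samples:
            break
        genes, samples = new_genes, new_samples
    if len(genes) < min_genes or len(samples) < min_samples:
        return None
    gi = tuple(sorted(genes))
    si = tuple(sorted(samples))
    return gi, si, float(zc[np.ix_(gi, si)].mean())


def detect_hotspots(
    matrix: pd.DataFrame,
    z_threshold: float = 1.5,
    min_genes: int = 2,
    min_samples: int = 2,
) -> HotspotReport:
    """Find coherent high-expression blocks in a genes x samples matrix.

    The matrix is row-z-scored against median/MAD (robust to a block that
    spans a minority of samples), genes and samples are average-linkage
    clustered under correlation distance (sensitive to a shared block
    pattern even when per-cell noise is large), both dendrograms are cut at
    their largest merge-height gap, and every resulting (gene cluster x
    sample cluster) block whose mean z >= ``z_threshold`` and that meets the
    size minima is reported, sorted by mean z descending.
    """
    if len(matrix.index) < min_genes or len(matrix.columns) < min_samples:
        raise ValueError("matrix smaller than the requested block minima")
    z = _robust_z(matrix)
    zc = z.to_numpy(float)
    if not zc.any():        # no variation anywhere: nothing to report
        return HotspotReport(blocks=[], parameters={
            "z_threshold": z_threshold, "min_genes": min_genes,
            "min_samples": min_samples,
        })

    row_Z = hierarchy.linkage(_corr_dist(zc), method="average")
    col_Z = hierarchy.linkage(_corr_dist(zc.T), method="average")
    row_cl = _gap_cut(row_Z, len(matrix.index))
    col_cl = _gap_cut(col_Z, len(matrix.columns))

    blocks, seen = [], set()
    for rc in np.unique(row_cl):
        gene_idx = np.nonzero(row_cl == rc)[0]
        if len(gene_idx) < min_genes:
            continue
        for cc in np.unique(col_cl):
            samp_idx = np.nonzero(col_cl == cc)[0]
            if len(samp_idx) < min_samples:
                continue
            refined = _refine_block(zc, gene_idx, samp_idx, z_threshold,
                                    min_genes, min_samples)
            if refined is None:
                continue
            gi, si, mean_z = refined
            key = (tuple(gi), tuple(si))
            if key in seen:
                continue
            seen.add(key)
            blocks.append(
                {
                    "genes": sorted(matrix.index[i] for i in gi),
                    "samples": sorted(matrix.columns[i] for i in si),
                    "mean_z": mean_z,
                }
            )
    blocks.sort(key=lambda b: -b["mean_z"])
    return HotspotReport(
        blocks=blocks,
        parameters={
            "z_threshold": z_threshold,
            "min_genes": min_genes,
            "min_samples": min_samples,
        },
    )
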