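"""Single-cell QC filtering and marker-based cell-cycle phase calling.

Operates on a cells x genes :class:`anndata.AnnData` of raw counts (the
Cell Ranger MTX triplet layout is read with genes as MTX rows and cells as
columns, then transposed).

QC keeps cells with **more than** 200 detected genes and **less than** 6% of
total counts on mitochondrial genes (strict inequalities).

Phase scoring uses two marker modules (43 G1/S genes, 55 G2/M genes by
default).  A module score is the mean library-size-normalised (counts per
10k, log1p) expression over the marker set minus the mean over a size-matched
control set drawn from the same average-expression bins, so that scores are
centred near zero for cells not expressing the program.  A cell is called G0
when both scores are at or below the threshold (default 0); otherwise the
higher score wins (ties go to G1/S).

The shipped default marker lists are a reconstruction of the standard human
G1/S / G2/M module gene symbols (the canonical 43 + 55 sets); both lists are
user-overridable.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .resources import default_cell_cycle_genes

PHASES = ("G0", "G1S", "G2M")


class CellCycleError(ValueError):
    pass


def read_cellranger_mtx(directory) -> AnnData:
    """Read a Cell Ranger-layout triplet (matrix.mtx, genes.tsv, barcodes.tsv).

    The MTX is genes x cells and is transposed into a cells x genes AnnData.
    """
    import os

    from scipy.io import mmread

    d = str(directory)
    mat = sparse.csr_matrix(mmread(os.path.join(d, "matrix.mtx")).T)
    genes = pd.read_csv(os.path.join(d, "genes.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(os.path.join(d, "barcodes.tsv"), sep="\t", header=None)
    adata = AnnData(
        X=mat,
        obs=pd.DataFrame(index=barcodes[0].astype(str).values),
        var=pd.DataFrame(index=genes[genes.shape[1] - 1].astype(str).values),
    )
    return adata


def write_cellranger_mtx(adata: AnnData, directory) -> None:
    """Write an AnnData back to the Cell Ranger triplet layout (genes x cells)."""
    import os

    from scipy.io import mmwrite

    os.makedirs(str(directory), exist_ok=True)
    mat = sparse.coo_matrix(adata.X).T
    mmwrite(os.path.join(str(directory), "matrix.mtx"), mat)
    pd.DataFrame({0: adata.var_names, 1: adata.var_names}).to_csv(
        os.path.join(str(directory), "genes.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(str(directory), "barcodes.tsv"), sep="\t", header=False, index=False
    )


def cell_qc(adata: AnnData, mito_pattern: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics: detected genes and mitochondrial count fraction."""
    X = sparse.csr_matrix(adata.X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith(mito_pattern)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {"n_genes_detected": n_genes.astype(int), "mito_fraction": mito_frac},
        index=adata.obs_names,
    )


def qc_filter(
    adata: AnnData,
    min_genes: int = 200,
    max_mito: float = 0.06,
    mito_pattern: str = "MT-",
) -> tuple[AnnData, pd.DataFrame]:
    """Keep cells with > *min_genes* detected genes and < *max_mito* mito fraction.

    Both thresholds are strict inequalities.  Returns the filtered AnnData and
    a per-cell report with pass/fail reasons.

    Raises
    ------
    CellCycleError
        If no cells pass.
    """
    report = cell_qc(adata, mito_pattern)
    pass_genes = report["n_genes_detected"] > min_genes
    pass_mito = report["mito_fraction"] < max_mito
    report["pass"] = pass_genes & pass_mito
    reasons = []
    for pg, pm in zip(pass_genes, pass_mito):
        r = []
        if not pg:
            r.append(f"n_genes <= {min_genes}")
        if not pm:
            r.append(f"mito_fraction >= {max_mito}")
        reasons.append("; ".join(r))
    report["fail_reason"] = reasons
    if not report["pass"].any():
        raise CellCycleError("no cells pass QC")
    return adata[report["pass"].values].copy(), report


def _normalize_log1p(adata: AnnData, target_sum: float = 1e4) -> np.ndarray:
    """Counts-per-10k then log1p, densified (cells x genes)."""
    X = sparse.csr_matrix(adata.X).astype(float)
    total = np.asarray(X.sum(axis=1)).ravel()
    scale = np.where(total > 0, target_sum / np.maximum(total, 1), 0.0)
    X = sparse.diags(scale) @ X
    return np.log1p(np.asarray(X.todense()))


def score_gene_set(
    X_norm: np.ndarray,
    gene_names: Sequence[str],
    markers: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    rng: np.random.Generator | None = None,
    min_markers: int = 5,
) -> np.ndarray:
    """Binned-control module score for one marker set.

    Genes are ranked by their mean normalised expression and split into
    *n_bins* equal-occupancy bins; for each bin containing a marker, up to
    *n_ctrl* non-marker genes are sampled (without replacement, from a
    name-sorted pool, so scores are invariant to gene order).  The score is
    the per-cell mean over markers minus the mean over the pooled controls.

    Raises
    ------
    CellCycleError
        If fewer than *min_markers* markers are present in the matrix, or the
        total non-marker pool is smaller than *n_ctrl*.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    gene_names = list(gene_names)
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    marker_idx = np.array(
        sorted(name_to_idx[m] for m in markers if m in name_to_idx), dtype=int
    )
    if marker_idx.size < min_markers:
        raise CellCycleError(
            f"only {marker_idx.size} of {len(markers)} markers found "
            f"(need >= {min_markers})"
        )
    n_genes = len(gene_names)
    if n_genes - marker_idx.size < n_ctrl:
        raise CellCycleError(
            f"control pool ({n_genes - marker_idx.size} non-marker genes) "
            f"smaller than n_ctrl={n_ctrl}"
        )
    means = X_norm.mean(axis=0)
    # Rank by (mean, name) so ties break deterministically and the binning is
    # invariant under gene-order permutation.
    order = np.lexsort((np.array(gene_names), means))
    rank = np.empty(n_genes, dtype=int)
    rank[order] = np.arange(n_genes)
    bins = rank * n_bins // n_genes
    marker_set = set(marker_idx.tolist())
    ctrl: set[int] = set()
    for b in sorted(set(bins[marker_idx].tolist())):
        pool = [
            i
            for i in np.flatnonzero(bins == b).tolist()
            if i not in marker_set
        ]
        pool.sort(key=lambda i: gene_names[i])
        take = min(n_ctrl, len(pool))
        if take:
            chosen = rng.choice(len(pool), size=take, replace=False)
            ctrl.update(pool[c] for c in chosen)
    ctrl_idx = np.array(sorted(ctrl), dtype=int)
    return X_norm[:, marker_idx].mean(axis=1) - X_norm[:, ctrl_idx].mean(axis=1)


def score_phase(
    adata: AnnData,
    g1s_markers: Sequence[str] | None = None,
    g2m_markers: Sequence[str] | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell G1/S and G2/M module scores (columns ``g1s_score``,
    ``g2m_score``, ``score_difference``)."""
    if g1s_markers is None or g2m_markers is None:
        g1s_default, g2m_default = default_cell_cycle_genes()
        g1s_markers = g1s_markers or g1s_default
        g2m_markers = g2m_markers or g2m_default
    X = _normalize_log1p(adata)
    rng = np.random.default_rng(seed)
    g1s = score_gene_set(X, adata.var_names, g1s_markers, n_bins, n_ctrl, rng)
    g2m = score_gene_set(X, adata.var_names, g2m_markers, n_bins, n_ctrl, rng)
    return pd.DataFrame(
        {"g1s_score": g1s, "g2m_score": g2m, "score_difference": g1s - g2m},
        index=adata.obs_names,
    )


def call_phase(scores: pd.DataFrame, threshold: float = 0.0) -> pd.Series:
    """Assign G0 / G1S / G2M from the two module scores.

    G0 when both scores are <= *threshold* (the cell expresses neither
    program); otherwise G2M if the G2/M score exceeds the G1/S score, else
    G1S (ties go to G1S).
    """
    g1s = scores["g1s_score"].to_numpy(dtype=float)
    g2m = scores["g2m_score"].to_numpy(dtype=float)
    if not (np.isfinite(g1s).all() and np.isfinite(g2m).all()):
        raise CellCycleError("phase scores must be finite")
    phase = np.where(
        (g1s <= threshold) & (g2m <= threshold),
        "G0",
        np.where(g2m > g1s, "G2M", "G1S"),
    )
    return pd.Series(phase, index=scores.index, name="phase")


def phase_fractions(
    phases: pd.Series, conditions: pd.Series | Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-condition phase counts and fractions (fractions sum to 1)."""
    if conditions is None:
        conditions = pd.Series("all", index=phases.index)
    conditions = pd.Series(list(conditions), index=phases.index, name="condition")
    rows = []
    for cond, grp in phases.groupby(conditions):
        if len(grp) == 0:
            raise CellCycleError(f"empty condition {cond!r}")
        counts = grp.value_counts()
        row = {"condition": cond, "n_cells": int(len(grp))}
        for ph in PHASES:
            row[f"n_{ph.lower()}"] = int(counts.get(ph, 0))
            row[f"frac_{ph.lower()}"] = counts.get(ph, 0) / len(grp)
        rows.append(row)
    return pd.DataFrame(rows)
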