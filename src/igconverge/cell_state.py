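"""Plasmablast vs naive/memory classification from expression counts.

Two methods reproduce the marker-anchored partition of antibody-secreting
cells: ``marker_rule`` compares log2(CPM+1) of PRDM1 (plasmablast
transcription factor) against MS4A1 (CD20, naive/memory marker) per cell;
``pca_kmeans`` runs PCA on log2(CPM+1) of the top-variance genes followed by
2-means with a fixed seed, labelling the cluster with higher mean PRDM1 as
plasmablast. The marker rule is the default because the partition is
explicitly anchored to those two genes; PCA is confirmatory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ContractError
from .airr_io import ExpressionProfile, canonical_gene

PLASMABLAST = "plasmablast"
NAIVE_MEMORY = "naive_memory"
UNASSIGNED = "unassigned"


@dataclass
class CellStateCall:
    cell_id: str
    log_cpm_prdm1: float
    log_cpm_ms4a1: float
    state: str
    margin: float
    pc1: float = 0.0
    pc2: float = 0.0


def cpm_normalize(profile: ExpressionProfile) -> dict[str, float]:
    """Counts-per-million: count * 1e6 / total_counts for every gene."""
    if profile.total_counts <= 0:
        raise ContractError(f"empty_cell: {profile.cell_id} has zero total counts")
    scale = 1e6 / profile.total_counts
    return {g: c * scale for g, c in profile.counts.items()}


def _find_marker(genes: list[str], marker: str) -> str:
    matches = [g for g in genes if canonical_gene(g) == marker]
    if not matches:
        raise ContractError(f"marker gene {marker} absent from the gene universe")
    return matches[0]


def _log_cpm_frame(profiles: list[ExpressionProfile]) -> pd.DataFrame:
    genes = sorted({g for p in profiles for g in p.counts})
    mat = np.zeros((len(profiles), len(genes)))
    gidx = {g: i for i, g in enumerate(genes)}
    for i, p in enumerate(profiles):
        if p.total_counts <= 0:
            raise ContractError(f"empty_cell: {p.cell_id} has zero total counts")
        scale = 1e6 / p.total_counts
        for g, c in p.counts.items():
            mat[i, gidx[g]] = c * scale
    return pd.DataFrame(
        np.log2(mat + 1.0), index=[p.cell_id for p in profiles], columns=genes
    )


def classify_state(
    profiles: list[ExpressionProfile],
    method: str = "marker_rule",
    seed: int = 0,
    n_top_genes: int = 500,
) -> list[CellStateCall]:
    """Classify each cell as plasmablast / naive_memory / unassigned.

    marker_rule: plasmablast iff log2(cpm_PRDM1+1) > log2(cpm_MS4A1+1);
    unassigned iff both raw marker counts are zero. Scale-invariant per cell.

    pca_kmeans: PCA (gene-mean centred, unscaled) on log2(CPM+1) of the
    ``n_top_genes`` highest-variance genes, 2-means with ``seed``; the margin
    is the distance gap between the two centroids in PC space.
    """
    if method not in ("marker_rule", "pca_kmeans"):
        raise ContractError(f"unknown method {method!r}")
    if not profiles:
        return []
    logcpm = _log_cpm_frame(profiles)
    genes = list(logcpm.columns)
    prdm1 = _find_marker(genes, "PRDM1")
    ms4a1 = _find_marker(genes, "MS4A1")

    calls: list[CellStateCall] = []
    if method == "marker_rule":
        for p in profiles:
            lp = float(logcpm.at[p.cell_id, prdm1])
            lm = float(logcpm.at[p.cell_id, ms4a1])
            if p.counts.get(prdm1, 0) == 0 and p.counts.get(ms4a1, 0) == 0:
                state, margin = UNASSIGNED, 0.0
            elif lp > lm:
                state, margin = PLASMABLAST, lp - lm
            else:
                state, margin = NAIVE_MEMORY, lm - lp
            calls.append(CellStateCall(p.cell_id, lp, lm, state, margin))
        return calls

    if len(profiles) < 2:
        raise ContractError("pca_kmeans requires at least 2 cells")
    variances = logcpm.var(axis=0)
    # stable top-variance selection: sort by (-variance, gene name)
    top = sorted(genes, key=lambda g: (-variances[g], g))[: min(n_top_genes, len(genes))]
    x = logcpm[top].to_numpy()
    pca = PCA(n_components=min(2, x.shape[0] - 1, x.shape[1]), svd_solver="full", random_state=seed)
    scores = pca.fit_transform(x - x.mean(axis=0))
    if scores.shape[1] < 2:
        scores = np.column_stack([scores, np.zeros(len(scores))])
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(scores)
    mean_prdm1 = [logcpm[prdm1].to_numpy()[labels == k].mean() for k in (0, 1)]
    pb_cluster = int(np.argmax(mean_prdm1))
    dists = np.linalg.norm(scores[:, None, :] - km.cluster_centers_[None, :, :], axis=2)
    for i, p in enumerate(profiles):
        state = PLASMABLAST if labels[i] == pb_cluster else NAIVE_MEMORY
        margin = float(abs(dists[i, 0] - dists[i, 1]))
        calls.append(
            CellStateCall(
                p.cell_id,
                float(logcpm.at[p.cell_id, prdm1]),
                float(logcpm.at[p.cell_id, ms4a1]),
                state,
                margin,
                pc1=float(scores[i, 0]),
                pc2=float(scores[i, 1]),
            )
        )
    return calls


def state_frame(calls: list[CellStateCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "state": c.state,
                "log_cpm_prdm1": c.log_cpm_prdm1,
                "log_cpm_ms4a1": c.log_cpm_ms4a1,
                "margin": c.margin,
                "pc1": c.pc1,
                "pc2": c.pc2,
            }
            for c in calls
        ]
    )
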