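"""Scaffold enrichment via ancestral haplotype (AHAP) clusters.

Scaffold haplotypes are clustered window by window (k-modes on alleles,
Hamming distance).  A dense variant whose alleles are uniform within every
cluster of its window is "perfectly associated" with the cluster labels,
so an individual's allele at that variant can be phased simply by looking
up which cluster each of its two scaffold haplotypes belongs to.  Adding
these deterministically phased variants to the scaffold shortens the
intervals the aligner must interpolate across.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import MISSING, HaplotypeSet, MarkerPanel

__all__ = ["AhapAssignment", "cluster_haplotypes", "perfect_associations", "enrich_scaffold"]

logger = logging.getLogger(__name__)


@dataclass
class AhapAssignment:
    """Per-haplotype, per-window cluster labels on the scaffold panel.

    ``labels`` has shape (2 * n_individuals, n_windows); haplotype rows are
    ordered ``[ind0_hap0, ind0_hap1, ind1_hap0, ...]``.  ``windows`` holds
    (start, stop) scaffold-marker index pairs.
    """

    labels: np.ndarray
    windows: list
    k: int


def _kmodes(rows: np.ndarray, k: int, rng: np.random.Generator, n_iter: int = 25, n_init: int = 5) -> np.ndarray:
    """k-modes with Hamming distance; ties in assignment go to the lower label.

    Lloyd-style iterations from several seeded initialisations; the labelling
    with the lowest within-cluster Hamming cost wins.
    """
    uniq = np.unique(rows, axis=0)
    k_eff = min(k, len(uniq))
    if k_eff < k:
        logger.info("window has %d distinct haplotypes < K=%d; using K=%d", len(uniq), k, k_eff)
    best_labels, best_cost = None, np.inf
    for _init in range(n_init):
        modes = uniq[rng.choice(len(uniq), size=k_eff, replace=False)]
        labels = np.zeros(len(rows), dtype=np.int64)
        for it in range(n_iter):
            d = (rows[:, None, :] != modes[None, :, :]).sum(axis=2)
            new_labels = d.argmin(axis=1)  # argmin takes the lowest label on ties
            if it > 0 and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k_eff):
                members = rows[labels == c]
                if len(members):
                    modes[c] = (members.mean(axis=0) > 0.5).astype(rows.dtype)  # tie -> allele 0
        cost = 0
        for c in range(k_eff):
            members = rows[labels == c]
            if len(members):
                mode = (members.mean(axis=0) > 0.5).astype(rows.dtype)
                cost += int((members != mode).sum())
        if cost < best_cost:
            best_cost, best_labels = cost, labels
        if len(uniq) <= k_eff:  # every distinct haplotype is its own mode
            break
    return best_labels


def cluster_haplotypes(
    scaffold: HaplotypeSet, window_markers: int = 20, k: int = 50, seed: int = 0
) -> AhapAssignment:
    """Cluster scaffold haplotypes into K ancestral haplotypes per window.

    Windows are non-overlapping blocks of ``window_markers`` scaffold
    markers; within each, haplotypes are clustered by k-modes on alleles.
    Labels are stable under a fixed seed.  Windows with fewer distinct
    haplotypes than K use a reduced K (logged).
    """
    if k < 2:
        raise ValueError("K must be >= 2")
    if window_markers < 2:
        raise ValueError("window_markers must be >= 2")
    rng = np.random.default_rng(seed)
    n, m = scaffold.n_individuals, scaffold.n_markers
    haps = np.concatenate([scaffold.alleles[:, :, 0:1], scaffold.alleles[:, :, 1:2]], axis=2)
    rows = haps.transpose(0, 2, 1).reshape(2 * n, m)
    windows = [(a, min(a + window_markers, m)) for a in range(0, m, window_markers)]
    labels = np.zeros((2 * n, len(windows)), dtype=np.int64)
    for w, (a, b) in enumerate(windows):
        block = rows[:, a:b].copy()
        block[block == MISSING] = 0  # missing treated as ref for distance purposes
        labels[:, w] = _kmodes(block, k, rng)
    return AhapAssignment(labels=labels, windows=windows, k=k)


def perfect_associations(
    ahap: AhapAssignment,
    dense: HaplotypeSet,
    panel: MarkerPanel,
    scaffold_idx: np.ndarray = None,
):
    """Dense markers perfectly associated with the AHAP clusters of their window.

    ``dense`` supplies training haplotypes (truth or pre-phased) for the
    clustered individuals, ordered identically.  A marker is perfect in its
    containing window iff every haplotype within each cluster carries the
    same allele.  Returns ``{marker_index: {cluster: allele}}``.
    """
    if scaffold_idx is None:
        scaffold_idx = panel.scaffold_indices
    scaffold_idx = np.asarray(scaffold_idx, dtype=np.int64)
    n = dense.n_individuals
    rows = dense.alleles.transpose(0, 2, 1).reshape(2 * n, dense.n_markers)
    if 2 * n != ahap.labels.shape[0]:
        raise ValueError("dense haplotypes do not match the clustered individuals")
    # window physical bounds: midpoints between adjacent windows' edge markers
    edges = []
    for w, (a, b) in enumerate(ahap.windows):
        lo = panel.pos[scaffold_idx[a]]
        hi = panel.pos[scaffold_idx[b - 1]]
        edges.append((lo, hi))
    bounds = np.empty(len(edges) + 1)
    bounds[0] = -np.inf
    bounds[-1] = np.inf
    for w in range(1, len(edges)):
        bounds[w] = 0.5 * (edges[w - 1][1] + edges[w][0])
    window_of = np.searchsorted(bounds, panel.pos, side="right") - 1

    assoc = {}
    for j in range(panel.n_markers):
        w = int(window_of[j])
        lab = ahap.labels[:, w]
        alleles = rows[:, j]
        known = alleles != MISSING
        cmap = {}
        perfect = True
        for c in np.unique(lab):
            vals = np.unique(alleles[(lab == c) & known])
            if len(vals) != 1:
                perfect = False
                break
            cmap[int(c)] = int(vals[0])
        if perfect and cmap:
            assoc[j] = cmap
    return assoc


def enrich_scaffold(
    scaffold: HaplotypeSet,
    ahap: AhapAssignment,
    assoc_map: dict,
    panel: MarkerPanel,
    scaffold_idx: np.ndarray = None,
):
    """Add perfectly associated dense markers, phased by cluster lookup.

    Returns ``(enriched_haps, enriched_idx)``: a scaffold over the union of
    the original scaffold markers and the associated markers.  Original
    scaffold sites are never altered; an individual whose haplotype cluster
    is absent from a marker's map gets a missing allele there.
    """
    if scaffold_idx is None:
        scaffold_idx = panel.scaffold_indices
    scaffold_idx = np.asarray(scaffold_idx, dtype=np.int64)
    n = scaffold.n_individuals
    extra = sorted(set(assoc_map) - set(scaffold_idx.tolist()))
    enriched_idx = np.array(sorted(set(scaffold_idx.tolist()) | set(extra)), dtype=np.int64)
    m_new = len(enriched_idx)
    alleles = np.full((n, m_new, 2), MISSING, dtype=np.int8)
    col_of = {int(j): c for c, j in enumerate(enriched_idx)}
    for c, j in enumerate(scaffold_idx):
        alleles[:, col_of[int(j)], :] = scaffold.alleles[:, c, :]

    # window bounds as in perfect_associations
    bounds = np.empty(len(ahap.windows) + 1)
    bounds[0] = -np.inf
    bounds[-1] = np.inf
    for w in range(1, len(ahap.windows)):
        prev_hi = panel.pos[scaffold_idx[ahap.windows[w - 1][1] - 1]]
        lo = panel.pos[scaffold_idx[ahap.windows[w][0]]]
        bounds[w] = 0.5 * (prev_hi + lo)
    for j in extra:
        w = int(np.searchsorted(bounds, panel.pos[j], side="right") - 1)
        cmap = assoc_map[j]
        col = col_of[int(j)]
        for i in range(n):
            for h in (0, 1):
                lab = int(ahap.labels[2 * i + h, w])
                if lab in cmap:
                    alleles[i, col, h] = cmap[lab]
    return HaplotypeSet(alleles, origin_known=scaffold.origin_known.copy()), enriched_idx
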