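"""Orient LD-pre-phased dense haplotypes on a familially phased scaffold.

LD-only phasing is locally accurate but leaves the global paternal/maternal
orientation of each chromosome random and switches it occasionally along
the chromosome.  The sparse scaffold panel, phased with familial
information, is correct at long range.  Alignment decodes, for every
individual and chromosome, a two-state hidden Markov model over the
scaffold sites that are heterozygous (and phased) in both panels: state
``same`` means the pre-phased dense pair currently matches the scaffold
orientation, ``flipped`` that it is swapped.  Emissions compare the dense
allele at the scaffold position against the scaffold haplotype allele with
a small error probability, which makes the decoder robust to singleton
discordances; transitions follow a per-cM switch prior over genetic
distance.  The dense pair is then flipped wholesale between decoded
changepoints, transferring the scaffold's long-range parental origin to
the dense panel, and the scaffold phase is restored exactly at scaffold
positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import MISSING, HaplotypeSet, MarkerPanel, SegmentMap, build_segment_map

__all__ = ["AlignParams", "OrientationPath", "align_to_scaffold", "place_changepoint"]

SAME, FLIPPED = 0, 1


@dataclass
class AlignParams:
    """Orientation-HMM settings.

    ``flip_error`` is the probability that a single scaffold-site comparison
    is wrong (emission); ``switch_rate_per_cm`` the prior rate of pre-phase
    orientation switches per cM (transition); segments of the dense panel
    with fewer than ``min_segment_snps`` SNPs are not aligned independently
    (their scaffold site contributes no evidence and they inherit the
    surrounding orientation).  ``refine_changepoints`` relocates each flip
    boundary to the pre-phase's most likely internal switch position by
    Li-Stephens likelihood; when off, the boundary falls at the segment-map
    boundary nearest the interval midpoint (:func:`place_changepoint`).
    """

    flip_error: float = 0.01
    switch_rate_per_cm: float = 0.02
    min_segment_snps: int = 3
    refine_changepoints: bool = True
    refine_context: int = 15
    refine_states: int = 60

    def validate(self):
        for name in ("flip_error",):
            v = getattr(self, name)
            if not (0 < v < 0.5):
                raise ValueError(f"{name} must be in (0, 0.5)")
        if self.switch_rate_per_cm <= 0:
            raise ValueError("switch_rate_per_cm must be positive")
        if self.min_segment_snps < 1:
            raise ValueError("min_segment_snps must be >= 1")


@dataclass
class OrientationPath:
    """Decoded orientation evidence for one individual on one chromosome."""

    individual: int
    chrom: object
    site_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))  # panel indices
    evidence_match: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    state: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))  # SAME/FLIPPED


def _viterbi_two_state(match: np.ndarray, gpos: np.ndarray, params: AlignParams) -> np.ndarray:
    """Decode same/flipped over informative sites; ``match`` is the evidence."""
    m = len(match)
    le_ok = np.log1p(-params.flip_error)
    le_bad = np.log(params.flip_error)
    # emission log-likelihood per state: SAME is supported by a match
    em_same = np.where(match, le_ok, le_bad)
    em_flip = np.where(match, le_bad, le_ok)
    V = np.array([em_same[0], em_flip[0]]) + np.log(0.5)
    back = np.zeros((m, 2), dtype=np.int8)
    for t in range(1, m):
        d = gpos[t] - gpos[t - 1]
        p_sw = float(np.clip(-np.expm1(-params.switch_rate_per_cm * d), 1e-9, 0.5))
        l_stay, l_sw = np.log1p(-p_sw), np.log(p_sw)
        newV = np.empty(2)
        for s in (SAME, FLIPPED):
            stay = V[s] + l_stay
            sw = V[1 - s] + l_sw
            back[t, s] = s if stay >= sw else 1 - s
            newV[s] = max(stay, sw) + (em_same[t] if s == SAME else em_flip[t])
        V = newV
    states = np.empty(m, dtype=np.int8)
    states[m - 1] = int(np.argmax(V))
    for t in range(m - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states


def place_changepoint(segmap: SegmentMap, genetic_pos: np.ndarray, left: int, right: int) -> int:
    """Evidence-free flip-boundary placement inside one scaffold interval.

    Returns the dense-marker index ``b`` (``left < b <= right``) at which the
    orientation changes: the segment-map boundary whose genetic position is
    nearest the interval midpoint, exact ties breaking toward the
    lower-position boundary.  If the interval contains no segment boundary
    the marker gap nearest the midpoint is used.
    """
    if right <= left:
        raise ValueError("flanking states must delimit a non-empty interval")
    cands = [b for b in range(left + 1, right + 1) if segmap.segment_id[b] != segmap.segment_id[b - 1]]
    if not cands:
        cands = list(range(left + 1, right + 1))
    mid = 0.5 * (genetic_pos[left] + genetic_pos[right])
    bpos = [(0.5 * (genetic_pos[b - 1] + genetic_pos[b])) for b in cands]
    dists = [abs(p - mid) for p in bpos]
    best = min(range(len(cands)), key=lambda k: (dists[k], cands[k]))
    return cands[best]


def _haploid_loglik(hap: np.ndarray, ref: np.ndarray, gpos: np.ndarray, e: float, ne: float = 200.0) -> float:
    """Scaled haploid Li-Stephens forward log-likelihood of ``hap`` copied from ``ref``."""
    K, m = ref.shape
    d = np.diff(gpos) / 100.0
    sw = -np.expm1(-4.0 * ne * d / K)
    sw = np.clip(sw, 1e-12, 1 - 1e-12)
    em = np.where(ref == hap[None, :], 1.0 - e, e)
    f = em[:, 0] / K
    ll = np.log(f.sum())
    f /= f.sum()
    for t in range(1, m):
        f = (1 - sw[t - 1]) * f + sw[t - 1] / K
        f = f * em[:, t]
        s = f.sum()
        ll += np.log(s)
        f /= s
    return float(ll)


def _refined_changepoint(
    pre: np.ndarray, ref: np.ndarray, gpos: np.ndarray, left: int, right: int, params: AlignParams
) -> int:
    """Most likely internal switch position of the pre-phase in (left, right].

    Scores every candidate boundary by the Li-Stephens likelihood of the
    re-oriented haplotype pair over a context window against a panel of
    other individuals' pre-phased haplotypes.
    """
    c0 = max(0, left - params.refine_context)
    c1 = min(len(gpos), right + 1 + params.refine_context)
    sub_ref = ref[:, c0:c1]
    g = gpos[c0:c1]
    best_b, best_ll = None, -np.inf
    for b in range(left + 1, right + 1):
        h0 = np.concatenate([pre[c0:b, 0], pre[b:c1, 1]])
        h1 = np.concatenate([pre[c0:b, 1], pre[b:c1, 0]])
        ll = _haploid_loglik(h0, sub_ref, g, 1e-3) + _haploid_loglik(h1, sub_ref, g, 1e-3)
        if ll > best_ll:
            best_ll, best_b = ll, b
    return best_b


def align_to_scaffold(
    dense_pre: HaplotypeSet,
    scaffold: HaplotypeSet,
    panel: MarkerPanel,
    params: AlignParams = None,
    scaffold_idx: np.ndarray = None,
    segmap: SegmentMap = None,
):
    """Align pre-phased dense haplotypes to the scaffold phase.

    ``scaffold`` is defined on the scaffold markers (``scaffold_idx`` panel
    indices, defaulting to ``panel.scaffold_indices``).  Returns
    ``(HaplotypeSet, list[OrientationPath])``: the re-oriented dense
    haplotypes (``origin_known`` inherited from the scaffold wherever an
    orientation could be assigned on every chromosome) and the per
    individual x chromosome decoded orientation paths for audit.

    Genotypes are conserved (flipping swaps a pair, never alters sums) and
    at scaffold positions the output equals the scaffold phase exactly for
    every oriented individual.
    """
    if params is None:
        params = AlignParams()
    params.validate()
    if scaffold_idx is None:
        scaffold_idx = panel.scaffold_indices
    scaffold_idx = np.asarray(scaffold_idx, dtype=np.int64)
    if scaffold.n_markers != len(scaffold_idx):
        raise ValueError("scaffold haplotypes do not match scaffold_idx")
    if scaffold.n_individuals != dense_pre.n_individuals:
        raise ValueError("scaffold and dense panels must cover the same individuals")
    if segmap is None:
        segmap = build_segment_map(panel)
    n, m = dense_pre.n_individuals, dense_pre.n_markers
    out = dense_pre.alleles.copy()
    oriented = np.ones(n, dtype=bool)
    paths = []

    seg_sizes = np.array([b - a for a, b in segmap.segment_bounds])
    small_seg = seg_sizes < params.min_segment_snps

    chrom_slices = panel.chrom_slices()
    for chrom, sl in chrom_slices.items():
        in_chrom = (scaffold_idx >= sl.start) & (scaffold_idx < sl.stop)
        sc_local = np.flatnonzero(in_chrom)  # rows of `scaffold` on this chromosome
        gpos = panel.genetic_pos
        for i in range(n):
            sa = scaffold.alleles[i]
            da = dense_pre.alleles[i]
            idx = scaffold_idx[sc_local]
            sc_het = (sa[sc_local, 0] != MISSING) & (sa[sc_local, 1] != MISSING) & (
                sa[sc_local, 0] != sa[sc_local, 1]
            )
            de_het = (da[idx, 0] != MISSING) & (da[idx, 1] != MISSING) & (da[idx, 0] != da[idx, 1])
            informative = sc_het & de_het & ~small_seg[segmap.segment_id[idx]]
            info_rows = sc_local[informative]
            info_idx = scaffold_idx[info_rows]
            path = OrientationPath(individual=i, chrom=chrom)
            if len(info_idx) == 0:
                oriented[i] = False
                warnings.warn(
                    f"individual {i} has no informative scaffold site on chromosome {chrom}; "
                    "orientation unassigned"
                )
                paths.append(path)
                continue
            match = da[info_idx, 0] == sa[info_rows, 0]
            states = _viterbi_two_state(match, gpos[info_idx], params)
            path.site_idx = info_idx
            path.evidence_match = match
            path.state = states
            paths.append(path)

            # orientation per dense marker on this chromosome
            orient = np.empty(sl.stop - sl.start, dtype=np.int8)
            orient[: info_idx[0] - sl.start + 1] = states[0]
            for s in range(len(info_idx) - 1):
                a_idx, b_idx = info_idx[s], info_idx[s + 1]
                if states[s] == states[s + 1]:
                    orient[a_idx - sl.start + 1 : b_idx - sl.start + 1] = states[s]
                else:
                    if params.refine_changepoints:
                        others = [j for j in range(n) if j != i][: params.refine_states // 2]
                        ref = np.concatenate(
                            [dense_pre.alleles[others, :, 0], dense_pre.alleles[others, :, 1]],
                            axis=0,
                        )
                        cp = _refined_changepoint(da, ref, gpos, a_idx, b_idx, params)
                    else:
                        cp = place_changepoint(segmap, gpos, a_idx, b_idx)
                    orient[a_idx - sl.start + 1 : cp - sl.start] = states[s]
                    orient[cp - sl.start : b_idx - sl.start + 1] = states[s + 1]
            orient[info_idx[-1] - sl.start + 1 :] = states[-1]

            flip = orient == FLIPPED
            block = out[i, sl]
            block[flip] = block[flip][:, ::-1]
            out[i, sl] = block
        # restore scaffold phase exactly at scaffold positions
        for i in range(n):
            if not oriented[i]:
                continue
            rows = sc_local
            ok = (scaffold.alleles[i, rows, 0] != MISSING) & (scaffold.alleles[i, rows, 1] != MISSING)
            out[i, scaffold_idx[rows[ok]]] = scaffold.alleles[i, rows[ok]]

    origin = scaffold.origin_known & oriented
    return HaplotypeSet(out, origin_known=origin), paths
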