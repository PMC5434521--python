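"""LD-only phasing by iterative conditional Li-Stephens haplotype sampling.

Each individual's genotype row is re-phased against the current haplotypes
of the other individuals (capped at ``n_states`` conditioning haplotypes)
with a diploid Li-Stephens copying model: hidden state = ordered pair of
conditioning haplotypes, Haldane-map transitions scaled by the effective
population size, symmetric allele-emission error.  A run starts from a
random consistent phase, samples pairs of mosaics during burn-in sweeps,
then takes Viterbi pairs during main sweeps and records, for every pair of
consecutive heterozygous sites, whether the two alt alleles landed on the
same haplotype; the run's phase is the per-junction majority over main
sweeps.  Because a single conditional chain mixes slowly, several
independent restarts are combined by a second junction-wise majority, and
the combined panel is polished with a few final conditional Viterbi sweeps
against the full panel.  The global paternal/maternal orientation stays
random: LD carries no parental-origin information.

Mendelian hard constraints (from :mod:`scaffoldphase.mendel`) can be
supplied; constrained heterozygous sites then admit only the
constraint-consistent allele ordering and are finally overwritten exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MISSING, GenotypeMatrix, HaplotypeSet, MarkerPanel

__all__ = ["LSParams", "ld_phase", "ls_pair_decode", "make_ld_engine"]


@dataclass
class LSParams:
    """Li-Stephens phaser settings.

    ``n_states`` caps the conditioning haplotypes per decode during
    restart sweeps (a fresh random subset each decode decorrelates the
    restarts; polish sweeps always condition on the full panel).
    ``n_burnin`` sampling sweeps precede ``n_main`` Viterbi sweeps in each
    of ``n_restarts`` independent runs; ``n_polish`` final sweeps refine
    the combined phase.  ``window_mb`` splits chromosomes into physical
    windows with 10% overlap (``None`` = whole chromosome, appropriate at
    the marker densities this package simulates).  ``mismatch_rate`` is
    the symmetric emission error; ``ne`` the effective population size
    scaling Haldane-map transitions.
    """

    n_states: int = 60
    window_mb: float = None
    n_burnin: int = 2
    n_main: int = 6
    n_restarts: int = 5
    n_polish: int = 3
    mismatch_rate: float = 1e-3
    ne: float = 200.0
    seed: int = 0

    def validate(self):
        if not (0 < self.mismatch_rate < 0.5):
            raise ValueError("mismatch_rate must be in (0, 0.5)")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.n_main < 1 or self.n_restarts < 1:
            raise ValueError("need at least one main iteration and one restart")
        if self.n_burnin < 0 or self.n_polish < 0:
            raise ValueError("iteration counts must be non-negative")
        if self.ne <= 0:
            raise ValueError("ne must be positive")


def interval_switch_probs(genetic_pos: np.ndarray, ne: float, n_haps: int) -> np.ndarray:
    """Per-interval copying-switch probability 1 - exp(-4 Ne d / K), d in Morgans."""
    d = np.diff(np.asarray(genetic_pos, dtype=float)) / 100.0
    rho = 4.0 * ne * d / max(n_haps, 1)
    return -np.expm1(-rho)


# ---------------------------------------------------------------------------
# diploid pair decode (Viterbi and forward-sampling)
# ---------------------------------------------------------------------------


def _site_mismatch_counts(g, c0, x, y):
    """Minimum per-state mismatch counts for Viterbi emission at one site.

    ``x``/``y`` are the conditioning alleles (K,), ``g`` the genotype,
    ``c0`` the constrained haplotype-0 allele (MISSING if free).
    """
    if g == 0:
        return x[:, None] + y[None, :]
    if g == 2:
        return (1 - x)[:, None] + (1 - y)[None, :]
    if g == 1:
        if c0 != MISSING:
            return (x != c0).astype(np.int8)[:, None] + (y != 1 - c0).astype(np.int8)[None, :]
        return (x[:, None] == y[None, :]).astype(np.int8)
    return np.zeros((len(x), len(y)), dtype=np.int8)  # missing genotype


def _site_emission_probs(g, c0, x, y, e):
    """Summed (not maximised) emission probabilities, for forward/sampling."""
    le = lambda a, h: np.where(h == a, 1.0 - e, e)
    if g == 0:
        return le(0, x)[:, None] * le(0, y)[None, :]
    if g == 2:
        return le(1, x)[:, None] * le(1, y)[None, :]
    if g == 1:
        if c0 != MISSING:
            return le(c0, x)[:, None] * le(1 - c0, y)[None, :]
        return le(0, x)[:, None] * le(1, y)[None, :] + le(1, x)[:, None] * le(0, y)[None, :]
    return np.ones((len(x), len(y)))


def _viterbi_pair(gt_row, ref, switch, e, constraints0=None):
    """Max-probability ordered pair of copying paths.

    Returns ``(path_j, path_k, logprob)`` where paths index rows of ``ref``.
    """
    K, m = ref.shape
    lmm = np.log(e) - np.log1p(-e)
    lconst = 2.0 * np.log1p(-e)
    c = constraints0 if constraints0 is not None else np.full(m, MISSING, dtype=np.int8)

    V = _site_mismatch_counts(gt_row[0], c[0], ref[:, 0], ref[:, 0]).astype(np.float64) * lmm
    V += lconst - 2.0 * np.log(K)
    stay1 = np.empty((m, K, K), dtype=bool)
    stay2 = np.empty((m, K, K), dtype=bool)
    amax0 = np.empty((m, K), dtype=np.int64)
    amax1 = np.empty((m, K), dtype=np.int64)
    for t in range(1, m):
        r = switch[t - 1]
        l_stay = np.log1p(-r + r / K)
        l_jump = np.log(r / K) if r > 0 else -np.inf
        col_arg = V.argmax(axis=0)
        col_max = V[col_arg, np.arange(K)]
        stay_sc = V + l_stay
        jump_sc = col_max[None, :] + l_jump
        s1 = stay_sc >= jump_sc
        M1 = np.where(s1, stay_sc, jump_sc)
        row_arg = M1.argmax(axis=1)
        row_max = M1[np.arange(K), row_arg]
        stay_sc = M1 + l_stay
        jump_sc = row_max[:, None] + l_jump
        s2 = stay_sc >= jump_sc
        V = np.where(s2, stay_sc, jump_sc)
        V += _site_mismatch_counts(gt_row[t], c[t], ref[:, t], ref[:, t]).astype(np.float64) * lmm + lconst
        stay1[t], stay2[t], amax0[t], amax1[t] = s1, s2, col_arg, row_arg
    j, k = np.unravel_index(int(V.argmax()), (K, K))
    logp = float(V[j, k])
    path_j = np.empty(m, dtype=np.int64)
    path_k = np.empty(m, dtype=np.int64)
    path_j[m - 1], path_k[m - 1] = j, k
    for t in range(m - 1, 0, -1):
        kp = k if stay2[t][j, k] else amax1[t][j]
        jp = j if stay1[t][j, kp] else amax0[t][kp]
        j, k = jp, kp
        path_j[t - 1], path_k[t - 1] = j, k
    return path_j, path_k, logp


def _forward_pair(gt_row, ref, switch, e, constraints0=None, keep=False):
    """Scaled diploid forward pass; returns (log total likelihood, stored F or None)."""
    K, m = ref.shape
    c = constraints0 if constraints0 is not None else np.full(m, MISSING, dtype=np.int8)
    F = _site_emission_probs(gt_row[0], c[0], ref[:, 0], ref[:, 0], e) / (K * K)
    loglik = 0.0
    stored = np.empty((m, K, K), dtype=np.float32) if keep else None
    s = F.sum()
    loglik += np.log(s)
    F /= s
    if keep:
        stored[0] = F
    for t in range(1, m):
        r = switch[t - 1]
        F1 = (1 - r) * F + (r / K) * F.sum(axis=0)[None, :]
        F2 = (1 - r) * F1 + (r / K) * F1.sum(axis=1)[:, None]
        F = F2 * _site_emission_probs(gt_row[t], c[t], ref[:, t], ref[:, t], e)
        s = F.sum()
        loglik += np.log(s)
        F /= s
        if keep:
            stored[t] = F
    return loglik, stored


def _sample_pair(gt_row, ref, switch, e, rng, constraints0=None):
    """Sample an ordered pair of copying paths from the posterior."""
    K, m = ref.shape
    _, F = _forward_pair(gt_row, ref, switch, e, constraints0, keep=True)
    flat = F[m - 1].ravel().astype(np.float64)
    pick = rng.choice(flat.size, p=flat / flat.sum())
    j, k = np.unravel_index(pick, (K, K))
    path_j = np.empty(m, dtype=np.int64)
    path_k = np.empty(m, dtype=np.int64)
    path_j[m - 1], path_k[m - 1] = j, k
    for t in range(m - 1, 0, -1):
        r = switch[t - 1]
        Fp = F[t - 1].astype(np.float64)
        stay = 1.0 - r
        jump = r / K
        row_j = Fp[j, :]  # j' = j, any k'
        col_k = Fp[:, k]  # any j', k' = k
        w = np.array(
            [
                stay * stay * Fp[j, k],
                stay * jump * row_j.sum(),
                jump * stay * col_k.sum(),
                jump * jump * Fp.sum(),
            ]
        )
        comp = rng.choice(4, p=w / w.sum())
        if comp == 0:
            jp, kp = j, k
        elif comp == 1:
            jp = j
            kp = rng.choice(K, p=row_j / row_j.sum())
        elif comp == 2:
            kp = k
            jp = rng.choice(K, p=col_k / col_k.sum())
        else:
            flatp = Fp.ravel()
            jp, kp = np.unravel_index(rng.choice(flatp.size, p=flatp / flatp.sum()), (K, K))
        j, k = int(jp), int(kp)
        path_j[t - 1], path_k[t - 1] = j, k
    return path_j, path_k


def _alleles_from_paths(gt_row, ref, path_j, path_k, rng, constraints0=None):
    """Read haplotype alleles off the copied reference paths.

    Returns (h0, h1, informative) where ``informative`` flags het sites at
    which the copied alleles determined the ordering (rather than a coin).
    """
    m = len(gt_row)
    x = ref[path_j, np.arange(m)]
    y = ref[path_k, np.arange(m)]
    h0 = np.empty(m, dtype=np.int8)
    h1 = np.empty(m, dtype=np.int8)
    informative = np.zeros(m, dtype=bool)
    hom = (gt_row == 0) | (gt_row == 2)
    h0[hom] = (gt_row[hom] // 2).astype(np.int8)
    h1[hom] = h0[hom]
    miss = gt_row == MISSING
    h0[miss] = x[miss]
    h1[miss] = y[miss]
    het = gt_row == 1
    c = constraints0
    if c is not None:
        fixed = het & (c != MISSING)
        h0[fixed] = c[fixed]
        h1[fixed] = 1 - c[fixed]
        informative[fixed] = True
        het = het & ~fixed
    direct = het & (x != y)
    h0[direct] = x[direct]
    h1[direct] = y[direct]
    informative[direct] = True
    amb = het & (x == y)
    if amb.any():
        coins = rng.integers(0, 2, size=int(amb.sum())).astype(np.int8)
        h0[amb] = coins
        h1[amb] = 1 - coins
    return h0, h1, informative


def ls_pair_decode(gt_row, reference: HaplotypeSet, params: LSParams, genetic_pos=None, rng=None):
    """Maximum-probability consistent haplotype pair under the diploid model.

    ``reference`` supplies the conditioning haplotypes (must be complete).
    Returns ``(h0, h1, path_posterior)`` where ``path_posterior`` is the
    Viterbi path probability normalised by the total forward likelihood.
    """
    params.validate()
    gt_row = np.asarray(gt_row, dtype=np.int8)
    ref = np.concatenate([reference.alleles[:, :, 0], reference.alleles[:, :, 1]], axis=0)
    if ref.shape[0] == 0:
        raise ValueError("reference panel is empty")
    if (ref == MISSING).any():
        raise ValueError("reference haplotypes must be complete")
    m = len(gt_row)
    if genetic_pos is None:
        genetic_pos = np.arange(m, dtype=float) * 0.05
    switch = np.clip(interval_switch_probs(genetic_pos, params.ne, ref.shape[0]), 1e-12, 1 - 1e-12)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pj, pk, logv = _viterbi_pair(gt_row, ref, switch, params.mismatch_rate)
    logz, _ = _forward_pair(gt_row, ref, switch, params.mismatch_rate)
    h0, h1, _ = _alleles_from_paths(gt_row, ref, pj, pk, rng)
    return h0, h1, float(np.exp(min(logv - logz, 0.0)))


# ---------------------------------------------------------------------------
# iterative population phasing
# ---------------------------------------------------------------------------


def _random_consistent_init(gt_vals, rng):
    n, m = gt_vals.shape
    H = np.empty((n, m, 2), dtype=np.int8)
    with np.errstate(invalid="ignore"):
        obs = np.where(gt_vals == MISSING, np.nan, gt_vals / 2.0)
        col_freq = np.nan_to_num(np.nanmean(obs, axis=0), nan=0.5)
    for i in range(n):
        g = gt_vals[i]
        hom = (g == 0) | (g == 2)
        H[i, hom, 0] = (g[hom] // 2).astype(np.int8)
        H[i, hom, 1] = H[i, hom, 0]
        het = g == 1
        coins = rng.integers(0, 2, size=int(het.sum())).astype(np.int8)
        H[i, het, 0] = coins
        H[i, het, 1] = 1 - coins
        miss = g == MISSING
        draws = (rng.random((int(miss.sum()), 2)) < col_freq[miss, None]).astype(np.int8)
        H[i, miss] = draws
    return H


def _sweep(H, gt_vals, gpos, params, constraints, rng, sample, subset_states, collect=None):
    """One conditional re-phasing sweep over all individuals, in place.

    With ``collect`` (a junction-vote accumulator) the decoded relative
    orientation of consecutive heterozygous sites is recorded.
    """
    n, m = gt_vals.shape
    e = params.mismatch_rate
    for i in rng.permutation(n):
        others = np.delete(np.arange(n), i)
        ref = np.concatenate([H[others, :, 0], H[others, :, 1]], axis=0)
        if subset_states and ref.shape[0] > params.n_states:
            pick = rng.choice(ref.shape[0], size=params.n_states, replace=False)
            ref = ref[pick]
        K = ref.shape[0]
        switch = np.clip(interval_switch_probs(gpos, params.ne, K), 1e-12, 1 - 1e-12)
        c0 = constraints[i, :, 0] if constraints is not None else None
        if sample:
            pj, pk = _sample_pair(gt_vals[i], ref, switch, e, rng, c0)
        else:
            pj, pk, _ = _viterbi_pair(gt_vals[i], ref, switch, e, c0)
        h0, h1, informative = _alleles_from_paths(gt_vals[i], ref, pj, pk, rng, c0)
        H[i, :, 0] = h0
        H[i, :, 1] = h1
        if collect is not None:
            het_idx, votes, counts = collect[i]
            if len(het_idx) > 1:
                ok = informative[het_idx[1:]] & informative[het_idx[:-1]]
                rel = h0[het_idx[1:]] != h0[het_idx[:-1]]
                votes[ok] += rel[ok]
                counts[ok] += 1


def _junction_reconstruct(gt_vals, H_template, rel_flips, het_sites, constraints, rng):
    """Rebuild a phase from per-junction majority decisions.

    ``rel_flips[i]`` says, for each consecutive het-site pair of individual
    ``i``, whether the alt allele changes haplotype.  The chain start is
    arbitrary unless constraints pin it (majority over constrained sites).
    """
    n, m = gt_vals.shape
    out = H_template.copy()
    for i in range(n):
        hs = het_sites[i]
        if len(hs) == 0:
            continue
        o = np.empty(len(hs), dtype=np.int8)
        o[0] = 0
        if len(hs) > 1:
            o[1:] = np.cumsum(rel_flips[i]) % 2
        if constraints is not None:
            c0 = constraints[i, hs, 0]
            anchored = c0 != MISSING
            if anchored.any():
                agree = int(np.sum(o[anchored] == c0[anchored]))
                if agree * 2 < int(anchored.sum()):
                    o = 1 - o
        elif rng.integers(0, 2):
            o = 1 - o
        out[i, hs, 0] = o
        out[i, hs, 1] = 1 - o
    return out


def _phase_block(gt_vals, gpos, params, constraints, rng):
    """Phase one marker block: restarts + junction majority + polish sweeps."""
    n, m = gt_vals.shape
    if n < 2:
        raise ValueError("LD phasing needs at least 2 individuals (no conditioning panel)")
    het_sites = [np.flatnonzero(gt_vals[i] == 1) for i in range(n)]

    run_rels = []  # per restart: list of per-individual junction decisions
    H_last = None
    for r in range(params.n_restarts):
        H = _random_consistent_init(gt_vals, rng)
        if constraints is not None:
            fixed = constraints[:, :, 0] != MISSING
            H[fixed] = constraints[fixed]
        collect = [
            (het_sites[i], np.zeros(max(len(het_sites[i]) - 1, 0)), np.zeros(max(len(het_sites[i]) - 1, 0)))
            for i in range(n)
        ]
        for sweep in range(params.n_burnin + params.n_main):
            is_main = sweep >= params.n_burnin
            _sweep(
                H, gt_vals, gpos, params, constraints, rng,
                sample=not is_main, subset_states=True,
                collect=collect if is_main else None,
            )
        rels = []
        for i in range(n):
            _, votes, counts = collect[i]
            rel = np.where(counts > 0, votes * 2 > counts, False)
            rels.append(rel.astype(np.int8))
        run_rels.append(rels)
        H_last = H

    # majority over restarts, junction by junction
    comb_rels = []
    for i in range(n):
        if len(het_sites[i]) < 2:
            comb_rels.append(np.zeros(0, dtype=np.int8))
            continue
        stack = np.stack([run_rels[r][i] for r in range(params.n_restarts)])
        comb_rels.append((stack.sum(axis=0) * 2 > params.n_restarts).astype(np.int8))
    H = _junction_reconstruct(gt_vals, H_last, comb_rels, het_sites, constraints, rng)

    for _ in range(params.n_polish):
        _sweep(H, gt_vals, gpos, params, constraints, rng, sample=False, subset_states=False)

    # genotype consistency and hard constraints
    g = gt_vals
    hom = (g == 0) | (g == 2)
    H[:, :, 0][hom] = (g[hom] // 2).astype(np.int8)
    H[:, :, 1][hom] = H[:, :, 0][hom]
    het = g == 1
    H[:, :, 1][het] = 1 - H[:, :, 0][het]
    if constraints is not None:
        fixed = constraints[:, :, 0] != MISSING
        H[fixed] = constraints[fixed]
    return H


def _window_spans(pos, window_mb):
    """Physical windows with 10% overlap; returns list of (start_idx, stop_idx)."""
    span = window_mb * 1e6
    step = span * 0.9
    lo = pos[0]
    spans = []
    while lo <= pos[-1]:
        hi = lo + span
        i0 = int(np.searchsorted(pos, lo, side="left"))
        i1 = int(np.searchsorted(pos, hi, side="right"))
        if i1 > i0:
            if spans and i1 == spans[-1][1]:
                break
            spans.append((i0, i1))
        lo += step
    if not spans:
        spans = [(0, len(pos))]
    spans[-1] = (spans[-1][0], len(pos))
    return spans


def ld_phase(
    gt: GenotypeMatrix,
    panel: MarkerPanel,
    params: LSParams = None,
    constraints: np.ndarray = None,
    rng=None,
) -> HaplotypeSet:
    """Phase a genotype matrix with LD information only.

    The output is genotype-consistent at every non-missing site, missing
    genotypes are imputed, and the haplotype-pair order is random with
    respect to parental origin (``origin_known`` stays False) unless
    ``constraints`` (a ``(n, m, 2)`` allele array with MISSING where free,
    as produced by Mendelian phasing) pins it.
    """
    if params is None:
        params = LSParams()
    params.validate()
    if gt.n_individuals < 2:
        raise ValueError("LD phasing needs at least 2 individuals (no conditioning panel)")
    if gt.n_markers != panel.n_markers:
        raise ValueError("genotypes and panel marker counts differ")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, m = gt.values.shape
    out = np.empty((n, m, 2), dtype=np.int8)
    for chrom, sl in panel.chrom_slices().items():
        gvals = gt.values[:, sl]
        gpos = panel.genetic_pos[sl]
        cons = constraints[:, sl] if constraints is not None else None
        if params.window_mb is None:
            out[:, sl] = _phase_block(gvals, gpos, params, cons, rng)
        else:
            spans = _window_spans(panel.pos[sl], params.window_mb)
            assembled = None
            asm_stop = 0
            for (i0, i1) in spans:
                blk = _phase_block(
                    gvals[:, i0:i1], gpos[i0:i1], params,
                    cons[:, i0:i1] if cons is not None else None, rng,
                )
                if assembled is None:
                    assembled = np.full((n, gvals.shape[1], 2), MISSING, dtype=np.int8)
                    assembled[:, i0:i1] = blk
                    asm_stop = i1
                else:
                    # stitch: flip the new window per individual to agree with
                    # the assembled phase at overlap heterozygous sites
                    ov = np.arange(i0, asm_stop)
                    full = np.full((n, gvals.shape[1], 2), MISSING, dtype=np.int8)
                    full[:, i0:i1] = blk
                    for i in range(n):
                        het = gvals[i] == 1
                        sel = ov[het[ov]]
                        if len(sel) and np.mean(assembled[i, sel, 0] != full[i, sel, 0]) > 0.5:
                            full[i, i0:i1] = full[i, i0:i1, ::-1]
                    assembled[:, asm_stop:i1] = full[:, asm_stop:i1]
                    asm_stop = i1
            out[:, sl] = assembled
    origin = np.zeros(n, dtype=bool)
    if constraints is not None:
        origin = (constraints[:, :, 0] != MISSING).any(axis=1)
    hs = HaplotypeSet(out, origin_known=origin)
    hs.check_consistent(gt)
    return hs


def make_ld_engine(panel: MarkerPanel, params: LSParams = None):
    """Adapter giving :func:`scaffoldphase.mendel.familial_plus_ld_phase` its LD engine."""
    def engine(gt: GenotypeMatrix, constraints: np.ndarray) -> HaplotypeSet:
        return ld_phase(gt, panel, params, constraints=constraints)
    return engine
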