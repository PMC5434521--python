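"""Pedigreed-population simulator with founder LD and recombination.

The generator emulates a multi-generation livestock population: founder
haplotypes are drawn with replacement from a small pool of ancestral
haplotypes (the pool size controls linkage disequilibrium — livestock
populations have small effective sizes and extensive haplotype sharing),
lightly diversified by per-marker mutation.  Gametes recombine under the
Haldane (no-interference) model: crossover counts are Poisson in the map
length in Morgans and crossover positions are uniform on the genetic scale.
A sparse scaffold panel is nested in the dense panel as an even subsample,
and optional genotyping error perturbs observed genotypes while the truth
haplotypes (with known parental origin) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import MISSING, GenotypeMatrix, HaplotypeSet, MarkerPanel, Pedigree

__all__ = ["SimConfig", "TruthSet", "simulate_founders", "simulate_meiosis", "simulate_population"]


@dataclass
class SimConfig:
    """Study conditions for the simulated population.

    Defaults describe a 3-generation pedigree of ~60 animals on one 100-Mb
    chromosome with 2,000 dense and 100 nested scaffold markers, founder LD
    from a pool of 30 ancestral haplotypes, and no genotyping error.
    """

    n_founder_haplotypes: int = 30
    n_founders: int = 20
    n_generations: int = 3  # including the founder generation
    offspring_per_mating: int = 2
    chrom_length_bp: int = 100_000_000
    n_dense_markers: int = 2000
    n_scaffold_markers: int = 100
    maf_min: float = 0.01
    genotype_error_rate: float = 0.0
    mutation_rate_per_marker: float = 0.005
    cm_per_mb: float = 1.0
    chrom: str = "1"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.maf_min < 0.5):
            raise ValueError("maf_min must be in (0, 0.5)")
        if self.n_scaffold_markers > self.n_dense_markers:
            raise ValueError("scaffold panel must nest inside the dense panel")
        for name in (
            "n_founder_haplotypes",
            "n_founders",
            "n_generations",
            "offspring_per_mating",
            "chrom_length_bp",
            "n_dense_markers",
            "n_scaffold_markers",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.genotype_error_rate < 1):
            raise ValueError("genotype_error_rate must be in [0, 1)")


@dataclass
class TruthSet:
    """True haplotypes (haplotype 0 paternal for non-founders) and crossovers.

    ``crossovers[i]`` holds two lists of genetic positions (cM): the
    crossover points of the paternal and maternal gametes that formed
    individual ``i`` (``None`` for founders).
    """

    haplotypes: HaplotypeSet
    crossovers: list
    founder_mask: np.ndarray
    sequenced: np.ndarray  # designated "sequenced subset" flags


def _draw_panel(cfg: SimConfig, rng: np.random.Generator) -> MarkerPanel:
    # draw distinct 1-based positions without materialising the whole range
    cand = np.unique(rng.integers(1, cfg.chrom_length_bp + 1, size=cfg.n_dense_markers * 2 + 16))
    while len(cand) < cfg.n_dense_markers:
        cand = np.unique(
            np.concatenate([cand, rng.integers(1, cfg.chrom_length_bp + 1, size=cfg.n_dense_markers)])
        )
    pos = np.sort(rng.choice(cand, size=cfg.n_dense_markers, replace=False))
    is_scaffold = np.zeros(cfg.n_dense_markers, dtype=bool)
    # even subsample of dense markers
    sc = np.linspace(0, cfg.n_dense_markers - 1, cfg.n_scaffold_markers).round().astype(int)
    is_scaffold[np.unique(sc)] = True
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = rng.choice(bases, size=cfg.n_dense_markers)
    alt_choice = rng.integers(1, 4, size=cfg.n_dense_markers)
    base_idx = np.searchsorted(bases, ref.astype(str))
    alt = bases[(base_idx + alt_choice) % 4]
    return MarkerPanel(
        chrom=np.array([cfg.chrom] * cfg.n_dense_markers, dtype=object),
        pos=pos,
        ref=ref,
        alt=alt,
        is_scaffold=is_scaffold,
        genetic_pos=pos / 1e6 * cfg.cm_per_mb,
    )


def _founder_pool(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Ancestral haplotype pool with all-site MAF >= maf_min within the pool."""
    npool, m = cfg.n_founder_haplotypes, cfg.n_dense_markers
    freq = rng.uniform(0.1, 0.9, size=m)
    pool = (rng.random((npool, m)) < freq).astype(np.int8)
    if npool >= 2:
        # resample monomorphic pool columns so segregation is possible
        for _ in range(50):
            mono = np.flatnonzero(pool.sum(0) % npool == 0)
            if len(mono) == 0:
                break
            pool[:, mono] = (rng.random((npool, len(mono))) < freq[mono]).astype(np.int8)
    return pool


def simulate_founders(cfg: SimConfig, rng=None, pool: np.ndarray = None) -> HaplotypeSet:
    """Draw founder haplotypes from a mutated ancestral pool.

    Founder haplotypes are sampled with replacement from the pool of
    ``n_founder_haplotypes`` ancestral haplotypes and each copy is mutated
    per marker with ``mutation_rate_per_marker``.  Sites whose resulting MAF
    falls below ``maf_min`` are resampled a bounded number of times.  An
    externally simulated ancestral pool (e.g. coalescent haplotypes) may be
    supplied via ``pool`` (shape ``(n_founder_haplotypes, n_dense_markers)``).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    external_pool = pool is not None
    if external_pool:
        pool = np.asarray(pool, dtype=np.int8).copy()
        if pool.shape != (cfg.n_founder_haplotypes, cfg.n_dense_markers):
            raise ValueError("pool shape must be (n_founder_haplotypes, n_dense_markers)")
    else:
        pool = _founder_pool(cfg, rng)
    n_haps = 2 * cfg.n_founders
    m = cfg.n_dense_markers
    for attempt in range(60):
        picks = rng.integers(0, cfg.n_founder_haplotypes, size=n_haps)
        haps = pool[picks].copy()
        if cfg.mutation_rate_per_marker > 0:
            flips = rng.random((n_haps, m)) < cfg.mutation_rate_per_marker
            haps[flips] = 1 - haps[flips]
        freq = haps.mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        low = maf < cfg.maf_min
        if not low.any() or external_pool:
            # an externally supplied pool is taken as-is (its frequencies are
            # part of the study conditions, not ours to resample)
            alleles = haps.reshape(cfg.n_founders, 2, m).transpose(0, 2, 1)
            return HaplotypeSet(alleles.astype(np.int8))
        if cfg.n_founder_haplotypes == 1 and cfg.mutation_rate_per_marker == 0:
            # degenerate single-haplotype pool: sites cannot segregate
            alleles = haps.reshape(cfg.n_founders, 2, m).transpose(0, 2, 1)
            return HaplotypeSet(alleles.astype(np.int8))
        # resample offending pool columns and retry
        freq_new = rng.uniform(0.2, 0.8, size=low.sum())
        pool[:, low] = (rng.random((cfg.n_founder_haplotypes, low.sum())) < freq_new).astype(np.int8)
    raise RuntimeError(
        "could not satisfy maf_min after bounded resampling; "
        "try a larger founder pool or lower maf_min"
    )


def simulate_meiosis(parent_haps: np.ndarray, genetic_map: np.ndarray, rng: np.random.Generator):
    """One gamete from a parent's haplotype pair under the Haldane model.

    ``parent_haps`` is (n_markers, 2); ``genetic_map`` in cM, non-decreasing.
    Returns ``(gamete, crossover_positions_cM, start_hap)``.
    """
    gmap = np.asarray(genetic_map, dtype=float)
    if np.any(np.diff(gmap) < 0):
        raise ValueError("genetic map must be non-decreasing")
    lo, hi = gmap[0], gmap[-1]
    length_morgans = (hi - lo) / 100.0
    n_xo = rng.poisson(length_morgans)
    xo = np.sort(rng.uniform(lo, hi, size=n_xo))
    start = int(rng.integers(0, 2))
    # haplotype source index per marker: start, alternating at each crossover
    n_switches_before = np.searchsorted(xo, gmap, side="left")
    source = (start + n_switches_before) % 2
    gamete = parent_haps[np.arange(len(gmap)), source]
    return gamete.astype(np.int8), xo, start


def _apply_genotype_error(gt: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip genotypes to a random *different* legal value with probability ``rate``."""
    if rate <= 0:
        return gt
    out = gt.copy()
    hit = (rng.random(out.shape) < rate) & (out != MISSING)
    draws = rng.integers(1, 3, size=hit.sum())  # offset 1 or 2 (mod 3) != 0
    out[hit] = ((out[hit] + draws) % 3).astype(np.int8)
    return out


def simulate_population(cfg: SimConfig):
    """Simulate the full pedigreed population.

    Returns ``(ped, panel, gt_dense, gt_scaffold, truth)``: pedigree, dense
    marker panel (with nested scaffold flags), observed dense and scaffold
    genotype matrices (with genotyping error applied) and the
    :class:`TruthSet` of pre-error haplotypes with parental origin.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    panel = _draw_panel(cfg, rng)
    founders = simulate_founders(cfg, rng)
    m = cfg.n_dense_markers

    ids, sires, dams, generation = [], [], [], []
    for i in range(cfg.n_founders):
        ids.append(f"F{i}")
        sires.append(-1)
        dams.append(-1)
        generation.append(0)
    alleles = [founders.alleles[i] for i in range(cfg.n_founders)]
    crossovers = [None] * cfg.n_founders

    prev_gen = list(range(cfg.n_founders))
    for g in range(1, cfg.n_generations):
        if len(prev_gen) < 2:
            raise ValueError("need at least 2 individuals per generation to mate")
        half = len(prev_gen) // 2
        perm = rng.permutation(prev_gen)
        sire_pool, dam_pool = perm[:half], perm[half : 2 * half]
        new_gen = []
        for s, d in zip(sire_pool, dam_pool):
            for _ in range(cfg.offspring_per_mating):
                pat, xo_p, _ = simulate_meiosis(alleles[s], panel.genetic_pos, rng)
                mat, xo_m, _ = simulate_meiosis(alleles[d], panel.genetic_pos, rng)
                idx = len(ids)
                ids.append(f"G{g}_{idx}")
                sires.append(int(s))
                dams.append(int(d))
                generation.append(g)
                alleles.append(np.stack([pat, mat], axis=1))
                crossovers.append((xo_p, xo_m))
                new_gen.append(idx)
        prev_gen = new_gen

    n = len(ids)
    ped = Pedigree(ids=ids, sire=np.array(sires), dam=np.array(dams))
    hap_arr = np.stack(alleles, axis=0).astype(np.int8)
    founder_mask = np.array(generation) == 0
    truth_haps = HaplotypeSet(hap_arr, origin_known=~founder_mask)
    truth_gt = truth_haps.genotypes().values

    gt_dense = GenotypeMatrix(_apply_genotype_error(truth_gt, cfg.genotype_error_rate, rng))
    sc_idx = panel.scaffold_indices
    gt_scaffold = GenotypeMatrix(gt_dense.values[:, sc_idx])

    # sequenced subset: non-founders — they have parents in the population and,
    # except for the last generation, offspring too
    sequenced = ~founder_mask
    truth = TruthSet(
        haplotypes=truth_haps,
        crossovers=crossovers,
        founder_mask=founder_mask,
        sequenced=sequenced,
    )
    return ped, panel, gt_dense, gt_scaffold, truth
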