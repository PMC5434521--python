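"""End-to-end experiments on simulated data.

The flow mirrors the two-step phasing strategy under study:

1. simulate a pedigreed population with a dense panel and nested scaffold;
2. GEN-P1: LD-only phasing of the scaffold panel;
3. GEN-P2: familial (Mendelian + half-sib linkage) phasing of the scaffold
   panel completed with LD — the scaffold;
4. WGS-P1: LD-only phasing of the dense panel (parental origin random);
5. WGS-P2: alignment of WGS-P1 onto the GEN-P2 scaffold;
6. evaluation of WGS-P1 and WGS-P2 against the Mendelian phase;
7. cross-validated imputation scaffold -> dense under both pre-phasings
   (WGS-I1 from GEN-P1/WGS-P1, WGS-I2 from GEN-P2/WGS-P2), longest-IBS
   diagnostics, and optional AHAP scaffold enrichment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import build_segment_map
from .pedsim import SimConfig, simulate_population
from .mendel import familial_plus_ld_phase, find_phasable, mendel_phase_offspring
from .ldphase import LSParams, ld_phase, make_ld_engine
from .align import AlignParams, align_to_scaffold
from .metrics import compare_phase, genome_proportion_by_length, segment_stats, switch_count
from .impute import accuracy_stats, crossval_impute, longest_ibs
from .ahap import cluster_haplotypes, enrich_scaffold, perfect_associations

__all__ = ["ExperimentConfig", "run_experiment", "ld_origin_randomness"]


def ld_origin_randomness(base_seed: int, n_replicates: int = 8, sim: SimConfig = None):
    """Mean per-animal parental-origin mismatch of an LD-only phase vs the Mendelian phase.

    LD carries no parental-origin information, so this should sit near 50%.
    The dense panel is phased with a single-pass Li-Stephens chain (one main
    iteration, no restart ensembling), which leaves a realistic density of
    phase switches per chromosome — the regime in which per-animal mismatch
    proportions concentrate around one half; the ensembled phaser leaves
    chromosomes nearly switch-free, turning each animal's proportion into a
    single 0-or-1 orientation coin whose 40-animal mean is far too noisy to
    report at desk scale.  ``n_replicates`` independent simulated
    populations (seeds derived from ``base_seed``; the first replicate is
    the base simulation itself) are averaged for Monte-Carlo precision.

    Returns ``(mean_proportion, per_replicate_list, n_animals_total)``.
    """
    from .metrics import compare_phase

    vals = []
    n_animals = 0
    base_sim = sim if sim is not None else SimConfig()
    for r in range(n_replicates):
        s = (base_seed + 9973 * r) & 0x7FFFFFFF
        cfg = SimConfig(**{**base_sim.__dict__, "seed": s})
        ped, panel, gt_dense, _gt_sc, _truth = simulate_population(cfg)
        params = LSParams(
            seed=(s * 31 + 11) & 0x7FFFFFFF,
            n_restarts=1, n_burnin=2, n_main=1, n_polish=0,
        )
        haps = ld_phase(gt_dense, panel, params)
        mendel, _ = mendel_phase_offspring(gt_dense, ped)
        mask = find_phasable(gt_dense, ped)
        cmp = compare_phase(haps, mendel, mask, panel, assume_origin=True)
        vals.append(cmp.mean_per_animal_error())
        n_animals += len(cmp.individuals())
    return float(np.mean(vals)), vals, n_animals


@dataclass
class ExperimentConfig:
    """Settings for one simulated experiment."""

    sim: SimConfig = field(default_factory=SimConfig)
    ls_sparse: LSParams = None
    ls_dense: LSParams = None
    align: AlignParams = field(default_factory=AlignParams)
    ne_impute: float = 200.0
    k_pools: int = None  # default: ~sqrt split into pools of pool_size
    pool_size: int = 5
    exclude_parents_from_training: bool = False
    do_impute: bool = True
    do_ahap: bool = True
    ahap_k: int = 50
    ahap_window: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.ls_sparse is None:
            self.ls_sparse = LSParams(seed=self.seed * 31 + 1 & 0x7FFFFFFF)
        if self.ls_dense is None:
            self.ls_dense = LSParams(seed=self.seed * 31 + 2 & 0x7FFFFFFF)


def _training_set(ped, truth, exclude_parents: bool):
    # at desk scale every simulated individual carries dense genotypes, so by
    # default the whole population forms the dense phasing panel; the
    # parents-removed split drops parents of evaluated animals instead
    sequenced = np.flatnonzero(truth.sequenced)
    if not exclude_parents:
        training = np.arange(ped.n_individuals, dtype=np.int64)
    else:
        candidates = set(sequenced.tolist())
        evaluable = [i for i in sequenced if ped.sire[i] >= 0 or ped.dam[i] >= 0]
        parents = {int(ped.sire[i]) for i in evaluable} | {int(ped.dam[i]) for i in evaluable}
        parents.discard(-1)
        training = np.array(sorted(candidates - parents), dtype=np.int64)
    evaluation = np.array(
        [i for i in training if ped.sire[i] >= 0 or ped.dam[i] >= 0], dtype=np.int64
    )
    if len(evaluation) == 0:
        raise ValueError("training split leaves no individual with a genotyped parent")
    return training, evaluation


def run_experiment(cfg: ExperimentConfig, out_dir=None) -> dict:
    """Run the full simulated experiment; optionally write the report bundle.

    Returns a dict of artifacts and summary numbers; every random stage is
    seeded from ``cfg`` so reruns are bit-identical.
    """
    ped, panel, gt_dense, gt_scaffold, truth = simulate_population(cfg.sim)
    sc_panel = panel.scaffold_panel()
    sc_idx = panel.scaffold_indices
    segmap = build_segment_map(panel)

    # --- scaffold-panel phasing (whole genotyped population) ---------------
    gen_p1 = ld_phase(gt_scaffold, sc_panel, cfg.ls_sparse)
    gen_p2 = familial_plus_ld_phase(
        gt_scaffold, ped, make_ld_engine(sc_panel, cfg.ls_sparse)
    )

    # --- dense-panel phasing (training set) --------------------------------
    training, evaluation = _training_set(ped, truth, cfg.exclude_parents_from_training)
    gt_dense_tr = gt_dense.subset_individuals(training)
    wgs_p1 = ld_phase(gt_dense_tr, panel, cfg.ls_dense)
    scaffold_tr = gen_p2.subset_individuals(training)
    wgs_p2, paths = align_to_scaffold(wgs_p1, scaffold_tr, panel, cfg.align, sc_idx, segmap)

    # --- Mendelian evaluation ---------------------------------------------
    mendel_full, _ = mendel_phase_offspring(gt_dense, ped)
    mask_full = find_phasable(gt_dense, ped)
    mendel = mendel_full.subset_individuals(training)
    from .mendel import PhasableMask

    mask = PhasableMask(mask_full.mask[training])
    eval_rows = np.isin(training, evaluation)
    mask.mask[~eval_rows] = False
    # individuals the aligner could not orient (no doubly-heterozygous
    # scaffold site, e.g. near-complete homozygosity) cannot be evaluated
    mask.mask[~wgs_p2.origin_known] = False

    cmp_p1 = compare_phase(wgs_p1, mendel, mask, panel, assume_origin=True)
    cmp_p2 = compare_phase(wgs_p2, mendel, mask, panel)

    seg_p1, seg_sum_p1 = segment_stats(cmp_p1, panel)
    seg_p2, seg_sum_p2 = segment_stats(cmp_p2, panel)
    report = {
        "ped": ped,
        "panel": panel,
        "truth": truth,
        "training": training,
        "evaluation": evaluation,
        "gen_p1": gen_p1,
        "gen_p2": gen_p2,
        "wgs_p1": wgs_p1,
        "wgs_p2": wgs_p2,
        "orientation_paths": paths,
        "mendel": mendel,
        "mask": mask,
        "cmp_p1": cmp_p1,
        "cmp_p2": cmp_p2,
        "p1_mean_per_animal_error": cmp_p1.mean_per_animal_error(),
        "p2_mean_per_animal_error": cmp_p2.mean_per_animal_error(),
        "p1_pooled_correct": cmp_p1.pooled_match(),
        "p2_pooled_correct": cmp_p2.pooled_match(),
        "switches_p1": switch_count(cmp_p1),
        "switches_p2": switch_count(cmp_p2),
        "segments_p1": seg_p1,
        "segments_p2": seg_p2,
        "genome_prop_p1": genome_proportion_by_length(seg_p1),
        "genome_prop_p2": genome_proportion_by_length(seg_p2),
    }

    # --- imputation scenarios ---------------------------------------------
    if cfg.do_impute:
        n_tr = len(training)
        pool_size = min(cfg.pool_size, max(1, n_tr // 2))
        k_pools = cfg.k_pools if cfg.k_pools is not None else n_tr // pool_size
        cv_seed = (cfg.seed * 31 + 5) & 0x7FFFFFFF
        obs_tr = gt_dense_tr
        dos_i1 = crossval_impute(
            gen_p1.subset_individuals(training), wgs_p1, panel,
            k_pools, pool_size, ne=cfg.ne_impute, seed=cv_seed, scaffold_idx=sc_idx,
        )
        dos_i2 = crossval_impute(
            gen_p2.subset_individuals(training), wgs_p2, panel,
            k_pools, pool_size, ne=cfg.ne_impute, seed=cv_seed, scaffold_idx=sc_idx,
        )
        report["acc_i1"] = accuracy_stats(dos_i1, obs_tr, panel)
        report["acc_i2"] = accuracy_stats(dos_i2, obs_tr, panel)

        # longest IBS between each target's scaffold haplotypes and the other
        # individuals' dense haplotypes restricted to scaffold markers
        ibs = {}
        for name, sparse_haps, dense_haps in [
            ("gen_p1", gen_p1.subset_individuals(training), wgs_p1),
            ("gen_p2", gen_p2.subset_individuals(training), wgs_p2),
        ]:
            vals = []
            dense_sc = dense_haps.subset_markers(sc_idx)
            for t in range(len(training)):
                others = np.setdiff1d(np.arange(len(training)), [t])
                tab = longest_ibs(
                    sparse_haps.subset_individuals([t]),
                    dense_sc.subset_individuals(others),
                    panel,
                    scaffold_idx=sc_idx,
                )
                vals.append(tab["longest_ibs_mb"].mean())
            ibs[name] = float(np.mean(vals))
        report["mean_longest_ibs_mb"] = ibs

    # --- AHAP scaffold enrichment -----------------------------------------
    if cfg.do_ahap:
        ahap = cluster_haplotypes(
            scaffold_tr, window_markers=cfg.ahap_window, k=cfg.ahap_k,
            seed=(cfg.seed * 31 + 7) & 0x7FFFFFFF,
        )
        assoc = perfect_associations(ahap, wgs_p2, panel, sc_idx)
        enriched, enriched_idx = enrich_scaffold(scaffold_tr, ahap, assoc, panel, sc_idx)
        wgs_p2e, _ = align_to_scaffold(wgs_p1, enriched, panel, cfg.align, enriched_idx, segmap)
        cmp_p2e = compare_phase(wgs_p2e, mendel, mask, panel)
        report["wgs_p2_enriched"] = wgs_p2e
        report["cmp_p2_enriched"] = cmp_p2e
        report["p2e_pooled_correct"] = cmp_p2e.pooled_match()
        report["n_enriched_markers"] = int(len(enriched_idx) - len(sc_idx))

    if out_dir is not None:
        _write_bundle(report, cfg, Path(out_dir))
    return report


def _write_bundle(report: dict, cfg: ExperimentConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for key in (
        "switches_p1", "switches_p2", "segments_p1", "segments_p2",
        "genome_prop_p1", "genome_prop_p2",
    ):
        report[key].to_csv(out / f"{key}.tsv", sep="\t", index=False)
    for scen in ("acc_i1", "acc_i2"):
        if scen in report:
            report[scen]["summary"].to_csv(out / f"{scen}_summary.tsv", sep="\t", index=False)
            report[scen]["error"].to_csv(out / f"{scen}_error.tsv", sep="\t", index=False)
    summary = {
        "p1_mean_per_animal_error": report["p1_mean_per_animal_error"],
        "p2_mean_per_animal_error": report["p2_mean_per_animal_error"],
        "p1_pooled_correct": report["p1_pooled_correct"],
        "p2_pooled_correct": report["p2_pooled_correct"],
    }
    if "acc_i1" in report:
        summary["i1_mean_r2"] = report["acc_i1"]["mean_r2"]
        summary["i2_mean_r2"] = report["acc_i2"]["mean_r2"]
        summary["mean_longest_ibs_mb"] = report["mean_longest_ibs_mb"]
    if "p2e_pooled_correct" in report:
        summary["p2e_pooled_correct"] = report["p2e_pooled_correct"]
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "sim": asdict(cfg.sim),
        "ls_sparse": asdict(cfg.ls_sparse),
        "ls_dense": asdict(cfg.ls_dense),
        "align": asdict(cfg.align),
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
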