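"""Phasing-accuracy evaluation against the Mendelian phase.

The unit of comparison is the "phasable" SNP (heterozygous in the
offspring, homozygous in >=1 genotyped parent): there the Mendelian phase
is forced, so any phasing method can be scored by matching its assigned
parental origin site by site.  Maximal runs of matches/mismatches form
correct/incorrect segments regardless of the distance between the SNPs; a
switch is a transition between segment statuses.  Singleton segments
contain exactly one phasable SNP (their physical length is 1 bp by the
last-first+1 convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MISSING, HaplotypeSet, MarkerPanel
from .mendel import PhasableMask

__all__ = [
    "PhaseComparison",
    "compare_phase",
    "switch_count",
    "segment_stats",
    "distance_to_nearest_switch",
    "genome_proportion_by_length",
]


@dataclass
class ComparisonRecord:
    individual: int
    chrom: object
    site_idx: np.ndarray  # panel indices of compared phasable SNPs, ordered
    match: np.ndarray  # bool, same length


@dataclass
class PhaseComparison:
    """Ordered match/mismatch strings per individual x chromosome."""

    records: list = field(default_factory=list)

    def individuals(self) -> list:
        return sorted({r.individual for r in self.records})

    def per_animal_error(self) -> pd.Series:
        """Mismatch proportion per individual (pooled over chromosomes)."""
        out = {}
        for i in self.individuals():
            ms = np.concatenate([r.match for r in self.records if r.individual == i])
            if len(ms):
                out[i] = float(np.mean(~ms))
        return pd.Series(out, name="error_proportion")

    def mean_per_animal_error(self) -> float:
        s = self.per_animal_error()
        return float(s.mean()) if len(s) else float("nan")

    def pooled_error(self) -> float:
        ms = np.concatenate([r.match for r in self.records]) if self.records else np.array([], bool)
        return float(np.mean(~ms)) if len(ms) else float("nan")

    def pooled_match(self) -> float:
        return 1.0 - self.pooled_error()


def compare_phase(
    test: HaplotypeSet,
    mendel: HaplotypeSet,
    mask: PhasableMask,
    panel: MarkerPanel,
    assume_origin: bool = False,
) -> PhaseComparison:
    """Match the test phase against the Mendelian phase at phasable SNPs.

    A site matches when the test's paternal (haplotype-0) allele equals the
    Mendelian paternal allele; sites missing in either phase are skipped.
    Individuals are compared only when their parental origin is assigned
    (``origin_known``); with ``assume_origin`` haplotype 0 is treated as
    paternal regardless — the convention used to quantify how *random* an
    LD-only phase is with respect to parental origin.
    """
    n, m = mask.mask.shape
    if test.n_markers != m or mendel.n_markers != m:
        raise ValueError("marker dimension mismatch")
    cmp = PhaseComparison()
    has_sites = mask.mask.any(axis=1)
    if not assume_origin:
        bad = has_sites & ~test.origin_known
        if bad.any():
            raise ValueError(
                f"individuals {np.flatnonzero(bad).tolist()} have unknown parental origin; "
                "align to a scaffold first or pass assume_origin=True"
            )
    for chrom, sl in panel.chrom_slices().items():
        for i in range(n):
            sites = np.flatnonzero(mask.mask[i, sl]) + sl.start
            if len(sites) == 0:
                continue
            ok = (
                (test.alleles[i, sites, 0] != MISSING)
                & (test.alleles[i, sites, 1] != MISSING)
                & (mendel.alleles[i, sites, 0] != MISSING)
            )
            sites = sites[ok]
            if len(sites) == 0:
                continue
            match = test.alleles[i, sites, 0] == mendel.alleles[i, sites, 0]
            cmp.records.append(ComparisonRecord(i, chrom, sites, match))
    return cmp


def switch_count(cmp: PhaseComparison) -> pd.DataFrame:
    """Switches (adjacent unequal match states) per individual and chromosome."""
    rows = [
        {
            "individual": r.individual,
            "chrom": r.chrom,
            "n_switches": int(np.sum(r.match[1:] != r.match[:-1])),
            "n_phasable": len(r.match),
        }
        for r in cmp.records
    ]
    return pd.DataFrame(rows, columns=["individual", "chrom", "n_switches", "n_phasable"])


def _runs(match: np.ndarray):
    """Run-length encode a boolean string into (status, start, stop) triples."""
    runs = []
    start = 0
    for t in range(1, len(match) + 1):
        if t == len(match) or match[t] != match[start]:
            runs.append((bool(match[start]), start, t))
            start = t
    return runs


def segment_stats(cmp: PhaseComparison, panel: MarkerPanel, filters: str = "none"):
    """Correct/incorrect segment table with optional small-segment filters.

    ``filters``: ``"none"``, ``"drop_singletons"`` (discard 1-SNP segments)
    or ``"drop_small"`` (discard segments with <5 phasable SNPs AND <5 kb).
    Dropped segments are removed and flanking same-status segments re-merge
    before summaries are recomputed.  Returns ``(table, summary)``.
    """
    if filters not in ("none", "drop_singletons", "drop_small"):
        raise ValueError(f"unknown filter {filters!r}")
    rows = []
    for r in cmp.records:
        pos = panel.pos[r.site_idx]
        segs = [(st, list(range(a, b))) for st, a, b in _runs(r.match)]
        if filters != "none":
            def keep(seg):
                st, idxs = seg
                length = int(pos[idxs[-1]] - pos[idxs[0]] + 1)
                if filters == "drop_singletons":
                    return len(idxs) > 1
                return not (len(idxs) < 5 and length < 5000)
            segs = [s for s in segs if keep(s)]
            merged = []
            for st, idxs in segs:
                if merged and merged[-1][0] == st:
                    merged[-1][1].extend(idxs)
                else:
                    merged.append((st, list(idxs)))
            segs = merged
        chrom_sl = panel.chrom_slices()[r.chrom]
        for st, idxs in segs:
            first, last = int(pos[idxs[0]]), int(pos[idxs[-1]])
            n_total = int(
                np.sum((panel.pos[chrom_sl] >= first) & (panel.pos[chrom_sl] <= last))
            )
            rows.append(
                {
                    "individual": r.individual,
                    "chrom": r.chrom,
                    "status": "correct" if st else "wrong",
                    "first_pos": first,
                    "last_pos": last,
                    "length_bp": last - first + 1,
                    "n_phasable_snps": len(idxs),
                    "n_total_snps": n_total,
                    "is_singleton": len(idxs) == 1,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "individual", "chrom", "status", "first_pos", "last_pos",
            "length_bp", "n_phasable_snps", "n_total_snps", "is_singleton",
        ],
    )
    if len(table):
        summary = (
            table.groupby("status")
            .agg(
                n_segments=("length_bp", "size"),
                mean_length_bp=("length_bp", "mean"),
                median_length_bp=("length_bp", "median"),
                max_length_bp=("length_bp", "max"),
                prop_singletons=("is_singleton", "mean"),
                mean_phasable=("n_phasable_snps", "mean"),
                median_phasable=("n_phasable_snps", "median"),
                max_phasable=("n_phasable_snps", "max"),
                mean_total=("n_total_snps", "mean"),
            )
            .reset_index()
        )
    else:
        summary = pd.DataFrame()
    return table, summary


def distance_to_nearest_switch(cmp: PhaseComparison, panel: MarkerPanel):
    """Distance (Mb) from every dense SNP to the closest phase switch.

    Switch positions are the physical midpoints between the flanking
    phasable SNPs of unequal status; on chromosomes without a switch the
    distance to the nearer chromosome end (outermost dense marker) is used,
    keeping maxima finite.  Returns ``(per_record, summary)`` where
    ``per_record`` maps (individual, chrom) -> distances array.
    """
    per_record = {}
    all_d = []
    for r in cmp.records:
        sl = panel.chrom_slices()[r.chrom]
        dense_pos = panel.pos[sl].astype(float)
        pos = panel.pos[r.site_idx].astype(float)
        sw = (pos[1:][r.match[1:] != r.match[:-1]] + pos[:-1][r.match[1:] != r.match[:-1]]) / 2.0
        if len(sw):
            d = np.min(np.abs(dense_pos[:, None] - sw[None, :]), axis=1) / 1e6
        else:
            d = np.minimum(dense_pos - dense_pos[0], dense_pos[-1] - dense_pos) / 1e6
        per_record[(r.individual, r.chrom)] = d
        all_d.append(d)
    pooled = np.concatenate(all_d) if all_d else np.array([])
    summary = pd.DataFrame(
        [
            {
                "mean_mb": float(np.mean(pooled)) if len(pooled) else np.nan,
                "median_mb": float(np.median(pooled)) if len(pooled) else np.nan,
                "max_mb": float(np.max(pooled)) if len(pooled) else np.nan,
            }
        ]
    )
    return per_record, summary


def genome_proportion_by_length(table: pd.DataFrame, classes=(1, 5, 10, 20, 50)) -> pd.DataFrame:
    """Proportion of the assayed genome in segments >= each length class (Mb).

    The denominator is the summed physical length of all segments in the
    table; proportions are reported per status and class.
    """
    total = float(table["length_bp"].sum())
    rows = []
    for c in classes:
        thresh = c * 1e6
        for status in ("correct", "wrong"):
            sel = table[(table["status"] == status) & (table["length_bp"] >= thresh)]
            rows.append(
                {
                    "min_length_mb": c,
                    "status": status,
                    "proportion": float(sel["length_bp"].sum()) / total if total > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
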