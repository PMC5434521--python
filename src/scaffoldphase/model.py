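"""Core data model and I/O shared by all phasing components.

Conventions
-----------
* Positions are 1-based base pairs, as in VCF; interval lengths in bp are
  ``last - first + 1``.
* Genotypes count alternate alleles: 0, 1, 2; missing data are encoded as
  :data:`MISSING` (-1), never as a legal dosage.
* Haplotype alleles are 0 (ref), 1 (alt) or :data:`MISSING`.  Haplotype
  index 0 is the paternal homolog whenever ``origin_known`` is set for the
  individual; otherwise the pair is defined only up to a global swap.
* Genetic positions are in cM and default to 1 cM per Mb (a standard
  cattle-scale assumption) when no genetic map is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "MarkerPanel",
    "Pedigree",
    "GenotypeMatrix",
    "HaplotypeSet",
    "SegmentMap",
    "VcfParseError",
    "read_vcf",
    "write_phased_vcf",
    "read_pedigree",
    "write_pedigree",
    "build_segment_map",
]


class VcfParseError(ValueError):
    """Raised when a VCF violates the accepted subset (biallelic SNPs, GT only)."""


# ---------------------------------------------------------------------------
# MarkerPanel
# ---------------------------------------------------------------------------


@dataclass
class MarkerPanel:
    """Ordered marker coordinates with nested sparse-in-dense membership.

    Every scaffold (sparse-panel) marker is also a dense-panel marker; the
    sparse panel is marked by ``is_scaffold``.
    """

    chrom: np.ndarray  # object array of chromosome labels
    pos: np.ndarray  # int64, 1-based bp, strictly increasing within chrom
    ref: np.ndarray  # single-character ref alleles
    alt: np.ndarray  # single-character alt alleles
    is_scaffold: np.ndarray  # bool
    genetic_pos: np.ndarray = field(default=None)  # cM, non-decreasing within chrom

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.is_scaffold = np.asarray(self.is_scaffold, dtype=bool)
        if self.genetic_pos is None:
            # default map: 1 cM / Mb
            self.genetic_pos = self.pos / 1e6
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        self.validate()

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        n = self.n_markers
        for arr, name in [
            (self.pos, "pos"),
            (self.ref, "ref"),
            (self.alt, "alt"),
            (self.is_scaffold, "is_scaffold"),
            (self.genetic_pos, "genetic_pos"),
        ]:
            if len(arr) != n:
                raise ValueError(f"MarkerPanel field {name} has length {len(arr)} != {n}")
        for sl in self.chrom_slices().values():
            if np.any(np.diff(self.pos[sl]) <= 0):
                raise ValueError("positions not strictly increasing within chromosome")
            if np.any(np.diff(self.genetic_pos[sl]) < 0):
                raise ValueError("genetic positions decreasing within chromosome")

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        seen, out = set(), []
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def chrom_slices(self) -> dict:
        """Mapping chromosome -> slice of contiguous marker indices."""
        out = {}
        start = 0
        for i in range(1, self.n_markers + 1):
            if i == self.n_markers or self.chrom[i] != self.chrom[start]:
                out[self.chrom[start]] = slice(start, i)
                start = i
        return out

    @property
    def scaffold_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_scaffold)

    def subset(self, idx) -> "MarkerPanel":
        idx = np.asarray(idx)
        return MarkerPanel(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            is_scaffold=self.is_scaffold[idx],
            genetic_pos=self.genetic_pos[idx],
        )

    def scaffold_panel(self) -> "MarkerPanel":
        """The sparse panel as a panel of its own (all markers scaffold)."""
        sub = self.subset(self.scaffold_indices)
        sub.is_scaffold[:] = True
        return sub


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """individual -> (sire, dam) links; parent index -1 means unknown.

    Individuals are stored in an order such that parents precede offspring
    (checked at construction; a cycle raises).
    """

    ids: list
    sire: np.ndarray  # int index into ids, -1 unknown
    dam: np.ndarray

    def __post_init__(self):
        self.ids = list(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(self.sire) != n or len(self.dam) != n:
            raise ValueError("sire/dam length mismatch")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual ids")
        self._check_acyclic()

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def _check_acyclic(self) -> None:
        # Kahn-style: every individual must be reachable after its parents.
        order = self.topological_order()
        if len(order) != self.n_individuals:
            raise ValueError("pedigree contains a cycle (individual is its own ancestor)")

    def topological_order(self) -> list:
        n = self.n_individuals
        placed = np.zeros(n, dtype=bool)
        order = []
        progress = True
        while progress:
            progress = False
            for i in range(n):
                if placed[i]:
                    continue
                s, d = self.sire[i], self.dam[i]
                if (s < 0 or placed[s]) and (d < 0 or placed[d]):
                    placed[i] = True
                    order.append(i)
                    progress = True
        return order

    def parents_of(self, i: int) -> tuple:
        return int(self.sire[i]), int(self.dam[i])

    def offspring_of(self, i: int) -> np.ndarray:
        return np.flatnonzero((self.sire == i) | (self.dam == i))

    def has_genotyped_parent(self) -> np.ndarray:
        """Boolean per individual: at least one parent present in the pedigree."""
        return (self.sire >= 0) | (self.dam >= 0)


def read_pedigree(path) -> Pedigree:
    """Read a 3-column whitespace pedigree (individual, sire, dam; '0' unknown)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"pedigree line needs 3 columns: {line!r}")
            rows.append(parts[:3])
    ids = [r[0] for r in rows]
    index = {iid: k for k, iid in enumerate(ids)}
    def look(tok):
        if tok == "0":
            return -1
        if tok not in index:
            raise ValueError(f"parent {tok!r} not listed as an individual")
        return index[tok]
    sire = np.array([look(r[1]) for r in rows], dtype=np.int64)
    dam = np.array([look(r[2]) for r in rows], dtype=np.int64)
    return Pedigree(ids=ids, sire=sire, dam=dam)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for i, iid in enumerate(ped.ids):
            s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else "0"
            d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else "0"
            fh.write(f"{iid}\t{s}\t{d}\n")


# ---------------------------------------------------------------------------
# GenotypeMatrix / HaplotypeSet
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """individuals x markers alt-allele counts; MISSING (-1) for no-calls."""

    values: np.ndarray  # int8 (n_ind, n_markers)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        bad = ~np.isin(self.values, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotypes must be in {0,1,2,MISSING}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def subset_markers(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values[:, idx])

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values[idx, :])


@dataclass
class HaplotypeSet:
    """Per-individual ordered haplotype pairs.

    ``alleles`` has shape (n_ind, n_markers, 2) with entries 0/1/MISSING.
    ``origin_known[i]`` means haplotype 0 is paternal and 1 maternal for
    individual ``i``; otherwise the pair order is arbitrary.
    """

    alleles: np.ndarray
    origin_known: np.ndarray = None

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_ind, n_markers, 2)")
        if self.origin_known is None:
            self.origin_known = np.zeros(self.alleles.shape[0], dtype=bool)
        self.origin_known = np.asarray(self.origin_known, dtype=bool)
        if len(self.origin_known) != self.alleles.shape[0]:
            raise ValueError("origin_known length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def genotypes(self) -> GenotypeMatrix:
        """Allele sums; MISSING wherever either allele is missing."""
        a = self.alleles
        miss = (a[:, :, 0] == MISSING) | (a[:, :, 1] == MISSING)
        g = (a[:, :, 0] + a[:, :, 1]).astype(np.int8)
        g[miss] = MISSING
        return GenotypeMatrix(g)

    def check_consistent(self, gt: GenotypeMatrix) -> None:
        """Assert allele sums match genotypes wherever both are non-missing."""
        a = self.alleles
        full = (a[:, :, 0] != MISSING) & (a[:, :, 1] != MISSING) & (gt.values != MISSING)
        sums = a[:, :, 0] + a[:, :, 1]
        if np.any(sums[full] != gt.values[full]):
            raise ValueError("haplotype allele sums disagree with genotypes")

    def swapped(self, which=None) -> "HaplotypeSet":
        """Copy with haplotype pair order swapped for ``which`` individuals (all by default)."""
        out = self.alleles.copy()
        if which is None:
            which = np.ones(self.n_individuals, dtype=bool)
        out[which] = out[which][:, :, ::-1]
        return HaplotypeSet(out, self.origin_known.copy())

    def subset_markers(self, idx) -> "HaplotypeSet":
        return HaplotypeSet(self.alleles[:, idx, :], self.origin_known.copy())

    def subset_individuals(self, idx) -> "HaplotypeSet":
        return HaplotypeSet(self.alleles[idx], self.origin_known[idx])

    def copy(self) -> "HaplotypeSet":
        return HaplotypeSet(self.alleles.copy(), self.origin_known.copy())


# ---------------------------------------------------------------------------
# SegmentMap
# ---------------------------------------------------------------------------


@dataclass
class SegmentMap:
    """Assignment of each dense marker to its nearest scaffold marker.

    ``scaffold_of`` holds, per dense marker, the panel index of the scaffold
    marker minimising the physical distance (exact midpoints break toward the
    lower-position scaffold marker).  Segments are maximal runs of dense
    markers sharing one scaffold marker; they partition the dense panel and
    there is exactly one segment per scaffold marker per chromosome.
    """

    scaffold_of: np.ndarray  # int64 per dense marker
    segment_id: np.ndarray  # int64 per dense marker, 0-based genome-wide
    segment_bounds: list  # list of (start, stop) marker-index pairs, stop exclusive

    @property
    def n_segments(self) -> int:
        return len(self.segment_bounds)


def build_segment_map(panel: MarkerPanel) -> SegmentMap:
    """Assign every dense marker to the physically closest scaffold marker.

    Raises if a chromosome carries no scaffold marker.
    """
    n = panel.n_markers
    scaffold_of = np.full(n, -1, dtype=np.int64)
    for chrom, sl in panel.chrom_slices().items():
        idx = np.arange(sl.start, sl.stop)
        sc = idx[panel.is_scaffold[sl]]
        if len(sc) == 0:
            raise ValueError(f"chromosome {chrom!r} has no scaffold marker")
        sc_pos = panel.pos[sc]
        pos = panel.pos[idx]
        # nearest scaffold marker, ties toward the lower position
        right = np.searchsorted(sc_pos, pos, side="left")
        left = np.clip(right - 1, 0, len(sc) - 1)
        right = np.clip(right, 0, len(sc) - 1)
        d_left = np.abs(pos - sc_pos[left])
        d_right = np.abs(sc_pos[right] - pos)
        choose_left = d_left <= d_right  # tie -> lower position
        scaffold_of[idx] = np.where(choose_left, sc[left], sc[right])
    # segments = runs of equal scaffold assignment
    seg_id = np.zeros(n, dtype=np.int64)
    bounds = []
    start = 0
    for i in range(1, n + 1):
        if i == n or scaffold_of[i] != scaffold_of[start] or panel.chrom[i] != panel.chrom[start]:
            bounds.append((start, i))
            seg_id[start:i] = len(bounds) - 1
            start = i
    return SegmentMap(scaffold_of=scaffold_of, segment_id=seg_id, segment_bounds=bounds)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(path, phased_required: bool = False):
    """Read a VCF with GT fields into panel + genotypes (+ haplotypes).

    Returns ``(panel, genotypes, haplotypes)``.  ``haplotypes`` is a
    :class:`HaplotypeSet` built from the phased separators and is ``None``
    when no site is phased.  Multi-allelic records are rejected.  With
    ``phased_required`` any unphased het GT raises.

    The scaffold membership flag is read from an INFO field ``SCAFFOLD``
    (flag) when present, else all markers are dense-only.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chroms, poss, refs, alts, scaff = [], [], [], [], []
    gts, haps, phased_flags = [], [], []
    any_phased = False
    for var in vcf:
        if len(var.ALT) != 1:
            raise VcfParseError(
                f"multi-allelic record at {var.CHROM}:{var.POS} rejected (ALT={var.ALT})"
            )
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        scaff.append(bool(var.INFO.get("SCAFFOLD")))
        row_g = np.empty(len(samples), dtype=np.int8)
        row_h = np.empty((len(samples), 2), dtype=np.int8)
        row_p = np.empty(len(samples), dtype=bool)
        for k, g in enumerate(var.genotypes):
            a1, a2, ph = g[0], g[1], bool(g[-1])
            a1 = MISSING if a1 < 0 else a1
            a2 = MISSING if a2 < 0 else a2
            row_h[k] = (a1, a2)
            row_g[k] = MISSING if (a1 == MISSING or a2 == MISSING) else a1 + a2
            row_p[k] = ph or a1 == a2  # homozygous/missing sites carry no phase ambiguity
            if ph:
                any_phased = True
            if phased_required and not row_p[k] and row_g[k] == 1:
                raise VcfParseError(
                    f"unphased heterozygote for sample {samples[k]} at "
                    f"{var.CHROM}:{var.POS} but phased input required"
                )
        gts.append(row_g)
        haps.append(row_h)
        phased_flags.append(row_p)
    vcf.close()
    if not poss:
        raise VcfParseError(f"no records in {path}")
    panel = MarkerPanel(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        is_scaffold=np.array(scaff, dtype=bool),
    )
    gt = GenotypeMatrix(np.array(gts, dtype=np.int8).T)
    hapset = None
    if any_phased:
        alleles = np.transpose(np.array(haps, dtype=np.int8), (1, 0, 2))
        # het sites lacking a phased separator are not phase-informative: mask them
        ph = np.array(phased_flags, dtype=bool).T
        alleles[~ph] = MISSING
        hapset = HaplotypeSet(alleles)
    return panel, gt, hapset


def write_phased_vcf(panel: MarkerPanel, haps: HaplotypeSet, path, sample_ids=None) -> None:
    """Write haplotypes as a phased VCF 4.2 (GT with '|', missing as '.').

    Haplotype order is preserved (index 0 written first).  Round-trips
    through :func:`read_vcf` bit-identically for allele content.
    """
    n_ind, n_mark = haps.n_individuals, haps.n_markers
    if n_mark != panel.n_markers:
        raise ValueError(f"panel has {panel.n_markers} markers, haplotypes {n_mark}")
    if sample_ids is None:
        sample_ids = [f"ind{i}" for i in range(n_ind)]
    if len(sample_ids) != n_ind:
        raise ValueError("sample_ids length mismatch")
    sym = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SCAFFOLD,Number=0,Type=Flag,Description="Member of the sparse scaffold panel">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if not haps.origin_known.all():
            fh.write("##phasing=haplotype order arbitrary for samples without known parental origin\n")
        for c in panel.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(map(str, sample_ids)) + "\n")
        a = haps.alleles
        for m in range(n_mark):
            info = "SCAFFOLD" if panel.is_scaffold[m] else "."
            cells = [f"{sym[int(a[i, m, 0])]}|{sym[int(a[i, m, 1])]}" for i in range(n_ind)]
            fh.write(
                f"{panel.chrom[m]}\t{panel.pos[m]}\t.\t{panel.ref[m]}\t{panel.alt[m]}\t.\t.\t{info}\tGT\t"
                + "\t".join(cells)
                + "\n"
            )
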