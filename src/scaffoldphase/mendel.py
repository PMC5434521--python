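"""Rule-based phasing from familial information.

Mendelian segregation forces the parental origin of an offspring allele at
"phasable" SNPs — sites heterozygous in the offspring and homozygous in at
least one genotyped parent.  These phases anchor the familially phased
panel and double as the evaluation truth for every phasing method.  Parents
with enough genotyped offspring are additionally phased by linkage in
(half-sib) families through a greedy minimum-recombination chaining of the
transmitted alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MISSING, GenotypeMatrix, HaplotypeSet, Pedigree

__all__ = [
    "PhasableMask",
    "find_phasable",
    "mendel_phase_offspring",
    "count_mendel_inconsistencies",
    "linkage_phase_parent",
    "familial_plus_ld_phase",
]


@dataclass
class PhasableMask:
    """Per individual x marker flag: het in the individual, homozygous in >=1 genotyped parent."""

    mask: np.ndarray  # bool (n_ind, n_markers)

    def count_per_individual(self) -> np.ndarray:
        return self.mask.sum(axis=1)


def find_phasable(gt: GenotypeMatrix, ped: Pedigree) -> PhasableMask:
    """Sites where Mendelian rules force the offspring's phase.

    Individuals without genotyped parents have empty masks.
    """
    v = gt.values
    n, m = v.shape
    if n != ped.n_individuals:
        raise ValueError("genotypes and pedigree are not aligned")
    mask = np.zeros((n, m), dtype=bool)
    het = v == 1
    for i in range(n):
        s, d = ped.parents_of(i)
        parent_homo = np.zeros(m, dtype=bool)
        if s >= 0:
            parent_homo |= (v[s] == 0) | (v[s] == 2)
        if d >= 0:
            parent_homo |= (v[d] == 0) | (v[d] == 2)
        mask[i] = het[i] & parent_homo
    return PhasableMask(mask)


def _phase_one_offspring(go, gs, gd):
    """Phase one individual's sites given parent genotype rows (None if absent).

    Returns (pat, mat, conflict) int8/bool arrays. Haplotype 0 is paternal.
    """
    m = len(go)
    pat = np.full(m, MISSING, dtype=np.int8)
    mat = np.full(m, MISSING, dtype=np.int8)
    conflict = np.zeros(m, dtype=bool)

    # opposite-homozygote conflicts (and trio-impossible het from double homo)
    for gp in (gs, gd):
        if gp is not None:
            conflict |= ((go == 0) & (gp == 2)) | ((go == 2) & (gp == 0))
    if gs is not None and gd is not None:
        both0 = (gs == 0) & (gd == 0)
        both2 = (gs == 2) & (gd == 2)
        conflict |= (go == 1) & (both0 | both2)

    homo = ((go == 0) | (go == 2)) & ~conflict
    pat[homo] = (go[homo] // 2).astype(np.int8)
    mat[homo] = pat[homo]

    het = (go == 1) & ~conflict
    if het.any():
        # allele transmitted by a homozygous parent is that parent's allele;
        # the other parent contributed the complementary allele
        if gs is not None:
            s_homo = het & ((gs == 0) | (gs == 2))
            pat[s_homo] = (gs[s_homo] // 2).astype(np.int8)
            mat[s_homo] = 1 - pat[s_homo]
        if gd is not None:
            d_homo = het & ((gd == 0) | (gd == 2))
            mat_allele = (gd[d_homo] // 2).astype(np.int8)
            # check agreement when both parents were informative
            prev = mat[d_homo]
            clash = (prev != MISSING) & (prev != mat_allele)
            mat_new = np.where(clash, MISSING, mat_allele).astype(np.int8)
            mat[d_homo] = mat_new
            pat_d = np.where(clash, MISSING, 1 - mat_allele).astype(np.int8)
            keep = pat[d_homo] == MISSING
            cur = pat[d_homo]
            cur[keep] = pat_d[keep]
            pat[d_homo] = cur
            if clash.any():
                idx = np.flatnonzero(d_homo)[clash]
                conflict[idx] = True
                pat[idx] = MISSING
                mat[idx] = MISSING
    return pat, mat, conflict


def mendel_phase_offspring(gt: GenotypeMatrix, ped: Pedigree):
    """Phase offspring by Mendelian segregation rules.

    At phasable sites the allele that the homozygous parent could not have
    transmitted is assigned to the other parent's haplotype; homozygous
    sites are phased trivially; opposite-homozygote conflicts are left
    unphased (they are data, not exceptions).  Returns
    ``(HaplotypeSet, conflict_mask)`` with haplotype 0 paternal and
    ``origin_known`` set for individuals with >=1 genotyped parent.
    """
    v = gt.values
    n, m = v.shape
    alleles = np.full((n, m, 2), MISSING, dtype=np.int8)
    conflicts = np.zeros((n, m), dtype=bool)
    origin = np.zeros(n, dtype=bool)
    for i in range(n):
        s, d = ped.parents_of(i)
        gs = v[s] if s >= 0 else None
        gd = v[d] if d >= 0 else None
        pat, mat, conf = _phase_one_offspring(v[i], gs, gd)
        alleles[i, :, 0] = pat
        alleles[i, :, 1] = mat
        conflicts[i] = conf
        origin[i] = s >= 0 or d >= 0
    return HaplotypeSet(alleles, origin_known=origin), conflicts


def count_mendel_inconsistencies(gt: GenotypeMatrix, ped: Pedigree) -> np.ndarray:
    """Per-marker count of Mendelian conflicts over all parent-offspring links.

    Counts opposite-homozygote parent-offspring pairs, plus trio-impossible
    heterozygotes when both parents are genotyped and homozygous for the
    same allele.
    """
    v = gt.values
    n, m = v.shape
    counts = np.zeros(m, dtype=np.int64)
    for i in range(n):
        s, d = ped.parents_of(i)
        for p in (s, d):
            if p >= 0:
                counts += ((v[i] == 0) & (v[p] == 2)) | ((v[i] == 2) & (v[p] == 0))
        if s >= 0 and d >= 0:
            counts += (v[i] == 1) & (
                ((v[s] == 0) & (v[d] == 0)) | ((v[s] == 2) & (v[d] == 2))
            )
    return counts


def _transmitted_alleles(v: np.ndarray, ped: Pedigree, parent: int, offspring: np.ndarray) -> np.ndarray:
    """Allele transmitted by ``parent`` to each offspring, where determinable.

    Determinable when the offspring is homozygous (transmitted allele is
    forced) or heterozygous with the *other* parent homozygous.
    Returns (n_offspring, n_markers) int8 with MISSING where unknown.
    """
    m = v.shape[1]
    out = np.full((len(offspring), m), MISSING, dtype=np.int8)
    for k, o in enumerate(offspring):
        go = v[o]
        homo = (go == 0) | (go == 2)
        out[k, homo] = (go[homo] // 2).astype(np.int8)
        other = ped.sire[o] if ped.dam[o] == parent else ped.dam[o]
        if other >= 0:
            got = v[other]
            forced = (go == 1) & ((got == 0) | (got == 2))
            out[k, forced] = (1 - got[forced] // 2).astype(np.int8)
    return out


def linkage_phase_parent(
    gt: GenotypeMatrix, ped: Pedigree, parent: int, min_offspring: int = 4
):
    """Phase a parent's heterozygous sites by linkage in its offspring.

    For every genotyped offspring the transmitted allele is deduced where
    determinable; consecutive parent-het informative sites are then chained
    to the same parental haplotype by a greedy minimum-recombination rule: a
    majority vote over offspring decides coupling vs repulsion, and a tie
    breaks the chain (the region is left unlinked).

    Returns ``(HaplotypeSet for this parent only (1 x m x 2), block_id)``
    where ``block_id`` (int per marker, -1 where unphased) labels the
    independent linkage chains; the haplotype-pair orientation is arbitrary
    within each chain and unrelated between chains.
    """
    v = gt.values
    offspring = [o for o in ped.offspring_of(parent) if (v[o] != MISSING).any()]
    m = v.shape[1]
    alleles = np.full((1, m, 2), MISSING, dtype=np.int8)
    block_id = np.full(m, -1, dtype=np.int64)
    gp = v[parent]
    homo = (gp == 0) | (gp == 2)
    alleles[0, homo, 0] = (gp[homo] // 2).astype(np.int8)
    alleles[0, homo, 1] = alleles[0, homo, 0]
    if len(offspring) < min_offspring:
        return HaplotypeSet(alleles), block_id
    trans = _transmitted_alleles(v, ped, parent, np.array(offspring))
    info_sites = np.flatnonzero(gp == 1)
    if len(info_sites) == 0:
        return HaplotypeSet(alleles), block_id
    block = 0
    prev_site = info_sites[0]
    alleles[0, prev_site] = (0, 1)  # arbitrary orientation for the chain start
    block_id[prev_site] = block
    for site in info_sites[1:]:
        x = trans[:, prev_site]
        y = trans[:, site]
        ok = (x != MISSING) & (y != MISSING)
        a = alleles[0, prev_site, 0]
        # offspring transmitted the same parental haplotype at both sites iff
        # (x == hap0(prev)) == (y == hap0(site)); vote over candidate hap0(site)=b
        same = int(np.sum((x[ok] == a) == (y[ok] == 0)))  # votes for b = 0
        diff = int(np.sum((x[ok] == a) == (y[ok] == 1)))  # votes for b = 1
        if same > diff:
            alleles[0, site] = (0, 1)
        elif diff > same:
            alleles[0, site] = (1, 0)
        else:
            block += 1  # tie: ambiguous linkage, start a new chain
            alleles[0, site] = (0, 1)
        block_id[site] = block
        prev_site = site
    return HaplotypeSet(alleles), block_id


def familial_plus_ld_phase(
    gt: GenotypeMatrix,
    ped: Pedigree,
    ld_engine,
    min_offspring: int = 4,
    use_parent_linkage: bool = True,
):
    """Complete familially anchored phasing with an LD engine.

    Mendelian/linkage-phased alleles are fixed as hard constraints; the LD
    engine (signature ``ld_engine(gt, constraints)`` returning a complete
    :class:`~scaffoldphase.model.HaplotypeSet`) fills remaining heterozygous
    sites and imputes missing genotypes.  Fixed alleles are never altered:
    the output is overwritten with the constraints and checked.

    Parent linkage chains are used only where a chain contains at least one
    Mendel-phased site, which pins the chain's absolute (paternal/maternal)
    orientation; the chain orientation is chosen by majority over those
    sites, a tie discards the chain.
    """
    mendel, _conflicts = mendel_phase_offspring(gt, ped)
    constraints = mendel.alleles.copy()
    n, m = gt.values.shape

    if use_parent_linkage:
        n_off = np.array([len(ped.offspring_of(i)) for i in range(n)])
        for p in np.flatnonzero(n_off >= min_offspring):
            link, block_id = linkage_phase_parent(gt, ped, p, min_offspring)
            for b in range(block_id.max() + 1):
                sites = np.flatnonzero(block_id == b)
                if len(sites) == 0:
                    continue
                anchored = sites[constraints[p, sites, 0] != MISSING]
                if len(anchored) == 0:
                    continue
                agree = int(np.sum(constraints[p, anchored, 0] == link.alleles[0, anchored, 0]))
                disagree = len(anchored) - agree
                if agree == disagree:
                    continue
                flip = disagree > agree
                la = link.alleles[0, sites, ::-1] if flip else link.alleles[0, sites, :]
                free = constraints[p, sites, 0] == MISSING
                constraints[p, sites[free]] = la[free]

    result = ld_engine(gt, constraints)
    fixed = constraints[:, :, 0] != MISSING
    out = result.alleles.copy()
    out[fixed] = constraints[fixed]
    hs = HaplotypeSet(out, origin_known=mendel.origin_known.copy())
    hs.check_consistent(gt)
    return hs
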