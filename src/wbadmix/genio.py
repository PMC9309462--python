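"""Genotype containers and I/O: PLINK-style .ped/.map text and VCF.

Genotypes are stored as counts of the alternate allele (0/1/2) in an
``int8`` matrix of individuals x SNPs, with :data:`MISSING` (-1) marking
missing calls.  Coordinates are 1-based inclusive internally and in
.map/VCF output; BED output elsewhere in the package is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1


class GenotypeError(ValueError):
    """Raised on malformed genotype input or invalid filter parameters."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPMap:
    """Ordered SNP map: chromosome, 1-based bp position and allele labels.

    Positions must be strictly increasing within each chromosome and SNPs
    of one chromosome must be contiguous in the array.
    """

    chrom: np.ndarray
    pos: np.ndarray
    snp_id: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=np.int64))
        object.__setattr__(self, "snp_id", np.asarray(self.snp_id, dtype=object))
        object.__setattr__(self, "ref", np.asarray(self.ref, dtype=object))
        object.__setattr__(self, "alt", np.asarray(self.alt, dtype=object))
        n = len(self.pos)
        for name in ("chrom", "snp_id", "ref", "alt"):
            if len(getattr(self, name)) != n:
                raise GenotypeError(f"SNPMap field {name!r} has wrong length")
        seen: set = set()
        last = object()
        for c in self.chrom:
            if c != last:
                if c in seen:
                    raise GenotypeError(
                        f"chromosome {c} is not contiguous in the map")
                seen.add(c)
                last = c
        for c in self.chromosomes:
            p = self.pos[self.chrom_mask(c)]
            if np.any(np.diff(p) <= 0):
                raise GenotypeError(
                    f"positions not strictly increasing on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list:
        out, last = [], object()
        for c in self.chrom:
            if c != last:
                out.append(c)
                last = c
        return out

    def chrom_mask(self, chrom) -> np.ndarray:
        return self.chrom == chrom

    def subset(self, index) -> "SNPMap":
        return SNPMap(self.chrom[index], self.pos[index], self.snp_id[index],
                      self.ref[index], self.alt[index])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos": self.pos,
                             "snp_id": self.snp_id, "ref": self.ref,
                             "alt": self.alt})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SNPMap":
        return cls(df["chrom"].to_numpy(), df["pos"].to_numpy(),
                   df["snp_id"].to_numpy(), df["ref"].to_numpy(),
                   df["alt"].to_numpy())

    def index_of(self, chrom, pos: int) -> int:
        hits = np.flatnonzero((self.chrom == chrom) & (self.pos == pos))
        if len(hits) != 1:
            raise GenotypeError(f"SNP {chrom}:{pos} not found (or duplicated)")
        return int(hits[0])


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of alternate-allele counts tied to a map."""

    ids: list
    snp_map: SNPMap
    geno: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.ids = list(self.ids)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2:
            raise GenotypeError("genotype matrix must be 2-D")
        if self.geno.shape != (len(self.ids), self.snp_map.n_snps):
            raise GenotypeError(
                f"genotype matrix shape {self.geno.shape} inconsistent with "
                f"{len(self.ids)} individuals and {self.snp_map.n_snps} SNPs")
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise GenotypeError(f"duplicated individual id(s): {dup}")
        bad = (self.geno < MISSING) | (self.geno > 2)
        if np.any(bad):
            raise GenotypeError("genotype codes must be 0/1/2 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return self.snp_map.n_snps

    def call_rates(self) -> np.ndarray:
        """Per-individual fraction of non-missing genotypes."""
        return (self.geno != MISSING).mean(axis=1)

    def snp_missing_rate(self) -> np.ndarray:
        return (self.geno == MISSING).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-SNP alternate-allele frequency over non-missing calls."""
        g = np.ma.masked_equal(self.geno, MISSING)
        p = g.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(p, dtype=float)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, index) -> "GenotypeMatrix":
        return GenotypeMatrix(self.ids, self.snp_map.subset(index),
                              self.geno[:, index])

    def subset_individuals(self, keep_ids) -> "GenotypeMatrix":
        idx = [self.ids.index(i) for i in keep_ids]
        return GenotypeMatrix(list(keep_ids), self.snp_map, self.geno[idx])


# ---------------------------------------------------------------------------
# PLINK text dialect
# ---------------------------------------------------------------------------

def write_plink(gm: GenotypeMatrix, prefix: str) -> None:
    """Write ``prefix.ped`` / ``prefix.map`` (white-space dialect, '0 0' missing)."""
    m = gm.snp_map
    with open(f"{prefix}.map", "w") as fh:
        for c, i, p in zip(m.chrom, m.snp_id, m.pos):
            fh.write(f"{c}\t{i}\t0\t{p}\n")
    # allele pair lookup per genotype code, per SNP
    with open(f"{prefix}.ped", "w") as fh:
        for ind, row in zip(gm.ids, gm.geno):
            fields = [str(ind), str(ind), "0", "0", "0", "-9"]
            for g, r, a in zip(row, m.ref, m.alt):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [str(r), str(r)]
                elif g == 1:
                    fields += [str(r), str(a)]
                else:
                    fields += [str(a), str(a)]
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix: str, snp_map: SNPMap | None = None) -> GenotypeMatrix:
    """Read ``prefix.ped`` / ``prefix.map``.

    The .ped dialect does not declare which allele is the alternate; if
    ``snp_map`` is given its ref/alt labels fix the coding (and the
    round-trip with :func:`write_plink` is exact), otherwise the counted
    allele is the first-listed minor allele at each SNP.
    """
    mdf = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos"], dtype=str)
    n_snps = len(mdf)
    ids, rows = [], []
    allele_pairs = []  # per individual: list of (a1, a2)
    with open(f"{prefix}.ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise GenotypeError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * n_snps} "
                    f"fields, found {len(parts)}")
            ind = parts[1]
            if ind in ids:
                raise GenotypeError(
                    f"{prefix}.ped line {lineno}: duplicated individual id {ind!r}")
            ids.append(ind)
            al = parts[6:]
            allele_pairs.append([(al[2 * j], al[2 * j + 1]) for j in range(n_snps)])
    if not ids:
        raise GenotypeError(f"{prefix}.ped line 1: no genotype records")

    if snp_map is not None:
        if snp_map.n_snps != n_snps:
            raise GenotypeError("provided SNPMap does not match .map SNP count")
        refs, alts = snp_map.ref, snp_map.alt
    else:
        refs, alts = _infer_alleles(allele_pairs, mdf, prefix)

    geno = np.full((len(ids), n_snps), MISSING, dtype=np.int8)
    for i, pairs in enumerate(allele_pairs):
        for j, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                continue
            for a in (a1, a2):
                if a not in (str(refs[j]), str(alts[j])):
                    raise GenotypeError(
                        f"{prefix}.ped individual {ids[i]}: unexpected allele "
                        f"{a!r} at SNP {mdf['snp_id'][j]} (site is not biallelic "
                        f"{refs[j]}/{alts[j]})")
            geno[i, j] = (a1 == str(alts[j])) + (a2 == str(alts[j]))

    if snp_map is None:
        snp_map = SNPMap(mdf["chrom"].to_numpy(),
                         mdf["pos"].astype(np.int64).to_numpy(),
                         mdf["snp_id"].to_numpy(),
                         np.asarray(refs, dtype=object),
                         np.asarray(alts, dtype=object))
    return GenotypeMatrix(ids, snp_map, geno)


def _infer_alleles(allele_pairs, mdf, prefix):
    # counted (alt) allele = first-listed minor allele at each SNP
    n_snps = len(mdf)
    refs = np.empty(n_snps, dtype=object)
    alts = np.empty(n_snps, dtype=object)
    for j in range(n_snps):
        counts: dict = {}
        order = []
        for pairs in allele_pairs:
            for a in pairs[j]:
                if a == "0":
                    continue
                if a not in counts:
                    counts[a] = 0
                    order.append(a)
                counts[a] += 1
        if len(counts) > 2:
            raise GenotypeError(
                f"{prefix}.ped: SNP {mdf['snp_id'][j]} has >2 alleles "
                f"({sorted(counts)}); multi-allelic sites are rejected")
        if not counts:  # all missing
            refs[j], alts[j] = "A", "B"
            continue
        if len(counts) == 1:
            refs[j] = order[0]
            alts[j] = "B" if order[0] != "B" else "A"
            continue
        a, b = order
        if counts[a] < counts[b] or (counts[a] == counts[b]):
            alts[j], refs[j] = a, b  # first-listed wins ties
        else:
            alts[j], refs[j] = b, a
    return refs, alts


# ---------------------------------------------------------------------------
# VCF (GT-only, via cyvcf2 for reading)
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write an uncompressed VCF 4.2 with unphased GT fields only."""
    m = gm.snp_map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=wbadmix\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in m.chromosomes:
            length = int(m.pos[m.chrom_mask(c)].max())
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(i) for i in gm.ids) + "\n")
        gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(m.n_snps):
            cols = [str(m.chrom[j]), str(m.pos[j]), str(m.snp_id[j]),
                    str(m.ref[j]), str(m.alt[j]), ".", ".", ".", "GT"]
            cols += [gt[int(g)] for g in gm.geno[:, j]]
            fh.write("\t".join(cols) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`; multi-allelic sites rejected."""
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib reports its own diagnostics
        raise GenotypeError(f"cannot parse VCF {path!r}: {exc}") from exc
    ids = list(vcf.samples)
    if len(set(ids)) != len(ids):
        raise GenotypeError(f"{path}: duplicated sample id in VCF header")
    chroms, poss, sids, refs, alts, cols = [], [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise GenotypeError(
                f"{path}: site {v.CHROM}:{v.POS} is not biallelic "
                f"(ALT={v.ALT}); multi-allelic sites are rejected")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        sids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        refs.append(v.REF)
        alts.append(v.ALT[0])
        col = np.full(len(ids), MISSING, dtype=np.int8)
        for i, (a1, a2, *_rest) in enumerate(v.genotypes):
            if a1 >= 0 and a2 >= 0:
                col[i] = a1 + a2
        cols.append(col)
    if not cols:
        raise GenotypeError(f"{path}: VCF contains no variant records")
    snp_map = SNPMap(np.asarray(chroms, dtype=object), np.asarray(poss),
                     np.asarray(sids, dtype=object),
                     np.asarray(refs, dtype=object),
                     np.asarray(alts, dtype=object))
    return GenotypeMatrix(ids, snp_map, np.column_stack(cols))


def read_genotypes(path_or_prefix: str, format: str,
                   snp_map: SNPMap | None = None) -> GenotypeMatrix:
    """Dispatch to :func:`read_plink` (``format='ped'``) or :func:`read_vcf`."""
    if format == "ped":
        return read_plink(path_or_prefix, snp_map=snp_map)
    if format == "vcf":
        return read_vcf(path_or_prefix)
    raise GenotypeError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# filtering / thinning / pruning
# ---------------------------------------------------------------------------

def _is_autosome(label) -> bool:
    try:
        int(str(label))
        return True
    except ValueError:
        return False


def filter_snps(gm: GenotypeMatrix, maf_min: float = 0.05,
                miss_max: float = 0.05,
                autosomes_only: bool = False) -> GenotypeMatrix:
    """Retain SNPs with MAF strictly > ``maf_min`` and missing fraction
    strictly < ``miss_max``; no Hardy-Weinberg filter is applied (admixture
    itself distorts HWE in the target sample)."""
    if not (0.0 <= maf_min <= 0.5):
        raise GenotypeError("maf_min must be in [0, 0.5]")
    if not (0.0 <= miss_max <= 1.0):
        raise GenotypeError("miss_max must be in [0, 1]")
    maf = gm.maf()
    maf = np.where(np.isnan(maf), 0.0, maf)  # all-missing SNP: MAF undefined -> drop
    keep = (maf > maf_min) & (gm.snp_missing_rate() < miss_max)
    if autosomes_only:
        keep &= np.array([_is_autosome(c) for c in gm.snp_map.chrom])
    if not keep.any():
        raise GenotypeError(
            "all SNPs removed by filtering; review maf_min/miss_max thresholds")
    return gm.subset_snps(np.flatnonzero(keep))


def ibs_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise mean identity-by-state over SNPs non-missing in both
    individuals: 1 - |g_i - g_j| / 2 averaged per pair."""
    g = gm.geno.astype(np.float64)
    miss = g == MISSING
    g[miss] = np.nan
    n = gm.n_individuals
    out = np.ones((n, n))
    for i in range(n):
        d = np.abs(g[i] - g[i + 1:])          # (n-i-1, M) with NaNs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ibs = 1.0 - np.nanmean(d, axis=1) / 2.0
        out[i, i + 1:] = out[i + 1:, i] = np.nan_to_num(ibs, nan=0.0)
    return out


def ibs_thin(gm: GenotypeMatrix, ibs_threshold: float) -> list:
    """Drop the lower-call-rate member of each pair with IBS above threshold.

    Pairs are processed greedily in descending IBS order (ties broken by
    individual order) so the result is deterministic; a pair both of whose
    members were already dropped through other pairs is skipped, hence the
    procedure never removes both members of a pair on account of that pair.
    """
    if not (0.0 < ibs_threshold <= 1.0):
        raise GenotypeError("ibs_threshold must be in (0, 1]")
    ibs = ibs_matrix(gm)
    cr = gm.call_rates()
    n = gm.n_individuals
    pairs = [(ibs[i, j], i, j) for i in range(n) for j in range(i + 1, n)
             if ibs[i, j] > ibs_threshold]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    removed: set = set()
    for _, i, j in pairs:
        if i in removed or j in removed:
            continue
        if cr[i] < cr[j] or (cr[i] == cr[j] and i > j):
            removed.add(i)
        else:
            removed.add(j)
    return [ind for k, ind in enumerate(gm.ids) if k not in removed]


def ld_prune(gm: GenotypeMatrix, r2_cutoff: float = 0.1,
             window: int = 50) -> GenotypeMatrix:
    """Sliding-window LD pruning: scanning left to right, a SNP is dropped
    when its squared genotype correlation with any retained SNP within the
    previous ``window`` positions exceeds ``r2_cutoff`` (all but one SNP per
    LD cluster retained).  Missing genotypes are mean-imputed for the
    correlation only."""
    if not (0.0 < r2_cutoff <= 1.0):
        raise GenotypeError("r2_cutoff must be in (0, 1]")
    g = gm.geno.astype(np.float64)
    g[g == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(g))
    g[inds] = col_mean[inds[1]]
    g -= g.mean(axis=0)
    norms = np.sqrt((g ** 2).sum(axis=0))
    norms[norms == 0] = np.inf   # monomorphic: correlation treated as 0
    z = g / norms
    kept: list[int] = []
    chrom = gm.snp_map.chrom
    for j in range(gm.n_snps):
        cand = [i for i in kept if j - i <= window and chrom[i] == chrom[j]]
        if cand:
            r = z[:, cand].T @ z[:, j]
            if np.any(r ** 2 > r2_cutoff):
                continue
        kept.append(j)
    return gm.subset_snps(np.asarray(kept, dtype=int))
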