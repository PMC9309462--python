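"""Synthetic reference panels and admixed individuals with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: three diverged source populations (wild boar, European domestic
pig, Asian domestic pig) whose SNP frequencies follow a Balding-Nichols
model around shared ancestral frequencies; admixed animals produced by
crosses and backcrosses whose haplotypes are recombinant mosaics of
single-ancestry founder haplotypes; and a Robertsonian fusion locus at
the chromosome 15/17 centromere junction whose allelic state (fused =
wild-type rob(15;17), unfused = domestic) travels with the haplotype
segment spanning the junction, so that an individual's diploid chromosome
number (2n = 36, 37 or 38) is 36 plus its number of unfused alleles.

During meiosis chromosomes 15 and 17 are treated as one linkage group on
the fused coordinate system (chromosome 17 telomere-to-centromere, then
chromosome 15), with crossovers suppressed between the junction's two
flanking SNPs - pericentromeric recombination suppression, which is also
what lets truth-based karyotype prediction from the flanking markers be
exact.  Crossover counts are Poisson(rate x length) with uniform
placement and no interference, matching the exponential-distance
transition model of the ancestry HMM.

Genotypes are emitted per SNP from the tract ancestry's panel
frequencies (one Bernoulli draw per haplotype); founder haplotypes carry
no fixed alleles of their own, since the downstream HMM consumes
unphased genotypes and panel frequencies only.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestryq import ReferencePanel
from .genio import MISSING, GenotypeMatrix, SNPMap
from .lai import LocalAncestryField

DEFAULT_LABELS = ("WB", "EUR_DP", "ASIA_DP")
WB_LABEL = "WB"
CHR17_LENGTH = 63_494_081

#: desk-scale stand-in for the pig autosomes actually analysed: chromosome
#: 17 at its true length (the junction coordinate), 15 and two more
#: autosomes at round pig-like lengths
DEFAULT_CHROM_LENGTHS = {
    "13": 208_000_000,
    "15": 140_000_000,
    "17": CHR17_LENGTH,
    "18": 56_000_000,
}

_DIVERGENCE_WARN = 0.01


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationModel:
    """Three-population divergence model over a shared SNP map.

    ``divergence`` is the per-population Fst-like Balding-Nichols
    parameter; ``ancestral_freqs`` are bounded away from 0/1 by
    ``freq_margin`` so that divergence acts symmetrically.
    """

    snp_map: SNPMap
    chrom_lengths: dict
    pop_labels: tuple = DEFAULT_LABELS
    divergence: tuple = (0.2, 0.2, 0.3)
    ancestral_freqs: np.ndarray = None
    freq_margin: float = 0.05

    def __post_init__(self):
        object.__setattr__(self, "pop_labels", tuple(self.pop_labels))
        object.__setattr__(self, "divergence", tuple(self.divergence))
        if len(self.divergence) != len(self.pop_labels):
            raise SimulationError("one divergence value per population required")
        for d in self.divergence:
            if not (0.0 < d < 1.0):
                raise SimulationError(
                    f"divergence must be strictly in (0, 1); got {d}")
        f = np.asarray(self.ancestral_freqs, dtype=np.float64)
        object.__setattr__(self, "ancestral_freqs", f)
        if f.shape != (self.snp_map.n_snps,):
            raise SimulationError("ancestral_freqs must have one value per SNP")
        m = self.freq_margin
        if np.any(f < m) or np.any(f > 1.0 - m):
            raise SimulationError(
                f"ancestral frequencies must lie in [{m}, {1 - m}]")
        for c in self.snp_map.chromosomes:
            if c not in self.chrom_lengths:
                raise SimulationError(f"no length given for chromosome {c}")
            if self.snp_map.pos[self.snp_map.chrom_mask(c)].max() > \
                    self.chrom_lengths[c]:
                raise SimulationError(f"SNP beyond chromosome {c} length")

    @property
    def n_snps(self) -> int:
        return self.snp_map.n_snps

    @property
    def wb_index(self) -> int:
        return self.pop_labels.index(WB_LABEL)

    # --- rob(15;17) geometry -------------------------------------------
    @property
    def has_fusion(self) -> bool:
        chroms = self.snp_map.chromosomes
        return "15" in chroms and "17" in chroms

    @property
    def junction(self) -> int:
        """Fused-coordinate junction = chromosome 17 length (its centromere)."""
        return self.chrom_lengths["17"]

    def _fusion_geometry(self):
        """(flank_lo, flank_hi) fused coordinates of the junction's two
        flanking SNPs; crossovers are suppressed on [flank_lo, flank_hi)."""
        j = self.junction
        pos17 = self.snp_map.pos[self.snp_map.chrom_mask("17")]
        pos15 = self.snp_map.pos[self.snp_map.chrom_mask("15")]
        lo = float(pos17.max()) if len(pos17) else float(j)
        hi = float(j + pos15.min()) if len(pos15) else float(j)
        return lo, hi


def default_snp_map(n_snps: int, chrom_lengths: dict | None = None,
                    seed=None) -> SNPMap:
    """Random SNP map with per-chromosome SNP counts proportional to length."""
    if chrom_lengths is None:
        chrom_lengths = DEFAULT_CHROM_LENGTHS
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.maximum(1, np.round(n_snps * lengths / lengths.sum()).astype(int))
    # adjust rounding drift on the largest chromosome
    counts[int(np.argmax(counts))] += n_snps - counts.sum()
    chrom_col, pos_col, id_col = [], [], []
    for c, length, k in zip(chroms, lengths, counts):
        pos = np.sort(rng.choice(np.arange(1, int(length) + 1, dtype=np.int64),
                                 size=k, replace=False))
        chrom_col += [c] * k
        pos_col.append(pos)
        id_col += [f"snp_{c}_{p}" for p in pos]
    pos_col = np.concatenate(pos_col)
    n = len(pos_col)
    return SNPMap(np.asarray(chrom_col, dtype=object), pos_col,
                  np.asarray(id_col, dtype=object),
                  np.asarray(["A"] * n, dtype=object),
                  np.asarray(["B"] * n, dtype=object))


def default_model(n_snps: int = 3000, chrom_lengths: dict | None = None,
                  divergence=(0.2, 0.2, 0.3), freq_margin: float = 0.05,
                  seed=None) -> PopulationModel:
    if chrom_lengths is None:
        chrom_lengths = DEFAULT_CHROM_LENGTHS
    rng = np.random.default_rng(seed)
    snp_map = default_snp_map(n_snps, chrom_lengths, seed=rng)
    freqs = rng.uniform(freq_margin, 1.0 - freq_margin, size=snp_map.n_snps)
    return PopulationModel(snp_map=snp_map, chrom_lengths=dict(chrom_lengths),
                           divergence=tuple(divergence),
                           ancestral_freqs=freqs, freq_margin=freq_margin)


# ---------------------------------------------------------------------------
# reference panels (Balding-Nichols)
# ---------------------------------------------------------------------------

def generate_reference_panels(model: PopulationModel, panel_sizes,
                              seed=None):
    """Draw per-population frequencies and panel genotypes.

    For population k with divergence F_k, per-SNP frequencies are
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p
    (Balding-Nichols); panel genotypes are binomial(2, freq) draws.
    Returns the :class:`ReferencePanel` of true population frequencies
    (clamped with eps = 1/(2n_k+2)) and one genotype matrix per
    population.
    """
    rng = np.random.default_rng(seed)
    sizes = dict(zip(model.pop_labels, panel_sizes)) \
        if not isinstance(panel_sizes, dict) else dict(panel_sizes)
    for label in model.pop_labels:
        if sizes.get(label, 0) < 1:
            raise SimulationError(
                f"panel size for population {label!r} must be >= 1 "
                f"(got {sizes.get(label, 0)})")
    if all(d < _DIVERGENCE_WARN for d in model.divergence):
        warnings.warn(
            "all divergence parameters are near zero: population frequencies "
            "collapse onto the ancestral frequencies and ancestry is weakly "
            "identifiable", stacklevel=2)
    p = model.ancestral_freqs
    freq_rows, matrices = [], {}
    for label, F in zip(model.pop_labels, model.divergence):
        scale = (1.0 - F) / F
        fk = rng.beta(p * scale, (1.0 - p) * scale)
        n_k = sizes[label]
        geno = rng.binomial(2, fk, size=(n_k, model.n_snps)).astype(np.int8)
        ids = [f"{label}_{i:03d}" for i in range(n_k)]
        matrices[label] = GenotypeMatrix(ids, model.snp_map, geno)
        eps = 1.0 / (2 * n_k + 2)
        freq_rows.append(np.clip(fk, eps, 1.0 - eps))
    panel = ReferencePanel(model.pop_labels, np.vstack(freq_rows),
                           model.snp_map)
    return panel, matrices


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------

@dataclass
class SimulatedIndividual:
    """Simulated animal with genotypes and per-haplotype ancestry truth.

    ``tracts`` maps, per haplotype, chromosome -> [(start, end, ancestry
    index)] tiling [1, chrom_length] (1-based inclusive).  ``fused``
    records per haplotype whether it carries the fused rob(15;17)
    centromere allele; the karyotype is 36 + number of unfused alleles.
    ``pedigree_depth`` counts generations since the last pure domestic
    founder (None for an all-wild pedigree).
    """

    id: str
    genotypes: np.ndarray = field(repr=False)
    tracts: tuple            # (hap0 dict, hap1 dict)
    fused: tuple             # (bool, bool)
    pedigree_depth: int | None = None

    @property
    def karyotype(self) -> int:
        return 36 + sum(0 if f else 1 for f in self.fused)

    def tract_table(self, labels=DEFAULT_LABELS) -> pd.DataFrame:
        rows = []
        for hap in (0, 1):
            for chrom, segs in self.tracts[hap].items():
                for s, e, a in segs:
                    rows.append((self.id, hap, chrom, s, e, labels[a]))
        return pd.DataFrame(rows, columns=["individual", "haplotype", "chrom",
                                           "start", "end", "ancestry"])

    def global_ancestry(self, model: PopulationModel) -> np.ndarray:
        """Tract-length-weighted ancestry fractions (sum to 1)."""
        K = len(model.pop_labels)
        w = np.zeros(K)
        for hap in (0, 1):
            for segs in self.tracts[hap].values():
                for s, e, a in segs:
                    w[a] += e - s + 1
        return w / w.sum()


def _founder_tracts(model: PopulationModel, anc: int):
    return {c: [(1, int(model.chrom_lengths[c]), anc)]
            for c in model.snp_map.chromosomes}


def _ancestry_per_snp(tracts_one_hap: dict, snp_map: SNPMap) -> np.ndarray:
    anc = np.empty(snp_map.n_snps, dtype=np.int8)
    for chrom, segs in tracts_one_hap.items():
        mask = snp_map.chrom_mask(chrom)
        pos = snp_map.pos[mask]
        idx = np.flatnonzero(mask)
        ends = np.array([e for _, e, _ in segs])
        labels = np.array([a for _, _, a in segs], dtype=np.int8)
        anc[idx] = labels[np.searchsorted(ends, pos, side="left")]
    return anc


def _sample_genotypes(tracts, model: PopulationModel,
                      freqs: np.ndarray, rng) -> np.ndarray:
    m = model.n_snps
    cols = np.arange(m)
    g = np.zeros(m, dtype=np.int8)
    for hap in (0, 1):
        anc = _ancestry_per_snp(tracts[hap], model.snp_map)
        g += (rng.random(m) < freqs[anc, cols]).astype(np.int8)
    return g


def make_founder(model: PopulationModel, label: str, panel: ReferencePanel,
                 rng, ind_id: str | None = None) -> SimulatedIndividual:
    anc = model.pop_labels.index(label)
    tracts = (_founder_tracts(model, anc), _founder_tracts(model, anc))
    fused = label == WB_LABEL
    g = _sample_genotypes(tracts, model, panel.freqs, rng)
    return SimulatedIndividual(
        id=ind_id or f"{label}_founder",
        genotypes=g, tracts=tracts, fused=(fused, fused),
        pedigree_depth=None if label == WB_LABEL else 0)


# ---------------------------------------------------------------------------
# karyotype transmission (junction locus only)
# ---------------------------------------------------------------------------

_P_FUSED = {36: 1.0, 37: 0.5, 38: 0.0}


def transmit_karyotype(kA: int, kB: int, seed=None, size=None):
    """Offspring diploid chromosome number(s) under Mendelian segregation
    of the rob(15;17) fusion: a 2n=36 parent always transmits the fused
    allele, 2n=38 never, 2n=37 with probability 1/2; the offspring
    karyotype is 36 plus its number of unfused alleles."""
    for k in (kA, kB):
        if k not in _P_FUSED:
            raise SimulationError(f"karyotype must be 36, 37 or 38; got {k}")
    rng = np.random.default_rng(seed)
    n = 1 if size is None else int(size)
    unfused = (rng.random(n) >= _P_FUSED[kA]).astype(int) \
        + (rng.random(n) >= _P_FUSED[kB]).astype(int)
    out = 36 + unfused
    return int(out[0]) if size is None else out


# ---------------------------------------------------------------------------
# meiosis and crosses
# ---------------------------------------------------------------------------

@dataclass
class CrossSpec:
    parentA: object          # SimulatedIndividual or population label
    parentB: object
    recomb_rate: float = 1e-8     # crossovers per bp per meiosis
    n_offspring: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.recomb_rate < 0:
            raise SimulationError("recomb_rate must be >= 0")
        if self.n_offspring < 1:
            raise SimulationError("n_offspring must be >= 1")


def _linkage_groups(model: PopulationModel):
    """[(spans, total length, junction info)] with spans = [(chrom,
    offset, length)].

    Chromosomes 17 and 15 form one fused group (17 first, chr15 offset by
    the chr17 length); junction info = (junction bp, suppression window)
    or None for ordinary chromosomes.
    """
    groups = []
    chroms = model.snp_map.chromosomes
    if model.has_fusion:
        j = model.junction
        l15 = int(model.chrom_lengths["15"])
        groups.append(([("17", 0, j), ("15", j, l15)], j + l15,
                       (float(j), model._fusion_geometry())))
        rest = [c for c in chroms if c not in ("15", "17")]
    else:
        rest = list(chroms)
    for c in rest:
        length = int(model.chrom_lengths[c])
        groups.append(([(c, 0, length)], length, None))
    return groups


def _merge_segs(segs):
    out = [segs[0]]
    for s, e, a in segs[1:]:
        ps, pe, pa = out[-1]
        if a == pa and s == pe + 1:
            out[-1] = (ps, e, a)
        else:
            out.append((s, e, a))
    return out


def _gamete_group(parent: SimulatedIndividual, spans, total_len,
                  junction_info, recomb_rate, rng):
    """One recombinant haplotype for one linkage group.

    ``spans`` = [(chrom, offset, length)] in group order.  Returns
    (tracts per chromosome, fused allele or None).
    """
    # parental haplotypes in group coordinates
    haps = []
    for hap in (0, 1):
        segs = []
        for c, off, _len in spans:
            segs += [(s + off, e + off, a) for s, e, a in parent.tracts[hap][c]]
        haps.append(segs)
    n_x = rng.poisson(recomb_rate * total_len)
    xs = np.sort(rng.uniform(0.0, total_len, size=n_x))
    if junction_info is not None:
        lo, hi = junction_info[1]
        xs = xs[(xs < lo) | (xs >= hi)]   # pericentromeric suppression
    breaks = sorted({int(np.floor(x)) for x in xs
                     if 1 <= int(np.floor(x)) < total_len})
    h0 = int(rng.integers(2))
    bounds = [0] + breaks + [total_len]
    out = []
    fused = None
    for i in range(len(bounds) - 1):
        lo_b, hi_b = bounds[i] + 1, bounds[i + 1]
        src = haps[(h0 + i) % 2]
        for s, e, a in src:
            if e < lo_b or s > hi_b:
                continue
            out.append((max(s, lo_b), min(e, hi_b), a))
        if junction_info is not None:
            j = junction_info[0]
            if lo_b <= j <= hi_b:   # segment whose last bp reaches the junction
                fused = parent.fused[(h0 + i) % 2]
    out = _merge_segs(sorted(out))
    # back to per-chromosome coordinates
    per_chrom = {}
    for c, off, length in spans:
        segs = [(max(s, off + 1) - off, min(e, off + length) - off, a)
                for s, e, a in out if e > off and s <= off + length]
        per_chrom[c] = _merge_segs(segs)
    return per_chrom, fused


def _make_gamete(parent: SimulatedIndividual, model: PopulationModel, rng,
                 recomb_rate: float):
    tracts = {}
    fused = None
    for spans, total, jinfo in _linkage_groups(model):
        per_chrom, f = _gamete_group(parent, spans, total,
                                     jinfo, recomb_rate, rng)
        tracts.update(per_chrom)
        if f is not None:
            fused = f
    if fused is None:   # map without the 15/17 pair: unlinked transmission
        fused = parent.fused[int(rng.integers(2))]
    return tracts, fused


def _resolve_parent(p, model, panel, rng):
    if isinstance(p, SimulatedIndividual):
        if set(p.tracts[0]) != set(model.snp_map.chromosomes) or \
                len(p.genotypes) != model.n_snps:
            raise SimulationError(
                f"parent {p.id!r} has a SNP map incompatible with the model")
        return p
    if p in model.pop_labels:
        return make_founder(model, p, panel, rng)
    raise SimulationError(f"unknown parent {p!r}")


def _child_depth(a: SimulatedIndividual, b: SimulatedIndividual):
    depths = [d for d in (a.pedigree_depth, b.pedigree_depth) if d is not None]
    return (min(depths) + 1) if depths else None


def simulate_cross(spec: CrossSpec, model: PopulationModel,
                   panel: ReferencePanel, seed=None,
                   missing_rate: float = 0.0, id_prefix: str = "off"
                   ) -> list:
    """Offspring of one mating: per linkage group, each parent contributes
    a recombinant gamete haplotype (Poisson crossovers, uniform placement);
    ancestry tracts and the fusion allele travel with the transmitted
    segments, and genotypes are re-sampled from tract ancestry panel
    frequencies."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    pa = _resolve_parent(spec.parentA, model, panel, rng)
    pb = _resolve_parent(spec.parentB, model, panel, rng)
    out = []
    for i in range(spec.n_offspring):
        ta, fa = _make_gamete(pa, model, rng, spec.recomb_rate)
        tb, fb = _make_gamete(pb, model, rng, spec.recomb_rate)
        tracts = (ta, tb)
        g = _sample_genotypes(tracts, model, panel.freqs, rng)
        if missing_rate > 0:
            g[rng.random(model.n_snps) < missing_rate] = MISSING
        out.append(SimulatedIndividual(
            id=f"{id_prefix}_{i:04d}", genotypes=g, tracts=tracts,
            fused=(fa, fb), pedigree_depth=_child_depth(pa, pb)))
    return out


def simulate_backcross_lineage(model: PopulationModel, panel: ReferencePanel,
                               depth: int, rng, dp_label: str = "EUR_DP",
                               recomb_rate: float = 1e-8,
                               missing_rate: float = 0.0,
                               ind_id: str = "bc") -> SimulatedIndividual:
    """F1 (wild x domestic) backcrossed to fresh wild-boar mates.

    ``depth`` = pedigree depth of the returned animal: 1 is the F1 itself,
    d > 1 is the F1 followed by d-1 wild backcrosses; its expected
    domestic fraction is 2**-depth.
    """
    if depth < 1:
        raise SimulationError("depth must be >= 1")
    spec = CrossSpec(WB_LABEL, dp_label, recomb_rate=recomb_rate)
    child = simulate_cross(spec, model, panel, seed=rng, id_prefix=ind_id)[0]
    for _ in range(depth - 1):
        spec = CrossSpec(child, WB_LABEL, recomb_rate=recomb_rate)
        child = simulate_cross(spec, model, panel, seed=rng,
                               id_prefix=ind_id)[0]
    if missing_rate > 0:
        g = child.genotypes.copy()
        g[rng.random(model.n_snps) < missing_rate] = MISSING
        child.genotypes = g
    child.id = ind_id
    return child


def simulate_admixed_cohort(model: PopulationModel, panel: ReferencePanel,
                            n: int, seed=None, pure_fraction: float = 0.4,
                            f1_fraction: float = 0.0,
                            depth_range: tuple = (2, 8),
                            asia_fraction: float = 0.1,
                            recomb_rate: float = 1e-8,
                            missing_rate: float = 0.02) -> list:
    """Cohort mixing unadmixed wild boar with backcrossed hybrids.

    Defaults target the structure reported for French wild boar: about
    40% unadmixed animals, the rest carrying domestic tracts from
    hybridizations 2-8 generations back (genome-wide wild ancestry around
    95%), domestic contributions mostly European with a minority Asian
    component, and 2% missing genotypes.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        u = rng.random()
        iid = f"ind_{i:04d}"
        if u < f1_fraction:
            dp = "ASIA_DP" if rng.random() < asia_fraction else "EUR_DP"
            ind = simulate_backcross_lineage(model, panel, 1, rng, dp,
                                             recomb_rate, 0.0, iid)
        elif u < f1_fraction + pure_fraction:
            ind = make_founder(model, WB_LABEL, panel, rng, iid)
        else:
            depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
            dp = "ASIA_DP" if rng.random() < asia_fraction else "EUR_DP"
            ind = simulate_backcross_lineage(model, panel, depth, rng, dp,
                                             recomb_rate, 0.0, iid)
        if missing_rate > 0:
            g = ind.genotypes.copy()
            g[rng.random(model.n_snps) < missing_rate] = MISSING
            ind.genotypes = g
        out.append(ind)
    return out


def simulate_karyotype_cohort(model: PopulationModel, panel: ReferencePanel,
                              n: int, seed=None,
                              depth_range: tuple = (2, 12),
                              missing_rate: float = 0.0) -> list:
    """Cohort for benchmarking in-silico karyotype prediction.

    Mirrors a monitoring sample enriched for cytogenetic hybrids: 30%
    unadmixed wild boar, 10% F1, 25% F2 (the only recent class segregating
    all three karyotypes), and 35% wild-boar backcrosses 2-12 generations
    deep, whose shortened domestic junction haplotypes make the
    heterozygous 2n=37 class the hard one.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        u = rng.random()
        iid = f"ind_{i:04d}"
        if u < 0.30:
            ind = make_founder(model, WB_LABEL, panel, rng, iid)
        elif u < 0.40:
            ind = simulate_backcross_lineage(model, panel, 1, rng,
                                             ind_id=iid)
        elif u < 0.65:
            f1a = simulate_backcross_lineage(model, panel, 1, rng)
            f1b = simulate_backcross_lineage(model, panel, 1, rng)
            ind = simulate_cross(CrossSpec(f1a, f1b), model, panel,
                                 seed=rng)[0]
            ind.id = iid
        else:
            depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
            ind = simulate_backcross_lineage(model, panel, depth, rng,
                                             ind_id=iid)
        if missing_rate > 0:
            g = ind.genotypes.copy()
            g[rng.random(model.n_snps) < missing_rate] = MISSING
            ind.genotypes = g
        out.append(ind)
    return out


# ---------------------------------------------------------------------------
# targeted introgression
# ---------------------------------------------------------------------------

def _overwrite_interval(segs, start, end, anc):
    out = []
    for s, e, a in segs:
        if e < start or s > end:
            out.append((s, e, a))
            continue
        if s < start:
            out.append((s, start - 1, a))
        if e > end:
            out.append((end + 1, e, a))
    out.append((start, end, anc))
    return _merge_segs(sorted(out))


def inject_introgression(population: list, interval, target_dp_dosage: float,
                         model: PopulationModel, panel: ReferencePanel,
                         seed=None, dp_label: str = "EUR_DP") -> list:
    """Overwrite ancestry to domestic inside one interval, creating a
    localized introgression signal of known strength.

    Each haplotype of each individual is switched to ``dp_label`` over
    ``interval`` = (chrom, start, end) with probability
    ``target_dp_dosage / 2``; genotypes inside the interval are
    re-sampled and truth records updated.  Returns modified copies.
    """
    chrom, start, end = interval
    if not (0.0 <= target_dp_dosage <= 2.0):
        raise SimulationError("target_dp_dosage must be in [0, 2]")
    if chrom not in model.snp_map.chromosomes:
        raise SimulationError(f"interval chromosome {chrom!r} not in the map")
    if start < 1 or end > model.chrom_lengths[chrom] or end < start:
        raise SimulationError("interval outside the chromosome bounds")
    mask = model.snp_map.chrom_mask(chrom) & (model.snp_map.pos >= start) \
        & (model.snp_map.pos <= end)
    if mask.sum() < 2:
        raise SimulationError("interval must cover at least 2 SNPs")
    if target_dp_dosage == 0.0:
        return population
    rng = np.random.default_rng(seed)
    anc = model.pop_labels.index(dp_label)
    snp_idx = np.flatnonzero(mask)
    covers_junction = model.has_fusion and chrom == "17" \
        and end >= model.chrom_lengths["17"]
    out = []
    for ind in population:
        ind = copy.deepcopy(ind)
        changed = False
        for hap in (0, 1):
            if rng.random() < target_dp_dosage / 2.0:
                ind.tracts[hap][chrom] = _overwrite_interval(
                    ind.tracts[hap][chrom], start, end, anc)
                changed = True
        if changed:
            g = ind.genotypes.copy()
            fresh = _sample_genotypes(ind.tracts, model, panel.freqs, rng)
            g[snp_idx] = fresh[snp_idx]
            ind.genotypes = g
            if covers_junction:
                fused = tuple(
                    _ancestry_per_snp(ind.tracts[h], model.snp_map)[snp_idx[-1]]
                    == model.wb_index for h in (0, 1))
                ind.fused = fused
        out.append(ind)
    return out


# ---------------------------------------------------------------------------
# truth extraction and output
# ---------------------------------------------------------------------------

def genotype_matrix(population: list, model: PopulationModel
                    ) -> GenotypeMatrix:
    return GenotypeMatrix([ind.id for ind in population], model.snp_map,
                          np.vstack([ind.genotypes for ind in population]))


def truth_dosages(population: list, model: PopulationModel
                  ) -> LocalAncestryField:
    """Exact per-SNP ancestry dosages from the simulated tracts."""
    K = len(model.pop_labels)
    N, M = len(population), model.n_snps
    d = np.zeros((N, M, K))
    cols = np.arange(M)
    for i, ind in enumerate(population):
        for hap in (0, 1):
            anc = _ancestry_per_snp(ind.tracts[hap], model.snp_map)
            d[i, cols, anc] += 1.0
    return LocalAncestryField(ids=[ind.id for ind in population],
                              labels=model.pop_labels,
                              snp_map=model.snp_map, dosages=d)


def mask_missing(gm: GenotypeMatrix, rate: float = 0.02,
                 seed=None) -> GenotypeMatrix:
    """I.i.d. missing-genotype masking (default 2%, well under the 10%
    per-SNP cap the filters enforce)."""
    if not (0.0 <= rate < 1.0):
        raise SimulationError("missing rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    g = gm.geno.copy()
    g[rng.random(g.shape) < rate] = MISSING
    return GenotypeMatrix(gm.ids, gm.snp_map, g)


def write_truth_tracts(population: list, path: str,
                       labels=DEFAULT_LABELS, seed=None) -> None:
    """Tab-separated truth tracts (1-based inclusive)."""
    df = pd.concat([ind.tract_table(labels) for ind in population],
                   ignore_index=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_truth_karyotypes(population: list, path: str, seed=None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("individual\tkaryotype\n")
        for ind in population:
            fh.write(f"{ind.id}\t{ind.karyotype}\n")
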