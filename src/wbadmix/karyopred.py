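"""In-silico rob(15;17) map fusion and karyotype prediction.

Chromosome maps are fused at their centromeres: chromosome 17 keeps its
coordinates (telomere to centromere, total length 63,494,081 bp) and
chromosome 15 is offset by that length, so the first nucleotide of the
q-arm is 63,494,081 + 1.  An animal's diploid chromosome number is then
read off the local-ancestry dosages of the SNPs flanking the junction:
both junction alleles of wild-boar ancestry -> 2n = 36, exactly one of
domestic ancestry -> 2n = 37, both domestic -> 2n = 38.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import SNPMap
from .lai import LocalAncestryField

CHR17_LENGTH = 63_494_081


class KaryotypeError(ValueError):
    pass


@dataclass(frozen=True)
class FusedMap:
    """SNPs ordered along the fused rob(15;17) coordinate system."""

    table: pd.DataFrame = field(repr=False)   # fused_pos, chrom, pos, snp_id
    junction: int

    def left_flank(self, window: int = 1) -> pd.DataFrame:
        """The ``window`` SNPs nearest the junction on the chr17 side."""
        left = self.table[self.table["fused_pos"] <= self.junction]
        if left.empty:
            raise KaryotypeError("no SNP on the chromosome-17 side of the "
                                 "junction")
        return left.tail(window)

    def right_flank(self, window: int = 1) -> pd.DataFrame:
        right = self.table[self.table["fused_pos"] > self.junction]
        if right.empty:
            raise KaryotypeError("no SNP on the chromosome-15 side of the "
                                 "junction")
        return right.head(window)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fuse_map(map15: SNPMap, map17: SNPMap,
             chr17_length: int = CHR17_LENGTH) -> FusedMap:
    """Fuse single-chromosome maps at their centromeres.

    Chromosome 17 SNPs keep their positions; chromosome 15 SNPs are
    shifted by ``chr17_length`` (chromosome 15 position 1 becomes fused
    position ``chr17_length`` + 1); the junction is recorded at
    ``chr17_length``.
    """
    for m, name in ((map15, "map15"), (map17, "map17")):
        if len(m.chromosomes) != 1:
            raise KaryotypeError(f"{name} must contain a single chromosome")
    if map17.pos.max() > chr17_length:
        raise KaryotypeError(
            "chromosome 17 SNP positions exceed the stated chromosome "
            f"length {chr17_length}; fused positions would overlap")
    rows = []
    for m, shift in ((map17, 0), (map15, chr17_length)):
        for c, p, i in zip(m.chrom, m.pos, m.snp_id):
            rows.append((int(p) + shift, c, int(p), i))
    table = pd.DataFrame(rows, columns=["fused_pos", "chrom", "pos", "snp_id"])
    if table["fused_pos"].duplicated().any():
        raise KaryotypeError("overlapping fused positions")
    return FusedMap(table=table, junction=int(chr17_length))


def fuse_from_map(snp_map: SNPMap, chr15="15", chr17="17",
                  chr17_length: int = CHR17_LENGTH) -> FusedMap:
    """Convenience: extract chromosomes 15 and 17 from a genome map and fuse."""
    m15 = snp_map.subset(np.flatnonzero(snp_map.chrom_mask(chr15)))
    m17 = snp_map.subset(np.flatnonzero(snp_map.chrom_mask(chr17)))
    if m15.n_snps == 0 or m17.n_snps == 0:
        raise KaryotypeError("map lacks SNPs on chromosome 15 or 17")
    return fuse_map(m15, m17, chr17_length)


def fused_chain(gm, panel, fmap: FusedMap):
    """Reorder chromosome 15/17 genotype columns and panel frequencies
    onto the fused rob(15;17) coordinate system.

    Local-ancestry inference along the fused chain gives the junction
    flanks two-sided information (on the per-chromosome maps they are
    chain ends).  Returns (GenotypeMatrix, ReferencePanel) on a
    single-chromosome map labelled ``rob15_17``.
    """
    from .ancestryq import ReferencePanel
    from .genio import GenotypeMatrix

    src_index = [gm.snp_map.index_of(c, p)
                 for c, p in zip(fmap.table["chrom"], fmap.table["pos"])]
    n = len(src_index)
    fused_map = SNPMap(np.asarray(["rob15_17"] * n, dtype=object),
                       fmap.table["fused_pos"].to_numpy(),
                       fmap.table["snp_id"].to_numpy(),
                       gm.snp_map.ref[src_index], gm.snp_map.alt[src_index])
    fused_gm = GenotypeMatrix(gm.ids, fused_map, gm.geno[:, src_index])
    fused_panel = ReferencePanel(panel.labels, panel.freqs[:, src_index],
                                 fused_map)
    return fused_gm, fused_panel


def junction_field(gm, panel, fmap: FusedMap, priors=None, g=None, r=None
                   ) -> LocalAncestryField:
    """Posterior ancestry dosages along the fused rob(15;17) chain."""
    from . import lai

    fused_gm, fused_panel = fused_chain(gm, panel, fmap)
    kwargs = {}
    if priors is not None:
        kwargs["priors"] = priors
    if g is not None:
        kwargs["g"] = g
    if r is not None:
        kwargs["r"] = r
    hmm = lai.build_hmm(fused_panel, **kwargs)
    return lai.posterior_dosages(hmm, fused_gm)


@dataclass
class KaryotypeCall:
    individual: str
    predicted_2n: int
    wb_dosage_left: float
    wb_dosage_right: float
    confidence: float


def predict_karyotype(field_: LocalAncestryField, fmap: FusedMap,
                      flank_window: int = 1,
                      wb_label: str = "WB") -> list:
    """Karyotype calls from wild-boar dosages at the junction flanks.

    Per flank, the wild-boar allelic proportion is the mean WB dosage
    over the ``flank_window`` nearest SNPs divided by 2; the combined
    proportion is the mean of the two flanks.  With x = 2 x combined
    (the expected number of fused alleles), the call is 2n = 36 when
    x > 1.5, 2n = 38 when x < 0.5, and 2n = 37 otherwise -- exact .5
    ties resolve toward the heterozygote, flagging the animal for
    follow-up rather than clearing it.  Confidence is the flank-level
    agreement with the called allele count (1 = dosages exactly at the
    called value), minimized over the two flanks.
    """
    wb = field_.ancestry_index(wb_label)
    left = fmap.left_flank(flank_window)
    right = fmap.right_flank(flank_window)
    # match flanks by SNP id: works whether the field was decoded on the
    # original per-chromosome maps or on the fused chain
    lookup = {sid: j for j, sid in enumerate(field_.snp_map.snp_id)}
    try:
        li = [lookup[sid] for sid in left["snp_id"]]
        ri = [lookup[sid] for sid in right["snp_id"]]
    except KeyError as exc:
        raise KaryotypeError(f"flanking SNP {exc} absent from the "
                             "local-ancestry field") from exc
    calls = []
    for i, ind in enumerate(field_.ids):
        dl = float(field_.dosages[i, li, wb].mean())
        dr = float(field_.dosages[i, ri, wb].mean())
        x = 2.0 * ((dl / 2.0 + dr / 2.0) / 2.0)   # expected fused alleles
        if x > 1.5:
            call = 36
        elif x < 0.5:
            call = 38
        else:
            call = 37
        n_fused = 38 - call
        conf = 1.0 - max(abs(dl - n_fused), abs(dr - n_fused)) / 2.0
        calls.append(KaryotypeCall(individual=ind, predicted_2n=call,
                                   wb_dosage_left=dl, wb_dosage_right=dr,
                                   confidence=max(0.0, conf)))
    return calls


def calls_to_dataframe(calls: list) -> pd.DataFrame:
    return pd.DataFrame([{"individual": c.individual,
                          "predicted_2n": c.predicted_2n,
                          "wb_dosage_left": c.wb_dosage_left,
                          "wb_dosage_right": c.wb_dosage_right,
                          "confidence": c.confidence} for c in calls])


@dataclass
class Concordance:
    matrix: pd.DataFrame        # rows = predicted, columns = true
    per_class: dict             # true class -> column-normalized diagonal
    overall: float              # trace / total

    def to_tsv(self, path: str) -> None:
        self.matrix.to_csv(path, sep="\t")


def concordance(calls: list, truth) -> Concordance:
    """Confusion of in-silico calls against true (or cytogenetic)
    karyotypes; rows are predictions, columns truth, rates are
    column-normalized."""
    if isinstance(truth, pd.DataFrame):
        truth = dict(zip(truth["individual"], truth["karyotype"]))
    truth = {str(k): int(v) for k, v in dict(truth).items()}
    call_ids = [c.individual for c in calls]
    missing = sorted(set(call_ids) ^ set(truth))
    if missing:
        raise KaryotypeError(
            f"prediction/truth individual sets differ: {missing}")
    classes = [36, 37, 38]
    mat = pd.DataFrame(0, index=pd.Index(classes, name="predicted_2n"),
                       columns=pd.Index(classes, name="true_2n"))
    for c in calls:
        mat.loc[c.predicted_2n, truth[c.individual]] += 1
    per_class = {}
    for k in classes:
        tot = int(mat[k].sum())
        per_class[k] = float(mat.loc[k, k]) / tot if tot else np.nan
    overall = float(np.trace(mat.to_numpy())) / len(calls)
    return Concordance(matrix=mat, per_class=per_class, overall=overall)
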