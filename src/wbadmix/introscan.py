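"""Genome scan for regions of unusually low wild-boar ancestry.

The per-SNP wild-boar ancestry proportion (posterior dosage / 2) is
averaged over the cohort; the genome-wide mean mu and standard deviation
sigma of that per-SNP series define the thresholds, and SNPs falling
more than 3 or 6 sigma below mu mark candidate adaptive-introgression
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lai import LocalAncestryField


class ScanError(ValueError):
    pass


@dataclass
class ScanResult:
    snp_map: object
    mean_wb: np.ndarray = field(repr=False)   # per-SNP mean WB proportion
    mu: float = 0.0
    sigma: float = 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.snp_map.chrom,
                             "pos": self.snp_map.pos,
                             "mean_wb": self.mean_wb})


def ancestry_scan(field_: LocalAncestryField, wb_label: str = "WB"
                  ) -> ScanResult:
    """Per-SNP mean wild-boar ancestry proportion across the cohort."""
    if len(field_.ids) < 2:
        raise ScanError("scan needs at least 2 individuals")
    wb = field_.ancestry_index(wb_label)
    mean_wb = field_.dosages[:, :, wb].mean(axis=0) / 2.0
    return ScanResult(snp_map=field_.snp_map, mean_wb=mean_wb,
                      mu=float(mean_wb.mean()), sigma=float(mean_wb.std()))


def flag_regions(scan: ScanResult, k_sd: float = 6,
                 max_gap: int = 0) -> pd.DataFrame:
    """Intervals where the mean wild-boar proportion drops below
    mu - k_sd * sigma.

    Flagged SNPs on the same chromosome separated by at most ``max_gap``
    unflagged SNPs are merged (default strictly consecutive); bounds are
    the bp of the first/last flagged SNP, 1-based inclusive.
    """
    if scan.sigma <= 0:
        raise ScanError("scan standard deviation is zero; thresholding is "
                        "degenerate (all per-SNP means identical)")
    thr = scan.mu - k_sd * scan.sigma
    flagged = scan.mean_wb < thr
    rows = []
    chrom_arr, pos_arr = scan.snp_map.chrom, scan.snp_map.pos
    idx = np.flatnonzero(flagged)
    if len(idx):
        run = [idx[0]]
        for j in idx[1:]:
            same = chrom_arr[j] == chrom_arr[run[-1]]
            if same and j - run[-1] - 1 <= max_gap:
                run.append(j)
            else:
                rows.append(run)
                run = [j]
        rows.append(run)
    records = []
    for run in rows:
        records.append((chrom_arr[run[0]], int(pos_arr[run[0]]),
                        int(pos_arr[run[-1]]), len(run),
                        float(scan.mean_wb[run].min())))
    return pd.DataFrame(records, columns=["chrom", "start", "end",
                                          "n_snps", "min_mean_wb"])


def write_intervals(intervals: pd.DataFrame, bed_path: str,
                    tsv_path: str | None = None) -> None:
    """BED (0-based half-open) plus an optional 1-based TSV mirror."""
    bed = intervals.copy()
    bed["start"] = bed["start"] - 1
    bed[["chrom", "start", "end"]].to_csv(bed_path, sep="\t", index=False,
                                          header=False)
    if tsv_path is not None:
        intervals.to_csv(tsv_path, sep="\t", index=False,
                         float_format="%.5f")


def plot_scan(scan: ScanResult, path: str = "scan.png") -> None:
    """Ancestry track with mean and 3/6 SD thresholds."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.5))
    x = np.arange(len(scan.mean_wb))
    for c in scan.snp_map.chromosomes:
        m = scan.snp_map.chrom_mask(c)
        ax.plot(x[m], scan.mean_wb[m], lw=0.7, label=str(c))
    ax.axhline(scan.mu, color="red", lw=1.5)
    for k in (3, 6):
        ax.axhline(scan.mu - k * scan.sigma, color="red", ls=":", lw=1)
    ax.set_xlabel("SNP index")
    ax.set_ylabel("mean WB ancestry")
    ax.legend(fontsize=7, ncol=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
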