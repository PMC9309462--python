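"""End-to-end orchestration: simulate -> filter -> PCA/outliers ->
global ancestry -> local ancestry -> karyotype prediction -> scan.

One :class:`RunConfig` (YAML-loadable) drives a full run; all
randomness flows from its single seed through per-stage child seeds, so
re-running an identical config reproduces byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import ancestryq, genio, introscan, karyopred, lai, pcaout, simdata

log = logging.getLogger("wbadmix")


@dataclass
class RunConfig:
    outdir: str = "wbadmix_run"
    seed: int = 1

    # simulation: a ~194 Mb four-chromosome desk genome; 3,000 SNPs give
    # roughly the marker density of the 70K porcine chip, and chromosome
    # 17 keeps its true length (it defines the rob(15;17) junction)
    n_snps: int = 3000
    n_individuals: int = 150
    chrom_lengths: dict = field(
        default_factory=lambda: {"13": 60_000_000, "15": 50_000_000,
                                 "17": 63_494_081, "18": 20_000_000})
    divergence: tuple = (0.2, 0.2, 0.3)
    panel_sizes: tuple = (100, 100, 40)
    pure_fraction: float = 0.4
    f1_fraction: float = 0.05
    depth_range: tuple = (2, 8)
    missing_rate: float = 0.02

    # filtering
    maf_min: float = 0.05
    miss_max: float = 0.05
    ld_r2: float = 0.1

    # ancestry estimation
    n_boot: int = 200
    hmm_generations: float = 25
    hmm_recomb_rate: float = 1e-8
    hmm_priors: tuple = (0.30, 0.66, 0.04)

    # karyotype / scan
    chr17_length: int = simdata.CHR17_LENGTH
    flank_window: int = 1
    k_sd: tuple = (3, 6)
    max_gap: int = 0
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_individuals < 2 or self.n_snps < 10:
            raise ValueError("config needs >= 2 individuals and >= 10 SNPs")
        if len(self.panel_sizes) != 3:
            raise ValueError("panel_sizes must give one size per reference "
                             "population (WB, EUR_DP, ASIA_DP)")
        if "15" not in self.chrom_lengths or "17" not in self.chrom_lengths:
            raise ValueError("chrom_lengths must include chromosomes '15' "
                             "and '17' for rob(15;17) prediction")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def _setup_logging(outdir: str) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers
                    if not isinstance(h, logging.FileHandler)]
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(sh)
    fh = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    _setup_logging(config.outdir)
    for key, value in sorted(config.to_dict().items()):
        log.info("config %s = %r", key, value)
    out = lambda name: os.path.join(config.outdir, name)  # noqa: E731
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(config.seed).spawn(8)]
    manifest = {"seed": config.seed, "config": config.to_dict(),
                "stages": {}, "outputs": {}}

    def stage(name):
        log.info("stage %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        # 1. simulate ----------------------------------------------------
        st = stage("simulate")
        model = simdata.default_model(
            n_snps=config.n_snps, chrom_lengths=config.chrom_lengths,
            divergence=config.divergence, seed=seeds[0])
        panel, panel_gms = simdata.generate_reference_panels(
            model, dict(zip(model.pop_labels, config.panel_sizes)),
            seed=seeds[1])
        cohort = simdata.simulate_admixed_cohort(
            model, panel, config.n_individuals, seed=seeds[2],
            pure_fraction=config.pure_fraction,
            f1_fraction=config.f1_fraction,
            depth_range=tuple(config.depth_range),
            missing_rate=config.missing_rate)
        gm = simdata.genotype_matrix(cohort, model)
        genio.write_plink(gm, out("cohort"))
        panel.to_tsv(out("panel_freqs.tsv"))
        simdata.write_truth_tracts(cohort, out("truth_tracts.tsv"),
                                   model.pop_labels, seed=config.seed)
        simdata.write_truth_karyotypes(cohort, out("truth_karyotypes.tsv"),
                                       seed=config.seed)
        st.update(n_snps=model.n_snps, n_individuals=len(cohort),
                  karyotype_counts={k: sum(1 for c in cohort
                                           if c.karyotype == k)
                                    for k in (36, 37, 38)})

        # 2. filter ------------------------------------------------------
        st = stage("filter")
        filtered = genio.filter_snps(gm, maf_min=config.maf_min,
                                     miss_max=config.miss_max,
                                     autosomes_only=True)
        keep = np.isin(gm.snp_map.snp_id, filtered.snp_map.snp_id)
        fpanel = panel.subset_snps(np.flatnonzero(keep))
        genio.write_plink(filtered, out("cohort_filtered"))
        st.update(n_snps_in=gm.n_snps, n_snps_kept=filtered.n_snps)

        # 3. pca / outliers ----------------------------------------------
        st = stage("pca")
        scores = pcaout.pca(filtered, n_components=10)
        calls = pcaout.detect_outliers(scores, seed=seeds[3])
        scores.to_dataframe().to_csv(out("pca_scores.tsv"), sep="\t",
                                     index=False, float_format="%.6g")
        pcaout.calls_to_dataframe(calls).to_csv(
            out("outlier_calls.tsv"), sep="\t", index=False,
            float_format="%.6g")
        if config.make_plots:
            pcaout.plot_scores(scores, calls, out("pca.png"))
        outliers = {c.individual for c in calls if c.is_outlier}
        st.update(n_outliers=len(outliers))

        # 4. global ancestry ---------------------------------------------
        st = stage("qestimate")
        qtab = ancestryq.ancestry_table(filtered, fpanel,
                                        n_boot=config.n_boot, seed=seeds[4])
        qtab.to_csv(out("qmatrix.tsv"), sep="\t", index=False,
                    float_format="%.6g")
        st.update(n_boot=config.n_boot,
                  classifications=qtab["classification"]
                  .value_counts().to_dict())

        # 5. local ancestry ----------------------------------------------
        st = stage("lai")
        hmm = lai.build_hmm(fpanel, priors=config.hmm_priors,
                            g=config.hmm_generations,
                            r=config.hmm_recomb_rate)
        field_ = lai.posterior_dosages(hmm, filtered)
        field_.to_tsv(out("dosages"))
        st.update(mean_loglik=float(np.mean(field_.loglik)))

        # 6. karyotype ---------------------------------------------------
        st = stage("karyotype")
        fmap = karyopred.fuse_from_map(filtered.snp_map,
                                       chr17_length=config.chr17_length)
        fmap.to_tsv(out("fused_map.tsv"))
        # decode on the fused rob(15;17) chain so both junction flanks see
        # two-sided haplotype information
        jfield = karyopred.junction_field(filtered, fpanel, fmap,
                                          priors=config.hmm_priors,
                                          g=config.hmm_generations,
                                          r=config.hmm_recomb_rate)
        kcalls = karyopred.predict_karyotype(jfield, fmap,
                                             flank_window=config.flank_window)
        karyopred.calls_to_dataframe(kcalls).to_csv(
            out("karyotype_calls.tsv"), sep="\t", index=False,
            float_format="%.6g")
        truth = {ind.id: ind.karyotype for ind in cohort}
        conc = karyopred.concordance(kcalls, truth)
        conc.to_tsv(out("karyotype_confusion.tsv"))
        st.update(overall_concordance=conc.overall,
                  per_class={str(k): (None if np.isnan(v) else v)
                             for k, v in conc.per_class.items()})

        # 7. scan --------------------------------------------------------
        st = stage("scan")
        keep_ids = [i for i in field_.ids if i not in outliers]
        keep_idx = [field_.ids.index(i) for i in keep_ids]
        scan_field = lai.LocalAncestryField(
            ids=keep_ids, labels=field_.labels, snp_map=field_.snp_map,
            dosages=field_.dosages[keep_idx])
        scan = introscan.ancestry_scan(scan_field)
        scan.to_dataframe().to_csv(out("scan.tsv"), sep="\t", index=False,
                                   float_format="%.6g")
        n_flagged = {}
        for k in config.k_sd:
            iv = introscan.flag_regions(scan, k_sd=k, max_gap=config.max_gap)
            introscan.write_intervals(iv, out(f"scan_{k}sd.bed"),
                                      out(f"scan_{k}sd.tsv"))
            n_flagged[str(k)] = len(iv)
        if config.make_plots:
            introscan.plot_scan(scan, out("scan.png"))
        st.update(mu=scan.mu, sigma=scan.sigma, n_intervals=n_flagged)
    except Exception as exc:
        failed = next((n for n, s in manifest["stages"].items() if not s),
                      "unknown")
        log.error("stage %s failed: %s", failed, exc)
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest["outputs"] = sorted(f for f in os.listdir(config.outdir)
                                 if f.endswith((".tsv", ".bed", ".ped",
                                                ".map")))
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %d outputs in %s",
             len(manifest["outputs"]), config.outdir)
    return manifest
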