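"""End-to-end orchestration: simulate -> qc -> call-asnps -> assoc -> prune.

Two modes mirror the two study designs the analysis supports:

* ``genotype`` — individual-level data: QC the panel, call aSNPs against
  the archaic genome, run covariate-adjusted logistic association
  (age, sex, top principal components), LD-prune at r2 > 0.5, count
  independent tests at r2 < 0.8 and report the Bonferroni threshold and
  inflation factor.
* ``summary`` — only per-study summary statistics: look the aSNPs up in
  each study and apply the P < 0.05 + effect-direction concordance rule.

Stage outputs are pure functions of (inputs, config, seed); running the
same configuration twice produces byte-identical TSV output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import introgression as intro_mod
from . import sample_qc as qc_mod
from .io_formats import (
    ConfigurationError,
    read_genetic_map,
    read_summary_stats,
    read_vcf,
    write_results,
)

logger = logging.getLogger("neanderscan")


@dataclass
class PipelineConfig:
    mode: str = "genotype"                  # "genotype" | "summary"
    vcf: str | None = None
    genetic_map: str | None = None
    genetic_map2: str | None = None
    rate_cm_per_mb: float | None = 1.0
    covariates: str | None = None           # TSV: sample status age sex ...
    summary_stats: str | None = None
    asnp_list: str | None = None            # summary mode: TSV with snp column
    outdir: str = "neanderscan_out"
    populations: dict = field(default_factory=dict)  # sample -> population
    african_pop: str = "AFR"
    archaic_sample: str = "Archaic"
    n_pcs: int = 8
    alpha: float = 0.05
    ils: intro_mod.ILSModelConfig = field(default_factory=intro_mod.ILSModelConfig)
    qc: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)
    mt: assoc_mod.MultipleTestingConfig = field(
        default_factory=assoc_mod.MultipleTestingConfig
    )
    skip_qc: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "ils" in kwargs:
            kwargs["ils"] = intro_mod.ILSModelConfig(**kwargs["ils"])
        if "qc" in kwargs:
            kwargs["qc"] = qc_mod.QCThresholds(**kwargs["qc"])
        if "mt" in kwargs:
            kwargs["mt"] = assoc_mod.MultipleTestingConfig(**kwargs["mt"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    seconds: float


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    mode: str
    stages: list[StageRecord] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def add(self, stage: str, n_in: int, n_out: int, t0: float) -> None:
        self.stages.append(StageRecord(stage, n_in, n_out, round(time.time() - t0, 3)))
        logger.info("stage %-12s: %d -> %d", stage, n_in, n_out)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "mode": self.mode,
                    "stages": [asdict(s) for s in self.stages],
                    "summary": self.summary,
                },
                fh,
                indent=2,
            )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed, mode=config.mode
    )
    if config.mode == "genotype":
        _run_genotype_mode(config, outdir, manifest)
    elif config.mode == "summary":
        _run_summary_mode(config, outdir, manifest)
    else:
        raise ConfigurationError(f"unknown mode {config.mode!r}")
    manifest.to_json(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Genotype mode (discovery-style, individual-level data)
# ---------------------------------------------------------------------------

def _run_genotype_mode(config, outdir: Path, manifest: RunManifest) -> None:
    if not config.vcf:
        raise ConfigurationError("genotype mode requires a VCF path")
    if not config.covariates:
        raise ConfigurationError("genotype mode requires a covariate/phenotype TSV")

    t0 = time.time()
    panel, archaic = read_vcf(
        config.vcf,
        populations=config.populations,
        archaic_sample=config.archaic_sample,
        african_pop=config.african_pop,
    )
    if archaic is None:
        raise ConfigurationError("genotype mode requires the archaic sample")
    manifest.add("read_vcf", panel.n_variants, panel.n_variants, t0)

    pheno = pd.read_csv(config.covariates, sep="\t")
    for col in ("sample", "status", "age", "sex"):
        if col not in pheno.columns:
            raise ConfigurationError(f"covariate TSV lacks column {col!r}")
    status_map = dict(zip(pheno["sample"].astype(str), pheno["status"].astype(int)))

    # QC (variant removals must propagate to the aligned archaic genome)
    t0 = time.time()
    n_before = panel.n_variants
    original_index = {v.id: i for i, v in enumerate(panel.variants)}
    if not config.skip_qc:
        panel, _reports = qc_mod.run_sample_qc(
            panel, config.qc, status=status_map,
            skip_pca=panel.n_samples < config.qc.pca_k + 1,
        )
    manifest.add("qc", n_before, panel.n_variants, t0)
    if panel.n_variants != archaic.n_variants:
        keep = np.array([original_index[v.id] for v in panel.variants], dtype=int)
        archaic = type(archaic)(
            sample=archaic.sample, genotypes=archaic.genotypes[keep]
        )

    # aSNP calling
    t0 = time.time()
    candidates = intro_mod.apply_site_criteria(panel, archaic)
    gmap = read_genetic_map(config.genetic_map) if config.genetic_map else None
    gmap2 = read_genetic_map(config.genetic_map2) if config.genetic_map2 else None
    segments = intro_mod.build_segments(
        panel, candidates, config.ils,
        genetic_map=gmap, genetic_map2=gmap2,
        rate_cm_per_mb=config.rate_cm_per_mb,
    )
    calls = intro_mod.call_asnps(candidates, segments, alpha=config.alpha)
    manifest.add("call_asnps", len(candidates), len(calls), t0)
    _write_segments_bed(outdir / "segments.bed", panel.chrom, segments)
    _write_asnps(outdir / "asnps.tsv", calls)

    # Association on non-African samples with phenotypes
    t0 = time.time()
    pheno = pheno.set_index("sample")
    nonafr = [
        s for s, p in zip(panel.samples, panel.populations)
        if p != config.african_pop and s in pheno.index
    ]
    if not nonafr:
        raise ConfigurationError("no phenotyped non-African samples")
    sub = panel.take_samples(np.array([panel.samples.index(s) for s in nonafr]))
    ph = pheno.loc[nonafr]
    y = ph["status"].to_numpy(dtype=float)

    covars = [ph["age"].to_numpy(dtype=float), ph["sex"].to_numpy(dtype=float)]
    names = ["age", "sex"]
    n_pcs = min(config.n_pcs, max(sub.n_samples - 2, 0))
    if n_pcs > 0 and sub.n_samples >= n_pcs + 1:
        try:
            scores, _ = qc_mod.pca_genotypes(sub, k=n_pcs)
            covars.extend(scores.T)
            names.extend(f"PC{i + 1}" for i in range(scores.shape[1]))
        except Exception as exc:  # few samples / low rank: PCs are optional here
            logger.warning("skipping PC covariates: %s", exc)
    covariates = np.column_stack(covars)

    dosages = sub.dosages()
    call_idx = np.array([c.candidate.index for c in calls], dtype=int)
    results = []
    import warnings as _warnings

    with _warnings.catch_warnings():
        # separation is recorded per result; one aggregate log line replaces
        # a per-SNP warning flood on small panels
        _warnings.simplefilter("ignore", assoc_mod.SeparationWarning)
        for c, row in zip(calls, dosages[call_idx] if len(call_idx) else []):
            d = row.copy()
            if np.all(np.isnan(d)) or np.nanstd(d) == 0:
                continue
            res = assoc_mod.fit_logistic(
                d, y, covariates,
                snp=c.id, study="discovery", covariate_names=names, pos=c.pos,
            )
            results.append(res)
    n_sep = sum(r.separation for r in results)
    if n_sep:
        logger.warning("assoc: %d of %d fits flagged as quasi-separated",
                       n_sep, len(results))
    manifest.add("assoc", len(calls), len(results), t0)
    write_results(outdir / "assoc.tsv", results)

    # Pruning, thresholds, diagnostics
    t0 = time.time()
    if results:
        idx = [panel.variants[i].id for i in call_idx]
        keep_ids = {r.snp for r in results}
        rows = [i for i, c in enumerate(calls) if c.id in keep_ids]
        ld = assoc_mod.ld_matrix(
            dosage_matrix=np.vstack([dosages[call_idx[i]] for i in rows]),
            ids=[calls[i].id for i in rows],
            positions=np.array([calls[i].pos for i in rows]),
        )
        pruned = assoc_mod.greedy_prune(results, ld, config.mt.prune_r2)
        m = assoc_mod.count_independent(ld, config.mt.independence_r2)
        threshold = assoc_mod.bonferroni_threshold(m, config.mt.alpha)
        clean_p = np.array([r.wald_p for r in results if not r.separation])
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            lam = (
                assoc_mod.genomic_lambda(p=clean_p)
                if len(clean_p) >= 2 else float("nan")
            )
        n_sig = sum(r.wald_p < threshold for r in results if not r.separation)
    else:
        pruned, m, threshold, lam, n_sig = [], 0, float("nan"), float("nan"), 0
    manifest.add("prune", len(results), len(pruned), t0)
    write_results(outdir / "assoc_pruned.tsv", pruned)
    manifest.summary = {
        "n_candidates": len(candidates),
        "n_segments": len(segments),
        "n_asnps": len(calls),
        "n_tested": len(results),
        "n_pruned": len(pruned),
        "m_independent": m,
        "bonferroni_threshold": threshold,
        "genomic_lambda": lam,
        "n_bonferroni_significant": n_sig,
    }


# ---------------------------------------------------------------------------
# Summary mode (FinnGen/JaPAN-style replication path)
# ---------------------------------------------------------------------------

def _run_summary_mode(config, outdir: Path, manifest: RunManifest) -> None:
    if not config.summary_stats:
        raise ConfigurationError("summary mode requires a summary-statistics TSV")
    t0 = time.time()
    records = read_summary_stats(config.summary_stats)
    manifest.add("read_summary", len(records), len(records), t0)

    asnp_ids = None
    if config.asnp_list:
        df = pd.read_csv(config.asnp_list, sep="\t")
        if "snp" not in df.columns:
            raise ConfigurationError("aSNP list TSV lacks 'snp' column")
        asnp_ids = set(df["snp"].astype(str))

    t0 = time.time()
    by_snp: dict[str, list] = {}
    for r in records:
        if asnp_ids is not None and r.snp not in asnp_ids:
            continue
        by_snp.setdefault(r.snp, []).append(r)

    rows = []
    n_pass = 0
    for snp in sorted(by_snp):
        recs = by_snp[snp]
        if len(recs) >= 2:
            passed = assoc_mod.concordance_filter(recs, alpha=config.alpha)
        else:
            passed = recs[0].p < config.alpha
        n_pass += passed
        for r in recs:
            rows.append(
                {
                    "snp": snp, "study": r.study, "effect_allele": r.effect_allele,
                    "beta": r.beta, "se": r.se if r.se is not None else "",
                    "p": r.p, "concordant_pass": bool(passed),
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "summary_concordance.tsv", sep="\t",
                              index=False, float_format="%.10g")
    manifest.add("concordance", len(by_snp), n_pass, t0)
    m = max(len(by_snp), 1)
    manifest.summary = {
        "n_snps": len(by_snp),
        "n_concordant": n_pass,
        "bonferroni_threshold": assoc_mod.bonferroni_threshold(m, config.mt.alpha),
        "m_independent": m,
    }


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def _write_segments_bed(path: Path, chrom: str, segments) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{chrom}\t{s.start}\t{s.end}\tseg{s.segment_id}|{s.haplotype}"
                f"\t{s.p_adj:.6g}\n"
            )


def _write_asnps(path: Path, calls) -> None:
    with open(path, "w") as fh:
        fh.write("snp\tpos\tarchaic_allele\tmin_p_adj\tsegments\n")
        for c in calls:
            fh.write(
                f"{c.id}\t{c.pos + 1}\t{c.candidate.archaic_allele}"
                f"\t{c.min_p_adj:.6g}\t{','.join(map(str, c.segment_ids))}\n"
            )
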