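"""Synthetic admixed panels with known archaic tracts and phenotypes.

The generator emulates the genomic signal the caller exploits: after
Neandertal–modern-human admixture roughly 55 thousand years ago,
recombination has had ``G_adm`` generations to break introgressed
haplotypes, so their lengths are approximately exponential with mean
``1/(r_bp * G_adm)``.  Alleles shared through incomplete lineage sorting
(ILS) have recombined over the full archaic–modern divergence
(``G_div >> G_adm`` generations) and sit on much shorter shared tracts,
some of which survive in the African outgroup as well.

Tracts are placed by an alternating (gap, tract) renewal process rather
than by a full coalescent: this is cheap, exactly reproducible, and
exposes precisely the tract-length contrast that the segment-length test
is built on.  Archaic marker alleles are fixed derived on their tracts
and homozygous derived in the archaic pseudo-genome; background SNPs are
shared by all populations and absent from the archaic derived state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import (
    MISSING,
    ArchaicGenome,
    ConfigurationError,
    GeneticMap,
    HaplotypePanel,
    TruthTract,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger("neanderscan")

_CM_PER_MB_TO_PER_BP = 1e-8  # 1 cM/Mb ~ 1e-8 crossovers per bp per generation


@dataclass
class SimulationParams:
    """Knobs of the admixture-tract simulator.

    Defaults follow the admixture history the analysis assumes: ~2% of
    each non-African genome of Neandertal origin (within the reported
    1-3% range), admixture ~55 ky ago and an archaic-modern divergence
    of ~550 ky, with a 29-year generation time; hence
    ``G_adm = 55e3/29 ~ 1900`` and ``G_div = 2 * 550e3/29 ~ 37 900``
    generations (two branches separate the lineages).
    """

    seq_length: int = 10_000_000
    n_afr: int = 50
    n_nonafr: int = 50
    n_nonafr2: int = 0            # optional second non-African population
    p_adm: float = 0.02           # introgressed genome fraction per haplotype
    p_adm2_scale: float = 1.14    # elevated admixture in the second population
    g_adm: float = 1900.0         # generations since admixture
    g_div: float = 37_900.0       # total branch generations since divergence
    mu_arch: float = 1e-3         # archaic-marker density per bp inside tracts
    mu_bg: float = 1e-3           # background SNP density per bp
    q_ils: float = 0.01           # per-haplotype genome fraction of ILS tracts
    pi_afr_loss: float = 0.3      # P(an ILS tract is absent from all Africans)
    ils_carrier_low: float = 0.05   # ILS tract carrier-frequency range
    ils_carrier_high: float = 0.30
    recomb_rate: float | GeneticMap = 1.0  # constant cM/Mb or a GeneticMap
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    afr_label: str = "AFR"
    nonafr_label: str = "EUR"
    nonafr2_label: str = "EAS"
    archaic_name: str = "Archaic"
    chrom: str = "1"
    seed: int | None = None

    def validate(self) -> None:
        for name in ("p_adm", "q_ils", "pi_afr_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.p_adm + self.q_ils >= 1.0:
            raise ValidationError("p_adm + q_ils must be < 1")
        if self.mu_arch <= 0 or self.mu_bg <= 0:
            raise ValidationError("marker/background densities must be positive")
        if not self.g_adm < self.g_div:
            raise ValidationError("G_adm must be smaller than G_div")
        if self.n_afr < 1 or self.n_nonafr < 1:
            raise ValidationError("need at least one African and one non-African sample")
        mean_len = self.mean_tract_length(self.g_adm)
        if self.seq_length < mean_len:
            warnings.warn(
                f"sequence length {self.seq_length} bp is shorter than the mean "
                f"introgressed tract ({mean_len:.0f} bp); tract statistics will "
                "be dominated by truncation",
                stacklevel=2,
            )

    # -- recombination helpers ---------------------------------------------

    def rate_at(self, pos: float) -> float:
        """Local recombination rate (cM/Mb) at a position."""
        if isinstance(self.recomb_rate, GeneticMap):
            m = self.recomb_rate
            return float(np.interp(pos, m.positions, m.rates))
        return float(self.recomb_rate)

    def mean_tract_length(self, generations: float, pos: float = 0.0) -> float:
        """Expected tract length 1/(r_bp * G) at ``pos``."""
        r_bp = self.rate_at(pos) * _CM_PER_MB_TO_PER_BP
        if r_bp <= 0:
            return float("inf")
        return 1.0 / (r_bp * generations)


@dataclass
class SimulationResult:
    """Panel plus ground truth.

    ``marker_positions`` / ``background_positions`` record which variant
    positions carry an archaic-derived allele versus neutral background;
    they exist for truth-based evaluation only and are never consumed by
    the calling pipeline.
    """

    panel: HaplotypePanel
    archaic: ArchaicGenome
    truth_tracts: list[TruthTract]
    marker_positions: np.ndarray
    background_positions: np.ndarray

    def __iter__(self):
        # Allows ``panel, archaic, truth = simulate_panel(...)``.
        return iter((self.panel, self.archaic, self.truth_tracts))


def _renewal_intervals(
    rng: np.random.Generator,
    length: int,
    mean_len: float,
    fraction: float,
) -> list[tuple[int, int]]:
    """Alternating gap/tract renewal with exponential lengths.

    The stationary covered fraction is ``fraction``; tract lengths are
    Exp(mean_len) and gaps Exp(mean_len * (1 - fraction) / fraction).
    """
    if fraction <= 0.0:
        return []
    mean_gap = mean_len * (1.0 - fraction) / fraction
    intervals: list[tuple[int, int]] = []
    # Stationary start: begin inside a tract with probability ``fraction``
    # (residual length is again exponential by memorylessness).
    pos = 0.0
    if rng.random() < fraction:
        tract_len = rng.exponential(mean_len)
        end = min(tract_len, length)
        if end - pos >= 1:
            intervals.append((0, int(round(end))))
        pos = tract_len
    while pos < length:
        pos += rng.exponential(mean_gap)
        if pos >= length:
            break
        tract_len = rng.exponential(mean_len)
        start, end = pos, min(pos + tract_len, length)
        if int(round(end)) - int(round(start)) >= 1:
            intervals.append((int(round(start)), int(round(end))))
        pos += tract_len
    return intervals


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _overlaps(starts: np.ndarray, ends: np.ndarray, s: int, e: int) -> bool:
    """Does ``[s, e)`` overlap any of the sorted disjoint intervals?"""
    if len(starts) == 0:
        return False
    i = int(np.searchsorted(starts, e, side="left")) - 1
    return i >= 0 and ends[i] > s


def simulate_panel(params: SimulationParams) -> SimulationResult:
    """Generate an admixed haplotype panel with ground-truth tracts.

    Per non-African haplotype, introgressed tracts are laid down by the
    renewal process at genome fraction ``p_adm`` with exponential lengths
    of mean ``1/(r_bp * G_adm)``.  ILS tract loci are laid down once at
    the genome level (mean length ``1/(r_bp * G_div)``) and assigned to
    random haplotypes in every population at a per-locus carrier
    frequency; with probability ``pi_afr_loss`` a locus is excluded from
    all African haplotypes, which is the sub-case the segment-length test
    alone must catch.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    L = int(params.seq_length)

    # --- sample bookkeeping -------------------------------------------------
    pops: list[tuple[str, int, float]] = [(params.afr_label, params.n_afr, 0.0)]
    pops.append((params.nonafr_label, params.n_nonafr, params.p_adm))
    if params.n_nonafr2 > 0:
        pops.append(
            (params.nonafr2_label, params.n_nonafr2, params.p_adm * params.p_adm2_scale)
        )
    samples: list[str] = []
    populations: list[str] = []
    hap_admixture: list[float] = []  # per haplotype
    for label, n, p in pops:
        for i in range(n):
            samples.append(f"{label}{i:04d}")
            populations.append(label)
            hap_admixture.extend([p, p])
    n_samples = len(samples)
    n_haps = 2 * n_samples
    is_afr_hap = np.repeat(np.asarray(populations) == params.afr_label, 2)

    mean_len_adm = params.mean_tract_length(params.g_adm)
    mean_len_ils = params.mean_tract_length(params.g_div)

    # --- introgressed tracts, per haplotype ---------------------------------
    hap_tracts: list[list[tuple[int, int, str]]] = [[] for _ in range(n_haps)]
    for h in range(n_haps):
        frac = hap_admixture[h]
        if frac > 0:
            for s, e in _renewal_intervals(rng, L, mean_len_adm, frac):
                hap_tracts[h].append((s, e, "introgressed"))

    # --- ILS tract loci, genome level ---------------------------------------
    f_mean = 0.5 * (params.ils_carrier_low + params.ils_carrier_high)
    q_loci = min(params.q_ils / f_mean, 0.9) if params.q_ils > 0 else 0.0
    ils_loci = _renewal_intervals(rng, L, mean_len_ils, q_loci)
    # frozen per-hap introgressed intervals for fast overlap rejection
    adm_starts = [
        np.array([t[0] for t in tr], dtype=np.int64) for tr in hap_tracts
    ]
    adm_ends = [
        np.array([t[1] for t in tr], dtype=np.int64) for tr in hap_tracts
    ]
    for s, e in ils_loci:
        f = rng.uniform(params.ils_carrier_low, params.ils_carrier_high)
        lost_in_afr = rng.random() < params.pi_afr_loss
        carriers = rng.random(n_haps) < f
        if lost_in_afr:
            carriers &= ~is_afr_hap
        for h in np.flatnonzero(carriers):
            if _overlaps(adm_starts[h], adm_ends[h], s, e):
                continue  # keep per-haplotype tracts non-overlapping
            hap_tracts[h].append((s, e, "ILS"))

    truth: list[TruthTract] = []
    for h in range(n_haps):
        hap_tracts[h].sort()
        sample, side = samples[h // 2], h % 2
        for s, e, origin in hap_tracts[h]:
            truth.append(TruthTract(sample=sample, side=side, start=s, end=e, origin=origin))

    # --- archaic marker sites on the union of all tracts --------------------
    union = _merge_intervals([(s, e) for tr in hap_tracts for (s, e, _) in tr])
    union_len = sum(e - s for s, e in union)
    marker_positions = np.empty(0, dtype=np.int64)
    if union_len > 0:
        n_markers = rng.poisson(params.mu_arch * union_len)
        offsets = np.sort(rng.uniform(0, union_len, n_markers))
        # map offsets within the union back to genome coordinates
        seg_starts = np.array([s for s, _ in union], dtype=np.int64)
        seg_lens = np.array([e - s for s, e in union], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(seg_lens)])
        seg_idx = np.searchsorted(cum, offsets, side="right") - 1
        marker_positions = (seg_starts[seg_idx] + (offsets - cum[seg_idx])).astype(np.int64)
        marker_positions = np.unique(marker_positions)

    # --- background SNPs -----------------------------------------------------
    n_bg = rng.poisson(params.mu_bg * L)
    bg_positions = np.unique(rng.integers(0, L, n_bg))
    bg_positions = np.setdiff1d(bg_positions, marker_positions, assume_unique=True)
    bg_freqs = rng.uniform(0.05, 0.95, len(bg_positions))

    # --- assemble haplotype matrix ------------------------------------------
    all_pos = np.concatenate([marker_positions, bg_positions])
    order = np.argsort(all_pos)
    all_pos = all_pos[order]
    is_marker = np.concatenate(
        [np.ones(len(marker_positions), bool), np.zeros(len(bg_positions), bool)]
    )[order]
    n_var = len(all_pos)

    alleles = np.zeros((n_var, n_haps), dtype=np.int8)
    # background: one shared frequency across all populations
    bg_rows = np.flatnonzero(~is_marker)
    if len(bg_rows):
        draws = rng.random((len(bg_rows), n_haps))
        alleles[bg_rows] = (draws < bg_freqs[:, None]).astype(np.int8)
        # The background ref allele is ancestral and shared with the archaic
        # genome; it segregates in the (large) real African population, so
        # guarantee it survives in the sampled outgroup even when the sampled
        # alt frequency drifts to fixation.
        afr_cols = np.flatnonzero(is_afr_hap)
        if len(afr_cols):
            afr_block = alleles[np.ix_(bg_rows, afr_cols)]
            fixed_alt = np.flatnonzero(afr_block.min(axis=1) == 1)
            if len(fixed_alt):
                back_col = afr_cols[rng.integers(0, len(afr_cols), len(fixed_alt))]
                alleles[bg_rows[fixed_alt], back_col] = 0
    # markers: derived allele wherever the haplotype's tracts cover the site
    marker_rows = np.flatnonzero(is_marker)
    marker_pos = all_pos[marker_rows]
    for h in range(n_haps):
        tr = hap_tracts[h]
        if not tr:
            continue
        starts = np.array([t[0] for t in tr], dtype=np.int64)
        ends = np.array([t[1] for t in tr], dtype=np.int64)
        idx = np.searchsorted(starts, marker_pos, side="right") - 1
        inside = (idx >= 0) & (marker_pos < ends[np.clip(idx, 0, None)])
        alleles[marker_rows[inside], h] = 1

    genotypes = alleles.reshape(n_var, n_samples, 2)

    # --- archaic pseudo-genome ----------------------------------------------
    arch = np.zeros((n_var, 2), dtype=np.int8)
    arch[is_marker] = 1  # homozygous derived at marker sites

    # --- noise knobs ----------------------------------------------------------
    if params.genotype_error_rate > 0:
        flips = rng.random(genotypes.shape) < params.genotype_error_rate
        genotypes = np.where(flips, 1 - genotypes, genotypes).astype(np.int8)
    if params.missing_rate > 0:
        miss = rng.random((n_var, n_samples)) < params.missing_rate
        genotypes = genotypes.copy()
        genotypes[miss] = MISSING

    # --- variant metadata -----------------------------------------------------
    base_pairs = np.array([["A", "G"], ["C", "T"], ["G", "A"], ["T", "C"]])
    pair_idx = rng.integers(0, 4, n_var)
    variants = [
        VariantRecord(
            chrom=params.chrom,
            pos=int(p),
            id=f"var{int(p) + 1}",
            ref=base_pairs[pair_idx[i]][0],
            alt=base_pairs[pair_idx[i]][1],
        )
        for i, p in enumerate(all_pos)
    ]

    panel = HaplotypePanel(
        chrom=params.chrom,
        variants=variants,
        samples=samples,
        populations=populations,
        genotypes=genotypes,
        african_pop=params.afr_label,
    )
    archaic = ArchaicGenome(sample=params.archaic_name, genotypes=arch)
    logger.info(
        "simulate_panel: %d variants (%d archaic markers, %d background), "
        "%d samples, %d truth tracts",
        n_var, int(is_marker.sum()), len(bg_rows), n_samples, len(truth),
    )
    return SimulationResult(
        panel=panel,
        archaic=archaic,
        truth_tracts=truth,
        marker_positions=all_pos[is_marker],
        background_positions=all_pos[~is_marker],
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeParams:
    """Generative logistic phenotype model (the mirror of the fitted one).

    ``causal`` maps variant ids to per-alt-allele log-odds.  Age enters
    the linear predictor centred at ``age_mean`` so that ``beta0`` alone
    controls the baseline prevalence.
    """

    beta0: float = 0.0
    causal: Mapping[str, float] = field(default_factory=dict)
    beta_age: float = 0.0
    beta_sex: float = 0.0
    age_mean: float = 60.0
    age_sd: float = 10.0
    sex_p: float = 0.5
    seed: int | None = None


def simulate_phenotypes(
    panel: HaplotypePanel, pp: PhenotypeParams
) -> pd.DataFrame:
    """Draw case/control status, age and sex per sample.

    Status is Bernoulli(expit(beta0 + sum beta_g * dosage
    + beta_age * (age - age_mean) + beta_sex * sex)).
    """
    rng = np.random.default_rng(pp.seed)
    n = panel.n_samples
    age = rng.normal(pp.age_mean, pp.age_sd, n)
    sex = (rng.random(n) < pp.sex_p).astype(int)
    eta = np.full(n, pp.beta0, dtype=float)
    eta += pp.beta_age * (age - pp.age_mean) + pp.beta_sex * sex

    if pp.causal:
        ids = {v.id: i for i, v in enumerate(panel.variants)}
        dosages = panel.dosages()
        for snp, beta_g in pp.causal.items():
            if snp not in ids:
                raise ConfigurationError(f"causal SNP {snp!r} not present in panel")
            d = dosages[ids[snp]]
            if np.isnan(d).any():
                fill = np.nanmean(d) if not np.isnan(d).all() else 0.0
                d = np.where(np.isnan(d), fill, d)
            eta += beta_g * d

    prob = expit(eta)
    if pp.causal and (prob.min() < 1e-6 or prob.max() > 1.0 - 1e-6):
        warnings.warn(
            "phenotype model drives case probabilities to 0/1 for some "
            "genotype groups; downstream fits may be quasi-separated",
            stacklevel=2,
        )
    status = (rng.random(n) < prob).astype(int)
    return pd.DataFrame(
        {"sample": panel.samples, "status": status, "age": age, "sex": sex}
    )


def sample_case_control(
    phenotypes: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Retrospective sampling: fixed numbers of cases and controls.

    Case-control ascertainment shifts only the logistic intercept, so
    genotype odds ratios remain estimable from the sampled set.
    """
    rng = np.random.default_rng(seed)
    cases = phenotypes.index[phenotypes["status"] == 1].to_numpy()
    controls = phenotypes.index[phenotypes["status"] == 0].to_numpy()
    if len(cases) < n_cases or len(controls) < n_controls:
        raise ValidationError(
            f"pool has {len(cases)} cases / {len(controls)} controls; "
            f"requested {n_cases}/{n_controls}"
        )
    chosen = np.concatenate(
        [
            rng.choice(cases, n_cases, replace=False),
            rng.choice(controls, n_controls, replace=False),
        ]
    )
    return phenotypes.loc[np.sort(chosen)]
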