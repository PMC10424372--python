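"""Pre-analysis quality control on samples and variants.

Implements the standard GWAS-style filters applied before association:
variant call rate (< 0.9 removed), sample call rate (< 0.75 removed),
heterozygosity outliers (> 3 SD from the mean, two-sided), relatedness
(PLINK-style method-of-moments PI_HAT > 0.2), PCA outliers, exact-form
Hardy-Weinberg chi-square (P < 1e-6) and imputation INFO score (< 0.7).

The fixed filter order is: variant call rate -> sample call rate ->
heterozygosity -> relatedness -> PCA -> HWE -> INFO.  Each pass returns a
:class:`QCReport` with the removed ids, the reason, and the statistic
value, so the full funnel is reconstructible from the reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
from scipy import stats

from .io_formats import (
    MISSING,
    EstimationError,
    HaplotypePanel,
    ValidationError,
)

logger = logging.getLogger("neanderscan")


@dataclass
class QCThresholds:
    variant_call_rate_min: float = 0.9
    sample_call_rate_min: float = 0.75
    het_sd: float = 3.0
    pi_hat_max: float = 0.2
    hwe_p_min: float = 1e-6
    info_min: float = 0.7
    pca_k: int = 8
    pca_outlier_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in ("variant_call_rate_min", "sample_call_rate_min", "info_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("het_sd", "pca_outlier_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.pi_hat_max <= 1.0:
            raise ValidationError("pi_hat_max must be in [0, 1]")
        if not 0.0 < self.hwe_p_min < 1.0:
            raise ValidationError("hwe_p_min must be in (0, 1)")


@dataclass
class QCReport:
    """Outcome of one filter pass."""

    filter_name: str
    kind: str                       # "variant" | "sample"
    n_before: int
    n_after: int
    removed: list[tuple[str, str, float]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_before - len(self.removed) != self.n_after:
            raise ValidationError(
                f"{self.filter_name}: removed count inconsistent with before/after"
            )


def _report(name, kind, before, after, removed, notes=None) -> QCReport:
    rep = QCReport(
        filter_name=name, kind=kind, n_before=before, n_after=after,
        removed=removed, notes=notes or [],
    )
    logger.info(
        "qc %-22s %s: %d -> %d (removed %d)",
        name, kind, before, after, len(removed),
    )
    return rep


# ---------------------------------------------------------------------------
# Call-rate filters
# ---------------------------------------------------------------------------

def filter_variant_call_rate(
    panel: HaplotypePanel, min_rate: float = 0.9
) -> tuple[HaplotypePanel, QCReport]:
    """Remove variants with call rate strictly below ``min_rate``."""
    rate = panel.variant_call_rate()
    keep = rate >= min_rate
    removed = [
        (panel.variants[i].id, "call_rate", float(rate[i]))
        for i in np.flatnonzero(~keep)
    ]
    return panel.take_variants(keep), _report(
        "variant_call_rate", "variant", panel.n_variants, int(keep.sum()), removed
    )


def filter_sample_call_rate(
    panel: HaplotypePanel, min_rate: float = 0.75
) -> tuple[HaplotypePanel, QCReport]:
    """Remove samples with genotyping call rate strictly below ``min_rate``."""
    rate = panel.sample_call_rate()
    keep = rate >= min_rate
    removed = [
        (panel.samples[i], "call_rate", float(rate[i]))
        for i in np.flatnonzero(~keep)
    ]
    return panel.take_samples(keep), _report(
        "sample_call_rate", "sample", panel.n_samples, int(keep.sum()), removed
    )


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def sample_heterozygosity(panel: HaplotypePanel) -> np.ndarray:
    """Fraction of heterozygous genotypes per sample over non-missing sites."""
    g = panel.genotypes
    called = np.all(g != MISSING, axis=2)
    het = (g[:, :, 0] != g[:, :, 1]) & called
    with np.errstate(invalid="ignore"):
        return np.where(
            called.sum(axis=0) > 0,
            het.sum(axis=0) / np.maximum(called.sum(axis=0), 1),
            np.nan,
        )


def filter_sample_het(
    panel: HaplotypePanel, sd: float = 3.0
) -> tuple[HaplotypePanel, QCReport]:
    """Remove samples whose heterozygosity deviates > ``sd`` SDs from the mean.

    Applied two-sided: both excess heterozygosity (contamination) and
    deficit (inbreeding, genotyping artefacts) flag a sample.
    """
    notes = []
    if panel.n_samples < 3:
        notes.append("fewer than 3 samples: SD unstable, nothing removed")
        logger.warning("filter_sample_het: %s", notes[-1])
        return panel, _report(
            "heterozygosity", "sample", panel.n_samples, panel.n_samples, [], notes
        )
    het = sample_heterozygosity(panel)
    mean, std = np.nanmean(het), np.nanstd(het)
    if std == 0 or np.isnan(std):
        notes.append("zero heterozygosity SD: nothing removed")
        return panel, _report(
            "heterozygosity", "sample", panel.n_samples, panel.n_samples, [], notes
        )
    keep = np.abs(het - mean) <= sd * std
    keep &= ~np.isnan(het)
    keep |= np.isnan(het)  # samples with no calls are left to call-rate filters
    removed = [
        (panel.samples[i], "heterozygosity", float(het[i]))
        for i in np.flatnonzero(~keep)
    ]
    return panel.take_samples(keep), _report(
        "heterozygosity", "sample", panel.n_samples, int(keep.sum()), removed, notes
    )


# ---------------------------------------------------------------------------
# Relatedness (PLINK-style method-of-moments PI_HAT)
# ---------------------------------------------------------------------------

def _ibd_expectations(p: np.ndarray) -> tuple[float, float, float, float, float]:
    """Summed IBS-state probabilities under IBD 0/1 given allele freqs."""
    q = 1.0 - p
    e00 = float(np.sum(2 * p**2 * q**2))
    e10 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e20 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e11 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e21 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))
    return e00, e10, e20, e11, e21


def estimate_pi_hat(
    panel: HaplotypePanel, sample_i: int | str, sample_j: int | str
) -> float:
    """Method-of-moments IBD sharing between two samples.

    Observed identity-by-state counts are corrected by panel allele
    frequencies to moments of the IBD distribution; negative estimates
    are clamped to zero before normalisation.
    PI_HAT = P(IBD=2) + 0.5 P(IBD=1).
    """
    if isinstance(sample_i, str):
        sample_i = panel.samples.index(sample_i)
    if isinstance(sample_j, str):
        sample_j = panel.samples.index(sample_j)
    d = panel.dosages()
    freq = panel.allele_frequency(1)
    ok = (
        ~np.isnan(d[:, sample_i]) & ~np.isnan(d[:, sample_j])
        & (freq > 0) & (freq < 1)
    )
    if not np.any(ok):
        raise EstimationError(
            "no polymorphic, jointly called sites to estimate relatedness"
        )
    return _pi_hat_from_dosages(d[ok, sample_i], d[ok, sample_j], freq[ok])


def _pi_hat_from_dosages(di: np.ndarray, dj: np.ndarray, p: np.ndarray) -> float:
    diff = np.abs(di - dj)
    n2 = int(np.sum(diff == 0))
    n1 = int(np.sum(diff == 1))
    n0 = int(np.sum(diff == 2))
    m = len(p)
    e00, e10, e20, e11, e21 = _ibd_expectations(p)
    k0 = n0 / e00 if e00 > 0 else 0.0
    k1 = (n1 - k0 * e10) / e11 if e11 > 0 else 0.0
    k2 = (n2 - k0 * e20 - k1 * e21) / m
    k = np.clip([k0, k1, k2], 0.0, None)
    total = k.sum()
    if total <= 0:
        return 0.0
    k = k / total
    return float(np.clip(k[2] + 0.5 * k[1], 0.0, 1.0))


def filter_relatedness(
    panel: HaplotypePanel, max_pi_hat: float = 0.2
) -> tuple[HaplotypePanel, QCReport]:
    """Remove one member of each pair with PI_HAT above the threshold.

    The member with the lower genotyping call rate is dropped, the
    standard practice when the study design does not dictate otherwise.
    """
    d = panel.dosages()
    freq = panel.allele_frequency(1)
    poly = (freq > 0) & (freq < 1)
    if not np.any(poly):
        raise EstimationError("panel is monomorphic: relatedness not estimable")
    call_rate = panel.sample_call_rate()
    flagged: list[tuple[int, int, float]] = []
    for i, j in combinations(range(panel.n_samples), 2):
        ok = poly & ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
        if not np.any(ok):
            continue
        pi = _pi_hat_from_dosages(d[ok, i], d[ok, j], freq[ok])
        if pi > max_pi_hat:
            flagged.append((i, j, pi))
    to_remove: dict[int, float] = {}
    for i, j, pi in sorted(flagged, key=lambda t: -t[2]):
        if i in to_remove or j in to_remove:
            continue
        worse = i if call_rate[i] <= call_rate[j] else j
        to_remove[worse] = pi
    keep = np.ones(panel.n_samples, dtype=bool)
    removed = []
    for idx, pi in sorted(to_remove.items()):
        keep[idx] = False
        removed.append((panel.samples[idx], "pi_hat", float(pi)))
    return panel.take_samples(keep), _report(
        "relatedness", "sample", panel.n_samples, int(keep.sum()), removed
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg proportions (1 df).

    Returns ``(chi2, P)``.  Monomorphic tables return ``(0.0, 1.0)`` by
    convention.
    """
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValidationError("HWE test needs at least one genotype")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        logger.debug("hwe_test: monomorphic table, P = 1 by convention")
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def filter_hwe(
    panel: HaplotypePanel,
    min_p: float = 1e-6,
    control_mask: np.ndarray | None = None,
) -> tuple[HaplotypePanel, QCReport]:
    """Remove variants out of Hardy-Weinberg equilibrium (P < ``min_p``).

    When ``control_mask`` is given the test uses controls only, so true
    case-enriched signals are not discarded.
    """
    g = panel.genotypes
    if control_mask is not None:
        g = g[:, np.asarray(control_mask, dtype=bool), :]
        notes = ["HWE tested in controls only"]
    else:
        notes = ["HWE tested in all samples (no status supplied)"]
    dos = g.sum(axis=2)
    called = np.all(g != MISSING, axis=2)
    keep = np.ones(panel.n_variants, dtype=bool)
    removed = []
    for i in range(panel.n_variants):
        c = called[i]
        di = dos[i][c]
        n_bb = int(np.sum(di == 2))
        n_ab = int(np.sum(di == 1))
        n_aa = int(np.sum(di == 0))
        if n_aa + n_ab + n_bb == 0:
            continue
        _, p = hwe_test(n_aa, n_ab, n_bb)
        if p < min_p:
            keep[i] = False
            removed.append((panel.variants[i].id, "hwe", float(p)))
    return panel.take_variants(keep), _report(
        "hwe", "variant", panel.n_variants, int(keep.sum()), removed, notes
    )


# ---------------------------------------------------------------------------
# INFO score
# ---------------------------------------------------------------------------

def filter_info(
    panel: HaplotypePanel, min_info: float = 0.7
) -> tuple[HaplotypePanel, QCReport]:
    """Remove variants with imputation INFO score strictly below ``min_info``.

    Variants lacking the field (directly genotyped sites) are retained.
    """
    notes = []
    scores = np.array(
        [np.nan if v.info_score is None else v.info_score for v in panel.variants]
    )
    n_absent = int(np.isnan(scores).sum())
    if n_absent == panel.n_variants and panel.n_variants > 0:
        warnings.warn("no variant carries an INFO score; filter is a no-op",
                      stacklevel=2)
        notes.append("INFO score absent everywhere")
    elif n_absent:
        notes.append(f"{n_absent} variant(s) without INFO score retained")
    with np.errstate(invalid="ignore"):
        keep = np.isnan(scores) | (scores >= min_info)
    removed = [
        (panel.variants[i].id, "info", float(scores[i]))
        for i in np.flatnonzero(~keep)
    ]
    return panel.take_variants(keep), _report(
        "info", "variant", panel.n_variants, int(keep.sum()), removed, notes
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_genotypes(panel: HaplotypePanel, k: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Sample scores on the top ``k`` genotype principal components.

    The dosage matrix is mean-imputed, centred at 2p and scaled by
    sqrt(2p(1-p)); components come from the SVD of the standardised
    matrix and are ordered by decreasing eigenvalue.

    Returns ``(scores, eigenvalues)`` with ``scores`` of shape
    ``(n_samples, k)``.
    """
    if panel.n_samples < k + 1:
        raise ValidationError(
            f"PCA with k={k} needs at least {k + 1} samples, have {panel.n_samples}"
        )
    d = panel.dosages()  # (variants, samples)
    freq = panel.allele_frequency(1)
    poly = (freq > 0) & (freq < 1) & ~np.isnan(freq)
    d = d[poly]
    p = freq[poly]
    if d.shape[0] == 0:
        raise EstimationError("no polymorphic variants for PCA")
    centred = d - 2 * p[:, None]
    centred = np.where(np.isnan(centred), 0.0, centred)  # mean imputation
    scale = np.sqrt(2 * p * (1 - p))
    z = (centred / scale[:, None]).T  # samples x variants
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    rank = int(np.sum(s > 1e-9 * s[0])) if len(s) else 0
    if k > rank:
        warnings.warn(f"requested k={k} components but rank is {rank}; truncating",
                      stacklevel=2)
        k = rank
    eigvals = (s**2) / max(z.shape[0] - 1, 1)
    return u[:, :k] * s[:k], eigvals[:k]


def flag_pca_outliers(scores: np.ndarray, sd: float = 6.0) -> np.ndarray:
    """Boolean mask of samples > ``sd`` SDs from the mean on any component.

    The flag-and-recompute cycle is iterated once so that a gross outlier
    does not mask a second, milder one.
    """
    scores = np.asarray(scores, dtype=float)
    flagged = np.zeros(scores.shape[0], dtype=bool)
    for _ in range(2):
        rest = scores[~flagged]
        if rest.shape[0] < 3:
            break
        mean = rest.mean(axis=0)
        std = rest.std(axis=0)
        std[std == 0] = np.inf
        new = np.any(np.abs(scores - mean) > sd * std, axis=1) & ~flagged
        if not new.any():
            break
        flagged |= new
    return flagged


def filter_pca_outliers(
    panel: HaplotypePanel, k: int = 8, sd: float = 6.0
) -> tuple[HaplotypePanel, QCReport]:
    scores, _ = pca_genotypes(panel, k=k)
    flagged = flag_pca_outliers(scores, sd=sd)
    keep = ~flagged
    removed = [
        (panel.samples[i], "pca_outlier", float(np.max(np.abs(scores[i]))))
        for i in np.flatnonzero(flagged)
    ]
    return panel.take_samples(keep), _report(
        "pca_outliers", "sample", panel.n_samples, int(keep.sum()), removed
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_sample_qc(
    panel: HaplotypePanel,
    thresholds: QCThresholds | None = None,
    status: "Mapping[str, int] | None" = None,
    skip_relatedness: bool = False,
    skip_pca: bool = False,
) -> tuple[HaplotypePanel, list[QCReport]]:
    """Apply the full QC funnel in its fixed order and collect reports.

    ``status`` (sample id -> 1 case / 0 control), when given, restricts
    the Hardy-Weinberg test to controls; the mask is rebuilt after the
    sample-level filters so it always aligns with the surviving samples.
    """
    t = thresholds or QCThresholds()
    reports: list[QCReport] = []

    panel, rep = filter_variant_call_rate(panel, t.variant_call_rate_min)
    reports.append(rep)
    panel, rep = filter_sample_call_rate(panel, t.sample_call_rate_min)
    reports.append(rep)
    panel, rep = filter_sample_het(panel, t.het_sd)
    reports.append(rep)
    if not skip_relatedness:
        panel, rep = filter_relatedness(panel, t.pi_hat_max)
        reports.append(rep)
    if not skip_pca and panel.n_samples >= t.pca_k + 1:
        panel, rep = filter_pca_outliers(panel, k=t.pca_k, sd=t.pca_outlier_sd)
        reports.append(rep)
    control_mask = None
    if status is not None:
        control_mask = np.array([status.get(s, 0) == 0 for s in panel.samples])
    panel, rep = filter_hwe(panel, t.hwe_p_min, control_mask=control_mask)
    reports.append(rep)
    panel, rep = filter_info(panel, t.info_min)
    reports.append(rep)
    return panel, reports
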