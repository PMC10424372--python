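"""Case-control logistic association, LD pruning and multiple testing.

Per-SNP covariate-adjusted logistic regression (Wald tests, matching the
"OR (95% CI) P" reporting convention), r-squared / D' linkage
disequilibrium, greedy P-ordered pruning at r2 > 0.5, independent-test
counting at r2 < 0.8 for Bonferroni thresholds, the genomic inflation
factor lambda, and the cross-study effect-direction concordance rule
used when only summary statistics are available.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .io_formats import SummaryStatRecord, ValidationError

logger = logging.getLogger("neanderscan")

CI_MULTIPLIER = 1.959964  # two-sided 95% normal quantile
SEPARATION_BETA = 15.0    # |beta| beyond which the fit is flagged as separated
_NULL_MEDIAN_CHI2 = float(stats.chi2.ppf(0.5, df=1))  # 0.454936...


@dataclass
class MultipleTestingConfig:
    alpha: float = 0.05
    prune_r2: float = 0.5          # LD-pruning threshold for reporting
    independence_r2: float = 0.8   # threshold defining independent tests

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        for name in ("prune_r2", "independence_r2"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1]")


@dataclass
class AssociationResult:
    """Per-SNP logistic association estimate."""

    snp: str
    n_cases: int
    n_controls: int
    beta: float                 # log-odds per effect allele
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float
    study: str = ""
    effect_allele: str = "alt"
    maf: float = float("nan")
    pos: int = -1
    converged: bool = True
    separation: bool = False


class SeparationWarning(UserWarning):
    """Raised when a logistic fit shows complete or quasi-separation."""


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------

def _irls(X: np.ndarray, y: np.ndarray, max_iter: int = 25, tol: float = 1e-8):
    """Newton/IRLS maximum likelihood for the logistic model.

    Converges when the largest score component falls below ``tol``;
    diverging coefficients (|beta| > 15) are reported as separation.
    Returns (beta, se, converged, separated).
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = separated = False
    for _ in range(max_iter):
        mu = expit(X @ beta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) > SEPARATION_BETA:
            separated = True
            break
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)
    return beta, se, converged, separated


def fit_logistic(
    dosages: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    snp: str = "",
    study: str = "",
    effect_allele: str = "alt",
    covariate_names: list[str] | None = None,
    pos: int = -1,
) -> AssociationResult:
    """Covariate-adjusted logistic regression of case status on dosage.

    The design matrix is [intercept, dosage, covariates]; the reported
    effect is the dosage coefficient with its Wald SE from the observed
    information, OR = exp(beta) and a 95% CI of exp(beta +/- 1.96 SE).
    Complete or quasi-separation is flagged (with a warning) rather than
    silently reported; rank-deficient designs raise an error naming the
    offending columns.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(status, dtype=float)
    if d.shape[0] != y.shape[0]:
        raise ValidationError("dosage and status lengths differ")
    n_cases = int(np.sum(y == 1))
    n_controls = int(np.sum(y == 0))
    if n_cases == 0 or n_controls == 0:
        raise ValidationError("need at least one case and one control")
    if np.isnan(d).any():
        fill = np.nanmean(d)
        d = np.where(np.isnan(d), fill, d)

    cols = [np.ones_like(y), d]
    names = ["intercept", "dosage"]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
        names.extend(
            covariate_names
            or [f"covar{i}" for i in range(cov.shape[1])]
        )
    X = np.column_stack(cols)

    # rank check with column attribution via QR
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        raise ValidationError(
            "design matrix is rank deficient; offending column(s): "
            + ", ".join(np.array(names)[bad])
        )

    beta, se, converged, separated = _irls(X, y)
    if separated:
        warnings.warn(
            f"logistic fit for {snp or 'SNP'} shows complete or "
            "quasi-separation; estimates are unreliable",
            SeparationWarning,
            stacklevel=2,
        )
    b, s = float(beta[1]), float(se[1])
    z = b / s if s > 0 and np.isfinite(s) else 0.0
    alt_freq = float(np.mean(d)) / 2.0

    def _exp(x: float) -> float:  # saturates instead of overflowing (separation)
        return math.exp(min(x, 709.0)) if np.isfinite(x) else float("inf")

    return AssociationResult(
        snp=snp,
        n_cases=n_cases,
        n_controls=n_controls,
        beta=b,
        se=s,
        odds_ratio=_exp(b),
        ci_low=0.0 if not np.isfinite(s) else _exp(b - CI_MULTIPLIER * s),
        ci_high=_exp(b + CI_MULTIPLIER * s),
        wald_p=float(min(max(2.0 * stats.norm.sf(abs(z)), 5e-324), 1.0)),
        study=study,
        effect_allele=effect_allele,
        maf=min(alt_freq, 1.0 - alt_freq),
        pos=pos,
        converged=converged,
        separation=separated,
    )


def logistic_scan(
    dosage_matrix: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    max_iter: int = 25,
    tol: float = 1e-8,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched per-SNP logistic Wald scan sharing one covariate set.

    Fits the same model as :func:`fit_logistic` for every row of
    ``dosage_matrix`` (shape ``(n_snps, n_samples)``) with a vectorised
    Newton iteration, which is what makes genome-wide null calibration
    runs tractable.  Returns ``(beta, se, chi2)`` arrays; rows that
    diverge (separation) get NaN.
    """
    y = np.asarray(status, dtype=float)
    D_all = np.asarray(dosage_matrix, dtype=float)
    n_snps, n = D_all.shape
    if covariates is None:
        C = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        C = np.column_stack([np.ones(n), cov])
    kc = C.shape[1]
    k = kc + 1  # covariate block + dosage
    # precomputed C-column products for the batched information matrix
    cc_pairs = [(a, b) for a in range(kc) for b in range(a, kc)]
    CC = np.column_stack([C[:, a] * C[:, b] for a, b in cc_pairs])
    ybar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    b0_start = math.log(ybar / (1 - ybar))

    def _hessian(w: np.ndarray, Dc: np.ndarray) -> np.ndarray:
        m = w.shape[0]
        H = np.empty((m, k, k))
        blocks = w @ CC                      # (m, n_pairs)
        for t, (a, b) in enumerate(cc_pairs):
            H[:, a, b] = H[:, b, a] = blocks[:, t]
        wd = w * Dc
        cross = wd @ C                       # (m, kc)
        H[:, :kc, k - 1] = cross
        H[:, k - 1, :kc] = cross
        H[:, k - 1, k - 1] = np.sum(wd * Dc, axis=1)
        return H

    beta_out = np.full(n_snps, np.nan)
    se_out = np.full(n_snps, np.nan)
    for lo in range(0, n_snps, chunk):
        hi = min(lo + chunk, n_snps)
        m = hi - lo
        B = np.zeros((m, k))
        B[:, 0] = b0_start
        active = np.arange(m)
        for _ in range(max_iter):
            Dc = D_all[lo:hi][active]
            Ba = B[active]
            eta = Ba[:, :-1] @ C.T + Ba[:, -1:] * Dc  # (a, n)
            mu = expit(eta)
            resid = y[None, :] - mu
            score = np.column_stack([resid @ C, np.sum(resid * Dc, axis=1)])
            unconverged = np.max(np.abs(score), axis=1) >= tol
            if not unconverged.any():
                break
            active = active[unconverged]
            Dc, mu, score = Dc[unconverged], mu[unconverged], score[unconverged]
            w = mu * (1.0 - mu)
            H = _hessian(w, Dc)
            try:
                step = np.linalg.solve(H, score[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                step = np.zeros_like(score)
                keep = np.ones(len(active), dtype=bool)
                for r in range(len(active)):
                    try:
                        step[r] = np.linalg.solve(H[r], score[r])
                    except np.linalg.LinAlgError:
                        keep[r] = False
                active, step = active[keep], step[keep]
                if len(active) == 0:
                    break
            B[active] += step
            sane = np.max(np.abs(B[active]), axis=1) <= SEPARATION_BETA
            active = active[sane]
            if len(active) == 0:
                break
        ok = np.max(np.abs(B), axis=1) <= SEPARATION_BETA
        idx = np.flatnonzero(ok)
        if len(idx):
            Dc = D_all[lo:hi][idx]
            Bo = B[idx]
            mu = expit(Bo[:, :-1] @ C.T + Bo[:, -1:] * Dc)
            w = np.clip(mu * (1 - mu), 1e-12, None)
            H = _hessian(w, Dc)
            try:
                cov_dd = np.linalg.inv(H)[:, k - 1, k - 1]
            except np.linalg.LinAlgError:
                cov_dd = np.full(len(idx), np.nan)
                for r in range(len(idx)):
                    try:
                        cov_dd[r] = np.linalg.inv(H[r])[k - 1, k - 1]
                    except np.linalg.LinAlgError:
                        pass
            good = cov_dd > 0
            beta_out[lo + idx[good]] = Bo[good, k - 1]
            se_out[lo + idx[good]] = np.sqrt(cov_dd[good])
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (beta_out / se_out) ** 2
    return beta_out, se_out, chi2


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage (or haplotype) vectors.

    Monomorphic input is undefined; it is logged and treated as r2 = 0
    so that pruning never links through an uninformative site.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if len(a) < 2 or np.var(a) == 0 or np.var(b) == 0:
        logger.debug("ld_r2: monomorphic or empty input, returning 0")
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_dprime(h1: np.ndarray, h2: np.ndarray) -> float:
    """Normalised disequilibrium coefficient D' from phased haplotypes."""
    a = np.asarray(h1, dtype=float)
    b = np.asarray(h2, dtype=float)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    if len(a) == 0:
        return float("nan")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        logger.debug("ld_dprime: monomorphic input, undefined")
        return float("nan")
    pab = np.mean(a * b)
    d = pab - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax == 0:
        return float("nan")
    return float(abs(d) / dmax)


@dataclass
class LDMatrix:
    """Pairwise r2 among a SNP set (symmetric, unit diagonal)."""

    ids: list[str]
    r2: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.ids)
        if self.r2.shape != (m, m):
            raise ValidationError("LD matrix shape does not match id list")
        self._index = {snp: i for i, snp in enumerate(self.ids)}

    def lookup(self, snp_a: str, snp_b: str) -> float:
        try:
            return float(self.r2[self._index[snp_a], self._index[snp_b]])
        except KeyError as exc:
            raise ValidationError(f"no LD entry for SNP {exc.args[0]!r}") from exc


def ld_matrix(
    dosage_matrix: np.ndarray,
    ids: list[str],
    positions: np.ndarray | None = None,
) -> LDMatrix:
    """All-pairs dosage r2 for a SNP set (rows = SNPs)."""
    D = np.asarray(dosage_matrix, dtype=float)
    if np.isnan(D).any():
        means = np.nanmean(D, axis=1)
        D = np.where(np.isnan(D), means[:, None], D)
    sd = D.std(axis=1)
    mono = sd == 0
    if mono.any():
        logger.debug("ld_matrix: %d monomorphic site(s) set to r2=0", mono.sum())
    Z = (D - D.mean(axis=1, keepdims=True))
    Z[~mono] /= sd[~mono][:, None]
    Z[mono] = 0.0
    r = (Z @ Z.T) / D.shape[1]
    r2 = np.clip(r * r, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(ids=list(ids), r2=r2, positions=positions)


# ---------------------------------------------------------------------------
# Pruning and independent-test counting
# ---------------------------------------------------------------------------

def greedy_prune(
    results: list[AssociationResult],
    ld: LDMatrix,
    r2_threshold: float = 0.5,
) -> list[AssociationResult]:
    """Keep, per LD block, the SNP with the lowest association P.

    Results are visited by ascending Wald P (position breaks ties); each
    kept SNP removes every remaining SNP in LD with it (r2 > threshold).
    """
    order = sorted(
        range(len(results)),
        key=lambda i: (results[i].wald_p, results[i].pos, results[i].snp),
    )
    kept: list[int] = []
    removed = np.zeros(len(results), dtype=bool)
    for i in order:
        if removed[i]:
            continue
        kept.append(i)
        for j in order:
            if j == i or removed[j]:
                continue
            if ld.lookup(results[i].snp, results[j].snp) > r2_threshold:
                removed[j] = True
    kept_sorted = sorted(kept, key=lambda i: (results[i].pos, results[i].snp))
    logger.info("greedy_prune: kept %d of %d at r2 > %g",
                len(kept_sorted), len(results), r2_threshold)
    return [results[i] for i in kept_sorted]


def count_independent(
    ld: LDMatrix,
    r2_threshold: float = 0.8,
) -> int:
    """Number of independent SNPs by position-ordered greedy selection.

    A SNP is kept when its r2 with every previously kept SNP does not
    exceed the threshold; the kept-set size is the Bonferroni ``m``.
    """
    m = len(ld.ids)
    if m == 0:
        return 0
    if ld.positions is not None:
        order = np.argsort(np.asarray(ld.positions), kind="mergesort")
    else:
        order = np.arange(m)
    kept: list[int] = []
    for i in order:
        if all(ld.r2[i, j] <= r2_threshold for j in kept):
            kept.append(int(i))
    return len(kept)


def count_independent_from_dosages(
    dosage_matrix: np.ndarray,
    positions: np.ndarray,
    r2_threshold: float = 0.8,
    window_bp: int | None = None,
) -> int:
    """Independent-test count without materialising the full LD matrix.

    Greedy in position order comparing each SNP only against kept SNPs
    within ``window_bp`` (LD beyond a physical window is negligible in
    the panels this targets); ``window_bp=None`` compares against all.
    """
    D = np.asarray(dosage_matrix, dtype=float)
    pos = np.asarray(positions)
    order = np.argsort(pos, kind="mergesort")
    D = D[order]
    pos = pos[order]
    mean = D.mean(axis=1, keepdims=True)
    sd = D.std(axis=1)
    Z = D - mean
    nz = sd > 0
    Z[nz] /= sd[nz][:, None]
    Z[~nz] = 0.0
    n = D.shape[1]
    kept: list[int] = []
    for i in range(len(pos)):
        lo = 0
        if window_bp is not None:
            lo_pos = pos[i] - window_bp
            import bisect
            lo = bisect.bisect_left([pos[k] for k in kept], lo_pos)
        compare = kept[lo:]
        if compare:
            r = (Z[compare] @ Z[i]) / n
            if np.any(r * r > r2_threshold):
                continue
        kept.append(i)
    return len(kept)


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def genomic_lambda(
    p: np.ndarray | None = None, chi2_stats: np.ndarray | None = None
) -> float:
    """Genomic inflation factor: median chi-square over the null median.

    Accepts either p-values (converted through the upper-tail inverse
    1-df chi-square) or chi-square statistics directly; lambda ~ 1 means
    no systematic inflation.
    """
    if (p is None) == (chi2_stats is None):
        raise ValueError("pass exactly one of p or chi2_stats")
    if p is not None:
        p = np.asarray(p, dtype=float)
        p = p[np.isfinite(p)]
        if p.size == 0:
            raise ValueError("empty p-value vector")
        stats_vec = stats.chi2.isf(p, df=1)
    else:
        stats_vec = np.asarray(chi2_stats, dtype=float)
        stats_vec = stats_vec[np.isfinite(stats_vec)]
        if stats_vec.size == 0:
            raise ValueError("empty chi-square vector")
    if stats_vec.size < 100:
        warnings.warn(
            f"genomic lambda from only {stats_vec.size} tests is unstable",
            stacklevel=2,
        )
    return float(np.median(stats_vec) / _NULL_MEDIAN_CHI2)


def concordance_filter(
    records: list[SummaryStatRecord], alpha: float = 0.05
) -> bool:
    """Cross-study support rule for summary-statistics analyses.

    Passes when every study reports P < ``alpha`` and all effects point
    the same way for the same effect allele.  Mismatched effect alleles
    raise: effects are never silently flipped.
    """
    if len(records) < 2:
        raise ValidationError("concordance requires at least two studies")
    alleles = {r.effect_allele for r in records}
    if len(alleles) != 1:
        raise ValidationError(
            f"effect alleles disagree across studies ({sorted(alleles)}); "
            "harmonise alleles before testing concordance"
        )
    if any(r.p >= alpha for r in records):
        return False
    signs = {np.sign(r.beta) for r in records}
    return signs in ({1.0}, {-1.0})
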