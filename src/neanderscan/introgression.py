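"""Calling Neandertal-introgressed SNPs (aSNPs) from a haplotype panel.

A site is an aSNP *candidate* when (a) one of its alleles is shared
between the archaic genome and at least one non-African population,
(b) that allele is absent from the African outgroup, and (c) the archaic
individual carries it in homozygous state.  Criterion (d) — admixture
rather than incomplete lineage sorting (ILS) — is decided at the level
of per-haplotype *segments* of consecutive candidate markers: under ILS
a shared segment has had the full archaic-modern divergence time
``G_div`` to be shortened by recombination, so its expected length is

    E[L] = 1 / (r_bp * G_div),      r_bp = local rate (cM/Mb) * 1e-8,

and the probability of observing a segment at least as long under ILS is
the exponential tail ``p = exp(-l / E[L])``.  Segment p-values are
corrected with the Benjamini-Hochberg step-up and haplotype segments
with adjusted P < 0.05 are declared introgressed; an aSNP is a candidate
lying on at least one such segment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    MISSING,
    ArchaicGenome,
    ConfigurationError,
    GeneticMap,
    HaplotypePanel,
    TruthTract,
    local_rate,
)

logger = logging.getLogger("neanderscan")

_UNTESTABLE = math.inf  # expected-length sentinel when the local rate is 0


@dataclass
class ILSModelConfig:
    """Parameters of the ILS segment-length null model.

    ``g_div`` is the *total* number of generations on the two branches
    separating the archaic and modern lineages since their divergence
    (2 x divergence time / generation time): recombination breaks the
    shared segment on both branches.
    """

    divergence_years: float = 550_000.0
    generation_years: float = 29.0
    tail_model: str = "exponential"
    min_markers_per_segment: int = 2
    conservative_two_maps: bool = False
    g_div_override: float | None = None

    def __post_init__(self) -> None:
        if self.min_markers_per_segment < 1:
            raise ValueError("min_markers_per_segment must be >= 1")
        if self.tail_model != "exponential":
            raise NotImplementedError(
                f"tail model {self.tail_model!r} not implemented"
            )
        if self.g_div <= 0:
            raise ValueError("G_div must be positive")

    @property
    def g_div(self) -> float:
        if self.g_div_override is not None:
            return self.g_div_override
        return 2.0 * self.divergence_years / self.generation_years


@dataclass(frozen=True)
class ASNPCandidate:
    """A site passing criteria (a)-(c), prior to the segment-length test."""

    index: int                       # position in the panel's variant list
    id: str
    pos: int                         # 0-based
    archaic_allele: int              # 0 = ref, 1 = alt
    crit_a: bool
    crit_b: bool
    crit_c: bool
    freqs: dict = field(hash=False, default_factory=dict)  # pop -> archaic-allele freq


@dataclass
class ArchaicSegment:
    """A run of candidate markers carried by one haplotype."""

    segment_id: int
    sample: str
    side: int
    start: int                       # position of the first marker (0-based)
    end: int                         # position of the last marker
    n_markers: int
    mean_rate: float                 # cM/Mb over [start, end)
    expected_ils_length: float       # bp; inf = untestable (zero local rate)
    p_raw: float
    p_adj: float = float("nan")

    @property
    def haplotype(self) -> str:
        return f"{self.sample}_h{self.side}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ASNPCall:
    """A candidate confirmed by at least one significant segment."""

    candidate: ASNPCandidate
    segment_ids: tuple[int, ...]
    min_p_adj: float

    @property
    def pos(self) -> int:
        return self.candidate.pos

    @property
    def id(self) -> str:
        return self.candidate.id


# ---------------------------------------------------------------------------
# Site criteria (a)-(c)
# ---------------------------------------------------------------------------

def apply_site_criteria(
    panel: HaplotypePanel, archaic: ArchaicGenome
) -> list[ASNPCandidate]:
    """Sites where the archaic-homozygous allele is absent from Africa and
    present in at least one non-African population.

    A site with a missing or heterozygous archaic genotype is never a
    candidate.  Absence from Africa requires at least one called African
    allele; with no African calls the absence cannot be established and
    the site is skipped (conservative).
    """
    if panel.african_pop is None:
        raise ConfigurationError("panel has no designated African population")
    if panel.african_pop not in panel.populations:
        raise ConfigurationError(
            f"African population {panel.african_pop!r} has no samples in panel"
        )
    if archaic.n_variants != panel.n_variants:
        raise ConfigurationError("archaic genome is not aligned to the panel")

    hom = archaic.homozygous_allele()          # (n_variants,), -1 when ineligible
    pops = panel.population_labels
    nonafr = [p for p in pops if p != panel.african_pop]
    if not nonafr:
        raise ConfigurationError("panel has no non-African population")

    g = panel.genotypes
    afr_idx = panel.pop_indices(panel.african_pop)
    g_afr = g[:, afr_idx, :]

    freqs: dict[str, np.ndarray] = {}
    for pop in pops:
        gp = g[:, panel.pop_indices(pop), :]
        called = gp != MISSING
        n_called = called.sum(axis=(1, 2))
        match = (gp == hom[:, None, None]) & called
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop] = np.where(
                n_called > 0, match.sum(axis=(1, 2)) / np.maximum(n_called, 1), np.nan
            )

    afr_called = (g_afr != MISSING).sum(axis=(1, 2))
    crit_c = hom != MISSING
    crit_b = crit_c & (afr_called > 0) & (freqs[panel.african_pop] == 0.0)
    crit_a = crit_c & np.any(
        np.stack([freqs[p] > 0 for p in nonafr]), axis=0
    )
    eligible = crit_a & crit_b & crit_c

    candidates = [
        ASNPCandidate(
            index=int(i),
            id=panel.variants[i].id,
            pos=int(panel.variants[i].pos),
            archaic_allele=int(hom[i]),
            crit_a=True,
            crit_b=True,
            crit_c=True,
            freqs={p: float(freqs[p][i]) for p in pops},
        )
        for i in np.flatnonzero(eligible)
    ]
    logger.info(
        "apply_site_criteria: %d candidate site(s) of %d",
        len(candidates), panel.n_variants,
    )
    return candidates


# ---------------------------------------------------------------------------
# Segment construction
# ---------------------------------------------------------------------------

def build_segments(
    panel: HaplotypePanel,
    candidates: list[ASNPCandidate],
    cfg: ILSModelConfig | None = None,
    genetic_map: GeneticMap | None = None,
    genetic_map2: GeneticMap | None = None,
    rate_cm_per_mb: float | None = None,
) -> list[ArchaicSegment]:
    """Per-haplotype maximal runs of candidate markers, with ILS p-values.

    On each non-African haplotype, a run collects consecutive candidate
    sites at which the haplotype carries the archaic allele; a candidate
    site where it carries the non-archaic allele breaks the run (missing
    calls neither extend nor break it).  Runs shorter than
    ``min_markers_per_segment`` markers are discarded.  The segment
    interval spans first to last marker.

    The local recombination rate comes from ``genetic_map`` or the
    constant ``rate_cm_per_mb``; with ``conservative_two_maps`` set and a
    second map supplied, the larger of the two expected ILS lengths is
    used (harder to reject ILS).  Adjusted p-values are filled in by
    Benjamini-Hochberg over all segments built here.
    """
    cfg = cfg or ILSModelConfig()
    if genetic_map is None and rate_cm_per_mb is None:
        raise ConfigurationError("need a genetic map or a constant rate")
    if panel.african_pop is None:
        raise ConfigurationError("panel has no designated African population")

    cand_idx = np.array([c.index for c in candidates], dtype=np.int64)
    cand_pos = np.array([c.pos for c in candidates], dtype=np.int64)
    if len(cand_pos) > 1 and np.any(np.diff(cand_pos) <= 0):
        order = np.argsort(cand_pos)
        cand_idx, cand_pos = cand_idx[order], cand_pos[order]
        candidates = [candidates[i] for i in order]
    cand_allele = np.array([c.archaic_allele for c in candidates], dtype=np.int8)

    nonafr_samples = np.flatnonzero(
        np.asarray(panel.populations) != panel.african_pop
    )
    segments: list[ArchaicSegment] = []
    if len(candidates) == 0:
        return segments

    geno_c = panel.genotypes[cand_idx]  # (n_cand, n_samples, 2)
    seg_id = 0
    for s in nonafr_samples:
        for side in (0, 1):
            alleles = geno_c[:, s, side]
            carries = alleles == cand_allele
            breaks = (alleles != cand_allele) & (alleles != MISSING)
            run_start = None
            run_len = 0
            last_marker = None
            for k in range(len(candidates) + 1):
                at_end = k == len(candidates)
                if not at_end and carries[k]:
                    if run_start is None:
                        run_start = k
                        run_len = 0
                    run_len += 1
                    last_marker = k
                elif at_end or breaks[k]:
                    if run_start is not None and run_len >= cfg.min_markers_per_segment:
                        segments.append(
                            _make_segment(
                                seg_id, panel.samples[s], side,
                                int(cand_pos[run_start]), int(cand_pos[last_marker]),
                                run_len, cfg, genetic_map, genetic_map2,
                                rate_cm_per_mb,
                            )
                        )
                        seg_id += 1
                    run_start, run_len, last_marker = None, 0, None
                # missing call: run state unchanged
    if segments:
        p_adj = bh_adjust(np.array([s.p_raw for s in segments]))
        for s, p in zip(segments, p_adj):
            s.p_adj = float(p)
    logger.info("build_segments: %d segment(s) on %d haplotype(s)",
                len(segments), 2 * len(nonafr_samples))
    return segments


def _make_segment(
    seg_id, sample, side, start, end, n_markers,
    cfg, gmap, gmap2, rate,
) -> ArchaicSegment:
    if end > start:
        if gmap is not None:
            rbar = local_rate(gmap, start, end)
            if cfg.conservative_two_maps and gmap2 is not None:
                rbar2 = local_rate(gmap2, start, end)
                el = max(
                    expected_ils_length(cfg, rbar),
                    expected_ils_length(cfg, rbar2),
                )
                rbar = min(rbar, rbar2)
            else:
                el = expected_ils_length(cfg, rbar)
        else:
            rbar = float(rate)
            el = expected_ils_length(cfg, rbar)
    else:  # single-marker segment (only when min_markers_per_segment == 1)
        rbar = float(rate) if gmap is None else 0.0
        el = _UNTESTABLE
    p_raw = ils_pvalue(end - start, el)
    return ArchaicSegment(
        segment_id=seg_id, sample=sample, side=side,
        start=start, end=end, n_markers=n_markers,
        mean_rate=rbar, expected_ils_length=el, p_raw=p_raw,
    )


# ---------------------------------------------------------------------------
# ILS length model
# ---------------------------------------------------------------------------

def expected_ils_length(cfg: ILSModelConfig, mean_rate_cm_per_mb: float) -> float:
    """Expected length (bp) of an ILS-shared segment at the local rate.

    ``E[L] = 1/(r_bp * G_div)``; a zero local rate returns the infinite
    sentinel: such a segment cannot reject ILS and gets ``p_raw = 1``.
    """
    if mean_rate_cm_per_mb < 0:
        raise ValueError("recombination rate must be non-negative")
    if mean_rate_cm_per_mb == 0:
        logger.debug("expected_ils_length: zero local rate, segment untestable")
        return _UNTESTABLE
    r_bp = mean_rate_cm_per_mb * 1e-8
    return 1.0 / (r_bp * cfg.g_div)


def ils_pvalue(length_bp: float, expected_length_bp: float) -> float:
    """P(segment length >= l | ILS) under the exponential tail model.

    Strictly decreasing in ``l`` with ``p(0) = 1``; the infinite
    expected-length sentinel yields ``p = 1`` (untestable segment).
    """
    if not np.isfinite(length_bp) or length_bp < 0:
        raise ValueError(f"segment length must be finite and >= 0, got {length_bp}")
    if math.isinf(expected_length_bp):
        return 1.0
    if not expected_length_bp > 0 or not np.isfinite(expected_length_bp):
        raise ValueError(
            f"expected length must be positive and finite, got {expected_length_bp}"
        )
    p = math.exp(-length_bp / expected_length_bp)
    return max(p, 5e-324)  # keep p in (0, 1]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved).

    ``adj_i = min_{j >= i} (m * p_(j) / j)`` capped at 1, where ``p_(j)``
    is the j-th smallest raw p-value.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_asnps(
    candidates: list[ASNPCandidate],
    segments: list[ArchaicSegment],
    alpha: float = 0.05,
) -> list[ASNPCall]:
    """aSNPs: candidates lying on >= 1 segment with adjusted P < ``alpha``.

    Segment support is inclusive of both end markers.  Output is sorted
    by position with the supporting segment ids attached.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    sig = [s for s in segments if s.p_adj < alpha]
    if not sig or not candidates:
        return []
    order = np.argsort([c.pos for c in candidates])
    cands = [candidates[i] for i in order]
    pos = np.array([c.pos for c in cands], dtype=np.int64)
    support: dict[int, list[int]] = {}
    best: dict[int, float] = {}
    for s in sig:
        lo = int(np.searchsorted(pos, s.start, side="left"))
        hi = int(np.searchsorted(pos, s.end, side="right"))
        for k in range(lo, hi):
            support.setdefault(k, []).append(s.segment_id)
            best[k] = min(best.get(k, 1.0), s.p_adj)
    calls = [
        ASNPCall(
            candidate=cands[k],
            segment_ids=tuple(support[k]),
            min_p_adj=best[k],
        )
        for k in sorted(support)
    ]
    logger.info("call_asnps: %d aSNP(s) from %d candidate(s) on %d significant "
                "segment(s)", len(calls), len(candidates), len(sig))
    return calls


# ---------------------------------------------------------------------------
# Truth-based evaluation (for simulated panels)
# ---------------------------------------------------------------------------

def evaluate_calls(
    calls: list[ASNPCall],
    truth_tracts: list[TruthTract],
    marker_positions: np.ndarray,
) -> dict:
    """Precision / sensitivity of called aSNPs against simulator truth.

    A *true introgressed site* is an archaic-marker position covered by
    at least one truth tract of introgressed origin.  Precision is the
    fraction of called positions that are true introgressed sites;
    sensitivity is the fraction of true introgressed sites called.
    """
    intro = _merge(
        [(t.start, t.end) for t in truth_tracts if t.origin == "introgressed"]
    )
    marker_positions = np.asarray(marker_positions, dtype=np.int64)
    true_sites = marker_positions[_covered(marker_positions, intro)]
    called_pos = np.array(sorted({c.pos for c in calls}), dtype=np.int64)
    if len(called_pos) == 0:
        return {"precision": float("nan"), "sensitivity": 0.0,
                "n_called": 0, "n_true": int(len(true_sites))}
    tp = int(np.isin(called_pos, true_sites).sum())
    return {
        "precision": tp / len(called_pos),
        "sensitivity": tp / len(true_sites) if len(true_sites) else float("nan"),
        "n_called": int(len(called_pos)),
        "n_true": int(len(true_sites)),
    }


def _merge(intervals):
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def _covered(pos: np.ndarray, intervals) -> np.ndarray:
    if not intervals:
        return np.zeros(len(pos), dtype=bool)
    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])
    idx = np.searchsorted(starts, pos, side="right") - 1
    return (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
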