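"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
All internal coordinates are **0-based, half-open**.  VCF positions are
1-based and are converted on read/write; BED intervals are already
half-open.  The functions in this module are the only code that changes
coordinate systems.

The in-memory substrate is :class:`HaplotypePanel` — phased alleles for
the modern samples with per-sample population labels — plus an
:class:`ArchaicGenome` aligned to the same variants for the single
archaic (Neandertal) individual.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("neanderscan")

MISSING = -1  # allele index for a missing call


# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------

class NeanderscanError(Exception):
    """Base class for errors raised by this package."""


class VCFParseError(NeanderscanError):
    """A VCF body line could not be parsed."""


class ConfigurationError(NeanderscanError):
    """Inconsistent user configuration (labels, sample maps, ids)."""


class ValidationError(NeanderscanError):
    """An input violated a structural invariant."""


class SchemaError(NeanderscanError):
    """A tabular input is missing mandatory columns."""


class EstimationError(NeanderscanError):
    """A statistic could not be estimated from the data given."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """A biallelic single-nucleotide variant (site metadata only).

    ``pos`` is the 0-based internal coordinate.  Genotypes live in the
    owning :class:`HaplotypePanel` so that per-site and per-sample
    operations stay vectorised.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    info_score: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"{self.id}: ref equals alt ({self.ref})")


@dataclass
class HaplotypePanel:
    """Phased diploid genotypes for one chromosome.

    Attributes
    ----------
    variants:
        Ordered :class:`VariantRecord` list, positions strictly increasing.
    samples:
        Sample identifiers.
    populations:
        Per-sample population label, aligned with ``samples``.
    genotypes:
        ``int8`` array of shape ``(n_variants, n_samples, 2)`` holding
        allele indices (0 = ref, 1 = alt, -1 = missing).
    phased:
        Boolean array ``(n_variants, n_samples)``; modern samples used in
        segment building must be phased.
    african_pop:
        The population label designated as the African outgroup.
    """

    chrom: str
    variants: list[VariantRecord]
    samples: list[str]
    populations: list[str]
    genotypes: np.ndarray
    phased: np.ndarray | None = None
    african_pop: str | None = None
    _positions: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_var, n_samp = len(self.variants), len(self.samples)
        if self.genotypes.shape != (n_var, n_samp, 2):
            raise ValidationError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{n_var} variants x {n_samp} samples"
            )
        if len(self.populations) != n_samp:
            raise ValidationError("population labels do not align with samples")
        if self.phased is None:
            self.phased = np.ones((n_var, n_samp), dtype=bool)
        pos = self.positions
        if n_var > 1 and not np.all(np.diff(pos) > 0):
            raise ValidationError("variant positions must be strictly increasing")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def positions(self) -> np.ndarray:
        if self._positions is None or len(self._positions) != len(self.variants):
            self._positions = np.array([v.pos for v in self.variants], dtype=np.int64)
        return self._positions

    def pop_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.populations) == label)

    @property
    def population_labels(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    def haplotype(self, sample: int | str, side: int) -> np.ndarray:
        """Allele indices along the chromosome for one haplotype."""
        if isinstance(sample, str):
            sample = self.samples.index(sample)
        return self.genotypes[:, sample, side]

    def dosages(self) -> np.ndarray:
        """Alt-allele dosage matrix ``(n_variants, n_samples)``, NaN = missing."""
        g = self.genotypes
        d = g.sum(axis=2).astype(float)
        d[np.any(g == MISSING, axis=2)] = np.nan
        return d

    def allele_frequency(self, allele: int = 1, pop: str | None = None) -> np.ndarray:
        """Per-variant frequency of ``allele`` among non-missing calls."""
        g = self.genotypes
        if pop is not None:
            g = g[:, self.pop_indices(pop), :]
        called = g != MISSING
        n_called = called.sum(axis=(1, 2))
        n_allele = ((g == allele) & called).sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, n_allele / np.maximum(n_called, 1), np.nan)

    # -- subsetting ---------------------------------------------------------

    def take_variants(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypePanel(
            chrom=self.chrom,
            variants=[self.variants[i] for i in index],
            samples=list(self.samples),
            populations=list(self.populations),
            genotypes=self.genotypes[index],
            phased=self.phased[index],
            african_pop=self.african_pop,
        )

    def take_samples(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypePanel(
            chrom=self.chrom,
            variants=list(self.variants),
            samples=[self.samples[i] for i in index],
            populations=[self.populations[i] for i in index],
            genotypes=self.genotypes[:, index],
            phased=self.phased[:, index],
            african_pop=self.african_pop,
        )

    def variant_call_rate(self) -> np.ndarray:
        called = np.all(self.genotypes != MISSING, axis=2)
        return called.mean(axis=1) if self.n_samples else np.zeros(self.n_variants)

    def sample_call_rate(self) -> np.ndarray:
        called = np.all(self.genotypes != MISSING, axis=2)
        return called.mean(axis=0) if self.n_variants else np.ones(self.n_samples)


@dataclass
class ArchaicGenome:
    """Diploid genotypes of the archaic individual at the panel's variants.

    The allele pair is unordered (the archaic genome need not be phased);
    a site with any missing allele is ineligible as an aSNP candidate.
    """

    sample: str
    genotypes: np.ndarray  # (n_variants, 2) int8, -1 missing

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != 2:
            raise ValidationError("archaic genotypes must have shape (n_variants, 2)")

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[0]

    def homozygous_allele(self) -> np.ndarray:
        """Per-variant homozygous allele index, or -1 when het/missing."""
        g = self.genotypes
        hom = (g[:, 0] == g[:, 1]) & (g[:, 0] != MISSING)
        return np.where(hom, g[:, 0], MISSING).astype(np.int8)


@dataclass
class GeneticMap:
    """HapMap-style recombination map: position, rate (cM/Mb), cumulative cM."""

    positions: np.ndarray
    rates: np.ndarray
    cum_cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        self.cum_cm = np.asarray(self.cum_cm, dtype=float)
        if not (len(self.positions) == len(self.rates) == len(self.cum_cm)):
            raise ValidationError("genetic map columns have unequal lengths")
        if len(self.positions) == 0:
            raise ValidationError("genetic map is empty")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("genetic map positions must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValidationError("genetic map rates must be non-negative")
        if np.any(np.diff(self.cum_cm) < 0):
            raise ValidationError("cumulative cM must be non-decreasing")

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def cm_at(self, pos) -> np.ndarray | float:
        """Cumulative cM at ``pos``; piecewise-linear, clamped at the map ends.

        Queries outside the mapped range take the boundary cumulative value
        (a zero-rate extension) rather than extrapolating rates.
        """
        pos = np.asarray(pos, dtype=float)
        out_of_range = (pos < self.positions[0]) | (pos > self.positions[-1])
        if np.any(out_of_range):
            logger.debug(
                "genetic-map query outside mapped range at %d position(s); "
                "using boundary cumulative cM (zero-rate extension)",
                int(np.sum(out_of_range)),
            )
        return np.interp(pos, self.positions, self.cum_cm)


def local_rate(gmap: GeneticMap, start: int, end: int) -> float:
    """Mean recombination rate (cM/Mb) over ``[start, end)``.

    This is the local rate used to set the expected length of segments
    shared through incomplete lineage sorting.
    """
    if start >= end:
        raise ValueError(f"start ({start}) must be < end ({end})")
    d_cm = float(gmap.cm_at(end) - gmap.cm_at(start))
    return d_cm / ((end - start) / 1e6)


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association summary from one study."""

    snp: str
    effect_allele: str
    beta: float  # log-odds per effect allele (natural log of OR)
    se: float | None
    p: float
    study: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"{self.snp}/{self.study}: P must be in (0, 1]")
        if self.se is not None and not self.se > 0:
            raise ValidationError(f"{self.snp}/{self.study}: SE must be positive")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


@dataclass(frozen=True)
class TruthTract:
    """Simulator ground truth: one archaic-origin interval on one haplotype."""

    sample: str
    side: int
    start: int
    end: int
    origin: str  # "introgressed" | "ILS"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError("truth tract start must be < end")
        if self.origin not in ("introgressed", "ILS"):
            raise ValidationError(f"unknown tract origin {self.origin!r}")

    @property
    def haplotype(self) -> str:
        return f"{self.sample}_h{self.side}"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    populations: Mapping[str, str],
    archaic_sample: str | None = None,
    african_pop: str | None = None,
    filter_biallelic_snv: bool = True,
) -> tuple[HaplotypePanel, ArchaicGenome | None]:
    """Read a VCF into a :class:`HaplotypePanel` (and archaic genome).

    ``populations`` maps every modern sample id in the VCF to its
    population label.  When ``filter_biallelic_snv`` is set, indels and
    multi-allelic sites are dropped.  Positions are converted to the
    internal 0-based convention.
    """
    from cyvcf2 import VCF  # deferred: htslib import is comparatively heavy

    path = Path(path)
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)

    modern = [s for s in vcf_samples if s != archaic_sample]
    unknown = [s for s in modern if s not in populations]
    if unknown:
        raise ConfigurationError(
            f"samples in VCF without a population label: {', '.join(unknown)}"
        )
    missing_from_vcf = [s for s in populations if s not in vcf_samples]
    if missing_from_vcf:
        raise ConfigurationError(
            "population map names samples absent from the VCF: "
            + ", ".join(missing_from_vcf)
        )
    if archaic_sample is not None and archaic_sample not in vcf_samples:
        raise ConfigurationError(
            f"archaic sample {archaic_sample!r} not present in the VCF"
        )
    arch_idx = vcf_samples.index(archaic_sample) if archaic_sample else None
    modern_idx = [i for i, s in enumerate(vcf_samples) if s != archaic_sample]

    variants: list[VariantRecord] = []
    geno_rows: list[np.ndarray] = []
    phase_rows: list[np.ndarray] = []
    arch_rows: list[tuple[int, int]] = []
    chrom: str | None = None
    n_dropped = 0
    n_seen = 0
    bases = {"A", "C", "G", "T"}

    iterator = iter(vcf)
    while True:
        try:
            v = next(iterator)
        except StopIteration:
            break
        except Exception as exc:  # htslib parse failure
            raise VCFParseError(
                f"{path}: malformed VCF near data line {n_seen + 1}: {exc}"
            ) from exc
        n_seen += 1
        if filter_biallelic_snv:
            if (
                len(v.ALT) != 1
                or v.REF not in bases
                or v.ALT[0] not in bases
            ):
                n_dropped += 1
                continue
        if chrom is None:
            chrom = v.CHROM
        gts = v.genotypes  # list of [a0, a1, phased]
        row = np.full((len(modern_idx), 2), MISSING, dtype=np.int8)
        phs = np.zeros(len(modern_idx), dtype=bool)
        for out_i, samp_i in enumerate(modern_idx):
            g = gts[samp_i]
            a0 = g[0] if g[0] is not None and g[0] >= 0 else MISSING
            a1 = g[1] if len(g) > 2 and g[1] is not None and g[1] >= 0 else MISSING
            row[out_i, 0] = a0
            row[out_i, 1] = a1
            phs[out_i] = bool(g[-1])
        geno_rows.append(row)
        phase_rows.append(phs)
        if arch_idx is not None:
            g = gts[arch_idx]
            a0 = g[0] if g[0] is not None and g[0] >= 0 else MISSING
            a1 = g[1] if len(g) > 2 and g[1] is not None and g[1] >= 0 else MISSING
            arch_rows.append((a0, a1))
        info_score = v.INFO.get("INFO_R2")
        variants.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS - 1,
                id=v.ID or f"{v.CHROM}_{v.POS}",
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else "N",
                info_score=float(info_score) if info_score is not None else None,
            )
        )
    vcf.close()

    if n_dropped:
        logger.info(
            "read_vcf: dropped %d non-biallelic/indel site(s) of %d",
            n_dropped, n_seen,
        )
    sample_names = [vcf_samples[i] for i in modern_idx]
    panel = HaplotypePanel(
        chrom=chrom if chrom is not None else "unknown",
        variants=variants,
        samples=sample_names,
        populations=[populations[s] for s in sample_names],
        genotypes=(
            np.stack(geno_rows) if geno_rows
            else np.empty((0, len(modern_idx), 2), dtype=np.int8)
        ),
        phased=(
            np.stack(phase_rows) if phase_rows
            else np.empty((0, len(modern_idx)), dtype=bool)
        ),
        african_pop=african_pop,
    )
    archaic = None
    if archaic_sample is not None:
        archaic = ArchaicGenome(
            sample=archaic_sample,
            genotypes=(
                np.array(arch_rows, dtype=np.int8) if arch_rows
                else np.empty((0, 2), dtype=np.int8)
            ),
        )
    return panel, archaic


def write_vcf(
    path: str | Path,
    panel: HaplotypePanel,
    archaic: ArchaicGenome | None = None,
) -> None:
    """Write the panel (optionally with the archaic sample) as VCF v4.2."""
    path = Path(path)
    samples = list(panel.samples)
    if archaic is not None:
        if archaic.n_variants != panel.n_variants:
            raise ValidationError("archaic genome not aligned to panel variants")
        samples = samples + [archaic.sample]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write(
            '##INFO=<ID=INFO_R2,Number=1,Type=Float,'
            'Description="Imputation INFO score r2">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for i, var in enumerate(panel.variants):
            info = (
                f"INFO_R2={var.info_score:.6g}" if var.info_score is not None else "."
            )
            fields = [
                var.chrom, str(var.pos + 1), var.id, var.ref, var.alt,
                ".", ".", info, "GT",
            ]
            for s in range(panel.n_samples):
                a0, a1 = panel.genotypes[i, s]
                sep = "|" if panel.phased[i, s] else "/"
                fields.append(
                    f"{'.' if a0 == MISSING else a0}{sep}"
                    f"{'.' if a1 == MISSING else a1}"
                )
            if archaic is not None:
                a0, a1 = archaic.genotypes[i]
                fields.append(
                    f"{'.' if a0 == MISSING else a0}/"
                    f"{'.' if a1 == MISSING else a1}"
                )
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a HapMap-format genetic map (chrom? position rate cM columns).

    A header row is tolerated; both 3-column (position, rate, cM) and
    4-column (chrom, position, rate, cM) layouts are accepted.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    # Drop a header row if the numeric columns do not parse.
    first = df.iloc[0]
    try:
        float(first.iloc[-1]), float(first.iloc[-2])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.shape[1] == 4:
        df = df.iloc[:, 1:]
    elif df.shape[1] != 3:
        raise SchemaError(
            f"{path}: expected 3 or 4 whitespace-delimited columns, "
            f"got {df.shape[1]}"
        )
    try:
        positions = df.iloc[:, 0].astype(float).astype(np.int64).to_numpy()
        rates = df.iloc[:, 1].astype(float).to_numpy()
        cum_cm = df.iloc[:, 2].astype(float).to_numpy()
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric value in genetic map: {exc}") from exc
    return GeneticMap(positions=positions, rates=rates, cum_cm=cum_cm)


def constant_rate_map(rate_cm_per_mb: float, length_bp: int) -> GeneticMap:
    """Build a uniform-rate map covering ``[0, length_bp]``."""
    if rate_cm_per_mb < 0:
        raise ValidationError("rate must be non-negative")
    return GeneticMap(
        positions=np.array([0, length_bp]),
        rates=np.array([rate_cm_per_mb, rate_cm_per_mb]),
        cum_cm=np.array([0.0, rate_cm_per_mb * length_bp / 1e6]),
    )


# ---------------------------------------------------------------------------
# Summary statistics / association result tables
# ---------------------------------------------------------------------------

_SUMMARY_COLUMNS = ["snp", "effect_allele", "beta", "se", "p", "study"]


def read_summary_stats(path: str | Path) -> list[SummaryStatRecord]:
    """Read per-study summary statistics from a TSV.

    Mandatory columns: ``snp effect_allele p study`` plus either ``beta``
    (log-odds) or ``or``; ``se`` is optional.  OR and beta are
    interconverted with the natural log (beta = ln OR).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    required = {"snp", "effect_allele", "p", "study"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {sorted(missing)}")
    if "beta" not in df.columns:
        if "or" not in df.columns:
            raise SchemaError(f"{path}: need a 'beta' or 'or' column")
        ors = df["or"].astype(float)
        if (ors <= 0).any():
            raise ValidationError(f"{path}: OR must be positive")
        df["beta"] = np.log(ors)
    records = []
    for row in df.itertuples(index=False):
        se = getattr(row, "se", None)
        se = None if se is None or (isinstance(se, float) and math.isnan(se)) else float(se)
        records.append(
            SummaryStatRecord(
                snp=str(row.snp),
                effect_allele=str(row.effect_allele),
                beta=float(row.beta),
                se=se,
                p=float(row.p),
                study=str(row.study),
            )
        )
    return records


def write_summary_stats(path: str | Path, records: Iterable[SummaryStatRecord]) -> None:
    rows = [
        {
            "snp": r.snp,
            "effect_allele": r.effect_allele,
            "beta": r.beta,
            "se": "" if r.se is None else r.se,
            "p": r.p,
            "study": r.study,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)


def write_results(path: str | Path, results: Sequence) -> None:
    """Write association results (or any flat dataclass records) as TSV."""
    import dataclasses

    rows = [dataclasses.asdict(r) for r in results]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path):
    """Read an association-result TSV back as a list of AssociationResult."""
    from .association import AssociationResult  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t")
    fields = {f.name for f in __import__("dataclasses").fields(AssociationResult)}
    out = []
    for row in df.to_dict(orient="records"):
        kwargs = {k: v for k, v in row.items() if k in fields}
        out.append(AssociationResult(**kwargs))
    return out


# ---------------------------------------------------------------------------
# Truth tracks (BED5)
# ---------------------------------------------------------------------------

def write_truth_bed(path: str | Path, tracts: Iterable[TruthTract], chrom: str = "1") -> None:
    """Write ground-truth tracts as BED5 (chrom start end haplotype origin)."""
    with open(path, "w") as fh:
        for t in tracts:
            fh.write(f"{chrom}\t{t.start}\t{t.end}\t{t.haplotype}\t{t.origin}\n")


def read_truth_bed(path: str | Path) -> list[TruthTract]:
    tracts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise SchemaError(
                    f"{path}:{lineno}: expected 5 BED columns, got {len(parts)}"
                )
            _, start, end, name, origin = parts[:5]
            if "_h" in name:
                sample, side = name.rsplit("_h", 1)
                side = int(side)
            else:
                sample, side = name, 0
            tracts.append(
                TruthTract(
                    sample=sample, side=side,
                    start=int(start), end=int(end), origin=origin,
                )
            )
    return tracts
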