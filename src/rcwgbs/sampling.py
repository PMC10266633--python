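"""Downsampling of read counts and coverage-based site selection.

Sequencing at a fraction of the original depth is emulated by binomial
thinning: each read covering a site is retained independently with the
target probability, so a site's methylated and unmethylated counts are
thinned with independent Binomial draws. Training sites are drawn from the
coverage band between the median and the third quartile, where observed
levels are considered relatively accurate; "low coverage" sites (the ones to
recalibrate) are those with at most ``threshold`` reads, default 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GenomeSequence, Methylome

logger = logging.getLogger(__name__)

__all__ = [
    "DownsampleSpec",
    "TrainingSelection",
    "downsample_counts",
    "coverage_quantiles",
    "select_training_sites",
    "low_coverage_sites",
]


@dataclass(frozen=True)
class DownsampleSpec:
    fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")


@dataclass(frozen=True)
class TrainingSelection:
    """Sites chosen for model fitting, with the coverage band that defined them."""

    sites: list[tuple[str, int]]
    median: int
    q3: int
    n_requested: int
    seed: int = 0
    quantile_method: str = field(default="nearest-rank", compare=False)


def downsample_counts(methylome: Methylome, fraction: float, seed: int = 0) -> Methylome:
    """Binomially thin every per-site read count by ``fraction``.

    Retained methylated reads ~ Binomial(meth_count, fraction) and likewise
    for unmethylated reads, independently per site. Deterministic given seed.
    """
    spec = DownsampleSpec(fraction, seed)  # validates fraction
    if spec.fraction == 1.0:
        return Methylome(
            {c: (methylome.positions(c), methylome.meth(c), methylome.unmeth(c))
             for c in methylome.chromosomes}
        )
    rng = np.random.default_rng(seed)
    data = {}
    for chrom in methylome.chromosomes:
        meth = rng.binomial(methylome.meth(chrom), fraction)
        unmeth = rng.binomial(methylome.unmeth(chrom), fraction)
        data[chrom] = (methylome.positions(chrom), meth, unmeth)
    return Methylome(data)


def _nearest_rank(sorted_values: np.ndarray, q: float) -> int:
    """Type-1 (nearest-rank) percentile of an ascending array."""
    n = len(sorted_values)
    rank = int(np.ceil(q * n))
    return int(sorted_values[max(rank, 1) - 1])


def coverage_quantiles(methylome: Methylome) -> tuple[int, int]:
    """(median, Q3) of per-site coverage over covered sites (coverage > 0)."""
    cov = np.concatenate([methylome.coverage(c) for c in methylome.chromosomes])
    cov = cov[cov > 0]
    if len(cov) == 0:
        raise ValueError("no covered sites")
    cov.sort()
    return _nearest_rank(cov, 0.5), _nearest_rank(cov, 0.75)


def select_training_sites(
    methylome: Methylome, n: int = 100_000, seed: int = 0
) -> TrainingSelection:
    """Uniformly sample ``n`` sites with coverage in [median, Q3], inclusive.

    The sample is without replacement over the genome-wide eligible set and
    reproducible given the seed; if fewer than ``n`` sites are eligible all
    of them are returned with a warning.
    """
    median, q3 = coverage_quantiles(methylome)
    eligible: list[tuple[str, int]] = []
    for chrom in methylome.chromosomes:
        cov = methylome.coverage(chrom)
        pos = methylome.positions(chrom)
        mask = (cov >= median) & (cov <= q3)
        eligible.extend((chrom, int(p)) for p in pos[mask])
    if not eligible:
        raise ValueError("no sites with coverage in the median-Q3 band")
    rng = np.random.default_rng(seed)
    if n >= len(eligible):
        if n > len(eligible):
            logger.warning(
                "requested %d training sites but only %d eligible; using all",
                n, len(eligible),
            )
        chosen = list(eligible)
    else:
        idx = rng.choice(len(eligible), size=n, replace=False)
        chosen = [eligible[i] for i in np.sort(idx)]
    return TrainingSelection(sites=chosen, median=median, q3=q3, n_requested=n, seed=seed)


def low_coverage_sites(
    methylome: Methylome,
    threshold: int = 3,
    genome: GenomeSequence | None = None,
) -> list[tuple[str, int]]:
    """All CpG sites with coverage <= threshold (zero-coverage included).

    When a genome is supplied, CpG positions absent from the methylome are
    added as zero-coverage sites.
    """
    out: list[tuple[str, int]] = []
    for chrom in methylome.chromosomes:
        cov = methylome.coverage(chrom)
        pos = methylome.positions(chrom)
        known = pos[cov <= threshold]
        if genome is not None and chrom in genome.chromosomes:
            all_cpg = genome.cpg_positions(chrom)
            missing = np.setdiff1d(all_cpg, pos, assume_unique=True)
            known = np.union1d(known, missing)
        out.extend((chrom, int(p)) for p in known)
    return out
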