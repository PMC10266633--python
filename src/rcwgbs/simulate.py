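"""Synthetic genomes, methylomes and bisulfite read counts.

The generator reproduces the statistical structure that recalibration
exploits, without any real data:

* **Genome** — i.i.d. bases at a background C+G fraction, with CpG-island
  segments of elevated C+G content; CpG dinucleotides arise naturally, at a
  much higher density inside islands.
* **True methylation** — each CpG carries a latent methylated (M) or
  unmethylated (U) state following a two-state Markov chain along
  consecutive CpGs, which produces the spatial correlation of real
  methylomes; inside islands the state is pushed toward U, which gives the
  sequence its predictive value. Levels are Beta-distributed per state
  (defaults Beta(20, 2) for M, Beta(2, 20) for U), so the marginal level
  distribution is bimodal with mass near 0 and 1.
* **Reads** — per-site coverage is Poisson at the configured mean depth and
  the methylated read count is Binomial(coverage, true level), the standard
  WGBS observation model.

All draws flow from a single integer seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeSequence, Methylome

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_methylome",
    "simulate_reads",
    "simulate_dataset",
    "write_simulation",
    "read_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model; defaults give a human-like 500 kb toy methylome."""

    genome_length: int = 500_000
    chrom_name: str = "chrSim"
    background_gc: float = 0.40      # genome-wide C+G fraction outside islands
    n_islands: int | None = None     # default: one island per 20 kb
    island_length: int = 1_000
    island_gc: float = 0.70
    switch_prob: float = 0.02        # M<->U transition probability per CpG step
    beta_m: tuple[float, float] = (20.0, 2.0)   # level ~ Beta(a, b) in state M
    beta_u: tuple[float, float] = (2.0, 20.0)   # level ~ Beta(a, b) in state U
    island_u_bias: float = 0.9       # probability an island CpG is forced to U
    mean_depth: float = 50.0         # reads per site, Poisson mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_islands is None:
            object.__setattr__(self, "n_islands", max(1, self.genome_length // 20_000))
        for name in ("background_gc", "island_gc", "switch_prob", "island_u_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(*self.beta_m, *self.beta_u) <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.mean_depth < 0:
            raise ValueError("mean depth must be non-negative")
        if self.n_islands * self.island_length > self.genome_length:
            raise ValueError("island spans do not fit in the genome")


@dataclass
class GroundTruth:
    """True per-CpG methylation levels and latent states, per chromosome."""

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # pos, level, state
    islands: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.data)

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p, _, _ in self.data.values())

    def positions(self, chrom: str) -> np.ndarray:
        return self.data[chrom][0]

    def levels(self, chrom: str) -> np.ndarray:
        return self.data[chrom][1]

    def states(self, chrom: str) -> np.ndarray:
        return self.data[chrom][2]

    def levels_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """True levels at the given positions; nan for positions not simulated."""
        pos, lev, _ = self.data[chrom]
        idx = np.searchsorted(pos, positions)
        idx = np.clip(idx, 0, len(pos) - 1)
        out = np.where(pos[idx] == positions, lev[idx], np.nan)
        return out

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for chrom in self.chromosomes:
            pos, lev, state = self.data[chrom]
            parts.append(pd.DataFrame(
                {"chrom": chrom, "pos": pos, "true_level": lev,
                 "state": np.where(state == 1, "M", "U")}
            ))
        return pd.concat(parts, ignore_index=True)


def _place_islands(rng: np.random.Generator, cfg: SimulationConfig) -> list[tuple[int, int]]:
    """Non-overlapping (start, end) island spans, 1-based inclusive."""
    spans: list[tuple[int, int]] = []
    attempts = 0
    while len(spans) < cfg.n_islands:
        attempts += 1
        if attempts > 1000 * max(cfg.n_islands, 1):
            raise RuntimeError("could not place non-overlapping islands")
        start = int(rng.integers(1, cfg.genome_length - cfg.island_length + 2))
        end = start + cfg.island_length - 1
        if all(end < s or start > e for s, e in spans):
            spans.append((start, end))
    return sorted(spans)


def simulate_genome(config: SimulationConfig) -> tuple[GenomeSequence, list[tuple[int, int]]]:
    """Random genome with CpG-dense island segments; deterministic given the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    spans = _place_islands(rng, config) if config.n_islands else []
    gc = np.full(config.genome_length, config.background_gc)
    for s, e in spans:
        gc[s - 1 : e] = config.island_gc
    u = rng.random(config.genome_length)
    # within each class (GC vs AT) the two bases are equiprobable
    bases = np.empty(config.genome_length, dtype="U1")
    is_gc = u < gc
    coin = rng.random(config.genome_length) < 0.5
    bases[is_gc & coin] = "C"
    bases[is_gc & ~coin] = "G"
    bases[~is_gc & coin] = "A"
    bases[~is_gc & ~coin] = "T"
    genome = GenomeSequence({config.chrom_name: "".join(bases)})
    return genome, spans


def simulate_methylome(
    genome: GenomeSequence,
    config: SimulationConfig,
    islands: list[tuple[int, int]] | None = None,
) -> GroundTruth:
    """Latent M/U states and true levels for every CpG of the genome."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    data = {}
    island_map = {}
    for chrom in genome.chromosomes:
        pos = genome.cpg_positions(chrom)
        if len(pos) == 0:
            raise ValueError(f"{chrom} contains no CpG")
        spans = islands or []
        in_island = np.zeros(len(pos), dtype=bool)
        for s, e in spans:
            in_island |= (pos >= s) & (pos <= e)
        state = np.empty(len(pos), dtype=np.int8)  # 1 = M, 0 = U
        state[0] = rng.integers(0, 2)
        switches = rng.random(len(pos)) < config.switch_prob
        for i in range(1, len(pos)):
            state[i] = state[i - 1] ^ switches[i]
        forced = in_island & (rng.random(len(pos)) < config.island_u_bias)
        state[forced] = 0
        levels = np.where(
            state == 1,
            rng.beta(*config.beta_m, size=len(pos)),
            rng.beta(*config.beta_u, size=len(pos)),
        )
        data[chrom] = (pos, levels, state)
        island_map[chrom] = spans
    return GroundTruth(data=data, islands=island_map)


def simulate_reads(truth: GroundTruth, mean_depth: float, seed: int = 0) -> Methylome:
    """Poisson coverage and Binomial methylated counts at every simulated CpG."""
    if mean_depth < 0:
        raise ValueError("mean depth must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    data = {}
    for chrom in truth.chromosomes:
        pos = truth.positions(chrom)
        lev = truth.levels(chrom)
        cov = rng.poisson(mean_depth, size=len(pos))
        meth = rng.binomial(cov, lev)
        data[chrom] = (pos, meth, cov - meth)
    return Methylome(data)


def simulate_dataset(config: SimulationConfig) -> tuple[GenomeSequence, GroundTruth, Methylome]:
    """Genome, ground truth and observed methylome from one config/seed."""
    genome, spans = simulate_genome(config)
    truth = simulate_methylome(genome, config, islands=spans)
    methylome = simulate_reads(truth, config.mean_depth, seed=config.seed)
    return genome, truth, methylome


def write_simulation(
    genome: GenomeSequence,
    truth: GroundTruth,
    methylome: Methylome,
    outdir: str,
    seed: int = 0,
) -> dict[str, str]:
    """Write FASTA genome, both-strand CpG report, and truth TSV to a directory.

    Each merged site's counts are split binomially between the + strand C and
    the - strand C at pos+1, so reading the report back through strand
    merging recovers the methylome exactly.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "report": os.path.join(outdir, "methylome.CpG_report.txt"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    genome.write_fasta(paths["genome"])
    with open(paths["report"], "w") as fh:
        for chrom, pos, meth, unmeth in methylome.iter_sites():
            mp = int(rng.binomial(meth, 0.5))
            up = int(rng.binomial(unmeth, 0.5))
            tri_p = genome.window(chrom, pos, 1)[1:] + genome.window(chrom, pos + 2, 0)
            fh.write(f"{chrom}\t{pos}\t+\t{mp}\t{up}\tCG\t{tri_p[:3]}\n")
            fh.write(f"{chrom}\t{pos + 1}\t-\t{meth - mp}\t{unmeth - up}\tCG\tCGN\n")
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return paths


def read_truth(path: str) -> GroundTruth:
    """Read back a truth TSV written by :func:`write_simulation`."""
    frame = pd.read_csv(path, sep="\t")
    data = {}
    for chrom, grp in frame.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        data[str(chrom)] = (
            grp["pos"].to_numpy(np.int64),
            grp["true_level"].to_numpy(np.float64),
            np.where(grp["state"].to_numpy() == "M", 1, 0).astype(np.int8),
        )
    return GroundTruth(data=data)
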