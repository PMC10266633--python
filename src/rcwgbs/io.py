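"""Per-cytosine methylation files, genome sequence access, and strand/replicate merging.

The on-disk formats are the two Bismark per-cytosine dialects:

* CpG report: ``chrom  pos  strand  count_methylated  count_unmethylated
  context  trinucleotide`` — one line per cytosine, 1-based, both strands,
  uncovered cytosines included with zero counts.
* coverage file: ``chrom  start  end  methylation_percentage
  count_methylated  count_unmethylated`` — covered cytosines only, no strand.

In memory a :class:`Methylome` keeps, per chromosome, position-sorted arrays
of methylated/unmethylated read counts for strand-merged CpG sites (keyed to
the + strand C of each CpG). The methylation level of a site is the fraction
of methylated reads over all reads covering it, defined only when coverage
is positive.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CytosineRecord",
    "Methylome",
    "GenomeSequence",
    "MethylationFileError",
    "read_cpg_report",
    "read_coverage_file",
    "merge_strands",
    "merge_replicates",
    "methylation_level",
    "extract_window",
    "mean_coverage",
    "write_imputed",
    "read_imputed",
    "write_cpg_report",
]


class MethylationFileError(ValueError):
    """Raised for malformed per-cytosine methylation files."""


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's read counts.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unknown, e.g. coverage files).
    """

    chrom: str
    pos: int  # 1-based position of the cytosine
    strand: str
    meth_count: int
    unmeth_count: int
    context: str = "CG"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count


def methylation_level(meth_count: int, unmeth_count: int) -> float:
    """Fraction of methylated reads over the total reads, in [0, 1].

    Returns ``nan`` (the undefined-level signal, distinct from 0.0) when the
    site has no coverage.
    """
    cov = meth_count + unmeth_count
    if cov <= 0:
        return math.nan
    return meth_count / cov


class Methylome:
    """Position-sorted CpG read counts per chromosome, strand-merged.

    Parameters
    ----------
    data
        Mapping chromosome -> ``(positions, meth_counts, unmeth_counts)``
        arrays. Positions must be strictly increasing; counts non-negative
        integers.
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (pos, meth, unmeth) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            meth = np.asarray(meth, dtype=np.int64)
            unmeth = np.asarray(unmeth, dtype=np.int64)
            if not (len(pos) == len(meth) == len(unmeth)):
                raise ValueError(f"{chrom}: array length mismatch")
            if len(pos) and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            if np.any(meth < 0) or np.any(unmeth < 0):
                raise ValueError(f"{chrom}: negative read counts")
            self._data[chrom] = (pos, meth, unmeth)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p, _, _ in self._data.values())

    def positions(self, chrom: str) -> np.ndarray:
        return self._data[chrom][0]

    def meth(self, chrom: str) -> np.ndarray:
        return self._data[chrom][1]

    def unmeth(self, chrom: str) -> np.ndarray:
        return self._data[chrom][2]

    def coverage(self, chrom: str) -> np.ndarray:
        _, m, u = self._data[chrom]
        return m + u

    def levels(self, chrom: str) -> np.ndarray:
        """Per-site methylation level; nan where coverage is zero."""
        _, m, u = self._data[chrom]
        cov = m + u
        with np.errstate(invalid="ignore", divide="ignore"):
            lev = np.where(cov > 0, m / np.maximum(cov, 1), np.nan)
        return lev

    def get(self, chrom: str, pos: int) -> tuple[int, int] | None:
        """(meth, unmeth) at a site, or None if the site is absent."""
        if chrom not in self._data:
            return None
        p, m, u = self._data[chrom]
        i = np.searchsorted(p, pos)
        if i < len(p) and p[i] == pos:
            return int(m[i]), int(u[i])
        return None

    def iter_sites(self) -> Iterator[tuple[str, int, int, int]]:
        for chrom in self.chromosomes:
            p, m, u = self._data[chrom]
            for i in range(len(p)):
                yield chrom, int(p[i]), int(m[i]), int(u[i])

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for chrom in self.chromosomes:
            p, m, u = self._data[chrom]
            parts.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": p, "meth_count": m, "unmeth_count": u}
                )
            )
        if not parts:
            return pd.DataFrame(columns=["chrom", "pos", "meth_count", "unmeth_count"])
        return pd.concat(parts, ignore_index=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Methylome):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self._data[c], other._data[c]))
            for c in self._data
        )

    def __repr__(self) -> str:
        return f"Methylome({len(self._data)} chromosomes, {self.n_sites} CpG sites)"


class GenomeSequence:
    """Uppercase nucleotide sequences addressed by 1-based inclusive coordinates."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seq = {c: str(s).upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._seq)

    def length(self, chrom: str) -> int:
        return len(self._seq[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seq[chrom]

    def base(self, chrom: str, pos: int) -> str:
        return self._seq[chrom][pos - 1]

    def window(self, chrom: str, pos: int, flank: int = 50) -> str:
        """2*flank+1 bases centered on pos; off-chromosome positions become N."""
        if chrom not in self._seq:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._seq[chrom]
        start = pos - flank  # 1-based
        end = pos + flank
        left_pad = max(0, 1 - start)
        right_pad = max(0, end - len(seq))
        core = seq[max(start, 1) - 1 : min(end, len(seq))]
        return "N" * left_pad + core + "N" * right_pad

    def cpg_positions(self, chrom: str) -> np.ndarray:
        """1-based positions of the C of every CpG on the + strand."""
        seq = self._seq[chrom]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = arr[:-1] == ord("C")
        is_g = arr[1:] == ord("G")
        return np.flatnonzero(is_c & is_g) + 1

    def is_cpg_c(self, chrom: str, pos: int) -> bool:
        seq = self._seq[chrom]
        return pos >= 1 and pos < len(seq) and seq[pos - 1 : pos + 1] == "CG"

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.chromosomes:
                fh.write(f">{chrom}\n")
                seq = self._seq[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def extract_window(genome: GenomeSequence, chrom: str, pos: int, flank: int = 50) -> str:
    """Flanking sequence of ``2*flank+1`` bases centered on ``pos``."""
    return genome.window(chrom, pos, flank)


def _open_text(path: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def read_cpg_report(path: str, cpg_only: bool = True) -> list[CytosineRecord]:
    """Parse a Bismark CpG report (optionally gzipped) into records.

    Columns: chrom, position, strand, count methylated, count unmethylated,
    context, trinucleotide. With ``cpg_only`` non-CG contexts are skipped.
    """
    records: list[CytosineRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise MethylationFileError(
                    f"{path}:{lineno}: expected >=6 tab-separated columns, got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
            try:
                pos, meth, unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise MethylationFileError(
                    f"{path}:{lineno}: non-integer position or count: {exc}"
                ) from None
            if cpg_only and context.upper() not in ("CG", "CPG"):
                continue
            records.append(CytosineRecord(chrom, pos, strand, meth, unmeth, context))
    if not records:
        logger.warning("no records read from %s", path)
    return records


def read_coverage_file(path: str, skip_header: bool = False) -> list[CytosineRecord]:
    """Parse a Bismark coverage file: chrom, start, end, pct, meth, unmeth.

    The percentage column is discarded; levels are recomputed from counts.
    Strand is unavailable in this dialect and recorded as ``'.'``.
    """
    records: list[CytosineRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and skip_header:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise MethylationFileError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
                )
            chrom, start_s, _end_s, _pct, meth_s, unmeth_s = fields[:6]
            try:
                pos, meth, unmeth = int(start_s), int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise MethylationFileError(
                    f"{path}:{lineno}: non-integer position or count: {exc}"
                ) from None
            records.append(CytosineRecord(chrom, pos, ".", meth, unmeth, "CG"))
    if not records:
        logger.warning("no records read from %s", path)
    return records


def merge_strands(
    records: Iterable[CytosineRecord], genome: GenomeSequence | None = None
) -> Methylome:
    """Combine the symmetric CpG counts of the two strands into one site.

    The + strand C at position p pairs with the - strand C at p+1; the merged
    site is keyed to p. Unpaired records are kept under their + strand
    equivalent key (a - strand record at q maps to q-1). Records of unknown
    strand ('.') are assumed already merged and keyed as-is.
    """
    per_chrom: dict[str, dict[int, list[int]]] = {}
    seen: set[tuple[str, int, str]] = set()
    for rec in records:
        key_id = (rec.chrom, rec.pos, rec.strand)
        if key_id in seen:
            raise ValueError(
                f"duplicate record for {rec.chrom}:{rec.pos} strand {rec.strand}"
            )
        seen.add(key_id)
        if rec.strand == "-":
            key = rec.pos - 1
            if key < 1:
                key = rec.pos  # degenerate: - strand C at position 1
        else:
            key = rec.pos
        if genome is not None and rec.strand in "+-":
            if not genome.is_cpg_c(rec.chrom, key):
                raise ValueError(
                    f"{rec.chrom}:{rec.pos} ({rec.strand}) does not map to a CpG at {key}"
                )
        sites = per_chrom.setdefault(rec.chrom, {})
        counts = sites.setdefault(key, [0, 0])
        counts[0] += rec.meth_count
        counts[1] += rec.unmeth_count
    data = {}
    for chrom, sites in per_chrom.items():
        pos = np.array(sorted(sites), dtype=np.int64)
        meth = np.array([sites[p][0] for p in pos], dtype=np.int64)
        unmeth = np.array([sites[p][1] for p in pos], dtype=np.int64)
        data[chrom] = (pos, meth, unmeth)
    return Methylome(data)


def merge_replicates(m1: Methylome, m2: Methylome) -> Methylome:
    """Sum per-site read counts over the union of sites of two replicates."""
    only_1 = set(m1.chromosomes) - set(m2.chromosomes)
    only_2 = set(m2.chromosomes) - set(m1.chromosomes)
    if only_1 or only_2:
        logger.warning(
            "chromosome sets differ between replicates: %s vs %s",
            sorted(only_1), sorted(only_2),
        )
    data = {}
    for chrom in sorted(set(m1.chromosomes) | set(m2.chromosomes)):
        counts: dict[int, list[int]] = {}
        for m in (m1, m2):
            if chrom not in m.chromosomes:
                continue
            for p, mc, uc in zip(m.positions(chrom), m.meth(chrom), m.unmeth(chrom)):
                c = counts.setdefault(int(p), [0, 0])
                c[0] += int(mc)
                c[1] += int(uc)
        pos = np.array(sorted(counts), dtype=np.int64)
        data[chrom] = (
            pos,
            np.array([counts[p][0] for p in pos], dtype=np.int64),
            np.array([counts[p][1] for p in pos], dtype=np.int64),
        )
    return Methylome(data)


def mean_coverage(methylome: Methylome) -> float:
    """Mean read coverage over all CpG sites (zero-coverage sites included)."""
    if methylome.n_sites == 0:
        raise ValueError("empty methylome")
    total = sum(int(methylome.coverage(c).sum()) for c in methylome.chromosomes)
    return total / methylome.n_sites


IMPUTED_COLUMNS = ["chrom", "pos", "coverage", "observed_level", "output_level", "source"]


def _fmt_level(x: float) -> str:
    return "NA" if (x is None or (isinstance(x, float) and math.isnan(x))) else repr(float(x))


def write_imputed(path: str, result) -> None:
    """Write an imputation result as a header + TSV, round-trippable losslessly.

    Columns: chrom, pos, coverage, observed_level (NA when uncovered),
    output_level, source in {observed, imputed}. Float levels are written in
    shortest round-trip decimal form.
    """
    frame = result.frame if hasattr(result, "frame") else result
    with open(path, "w") as fh:
        fh.write("\t".join(IMPUTED_COLUMNS) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t{int(row.coverage)}\t"
                f"{_fmt_level(row.observed_level)}\t{_fmt_level(row.output_level)}\t"
                f"{row.source}\n"
            )


def read_imputed(path: str) -> pd.DataFrame:
    """Read back a file produced by :func:`write_imputed`."""
    frame = pd.read_csv(
        path, sep="\t", na_values=["NA"],
        dtype={"chrom": str, "pos": np.int64, "coverage": np.int64, "source": str},
    )
    missing = set(IMPUTED_COLUMNS) - set(frame.columns)
    if missing:
        raise MethylationFileError(f"{path}: missing columns {sorted(missing)}")
    return frame[IMPUTED_COLUMNS]


def write_cpg_report(path: str, methylome: Methylome, context: str = "CG") -> None:
    """Write a strand-merged methylome as a + strand CpG report."""
    with open(path, "w") as fh:
        for chrom, pos, meth, unmeth in methylome.iter_sites():
            fh.write(f"{chrom}\t{pos}\t+\t{meth}\t{unmeth}\t{context}\t{context}N\n")
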