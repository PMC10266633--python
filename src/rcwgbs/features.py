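"""Per-site model inputs: encoded flanking sequence plus the methylation chain.

Each CpG site is described by a 5 x 100 x 1 matrix. Rows 1-4 carry the
flanking DNA sequence: the 101 bp window centered on the site yields 100
overlapping dinucleotides (step 1), each mapped to its lexicographic index
0-15 (A < C < G < T, index = 4 * first + second) and written as a 4-bit
big-endian column, so AA -> [0,0,0,0] and TT -> [1,1,1,1]. Row 5 is the
methylation chain: the observed levels of the 50 nearest covered CpG
neighbors on each side of the site, the site itself excluded.

An alternative one-hot scheme encodes the 100 non-center window bases with
the per-base vectors A -> [0,0,0,1], C -> [0,0,1,0], G -> [0,1,0,0],
T -> [1,0,0,0], keeping the same 5 x 100 shape.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .io import GenomeSequence, Methylome, extract_window

__all__ = [
    "FLANK",
    "CHAIN_K",
    "WINDOW_LENGTH",
    "FEATURE_SHAPE",
    "PAD_LEVEL",
    "encode_2mer",
    "encode_onehot",
    "neighbor_chain",
    "assemble_features",
    "neighbor_average",
]

FLANK = 50            # bp of sequence on each side of the target C
CHAIN_K = 50          # covered CpG neighbors used per side
WINDOW_LENGTH = 2 * FLANK + 1
FEATURE_SHAPE = (5, 100, 1)
PAD_LEVEL = 0.5       # maximally uninformative fill at chromosome edges

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
# per-base one-hot columns, read top-to-bottom
_ONEHOT = {
    "A": (0, 0, 0, 1),
    "C": (0, 0, 1, 0),
    "G": (0, 1, 0, 0),
    "T": (1, 0, 0, 0),
    "N": (0, 0, 0, 0),
}


def encode_2mer(window: str) -> np.ndarray:
    """Encode a 101-base window as a 4 x 100 binary matrix of dinucleotide codes.

    Dinucleotides containing N produce an all-zero column; callers can count
    such columns to flag low-information windows.
    """
    window = window.upper()
    if len(window) != WINDOW_LENGTH:
        raise ValueError(f"window must be {WINDOW_LENGTH} bases, got {len(window)}")
    out = np.zeros((4, WINDOW_LENGTH - 1), dtype=np.int8)
    for i in range(WINDOW_LENGTH - 1):
        a, b = window[i], window[i + 1]
        if a not in _BASE_INDEX or b not in _BASE_INDEX:
            continue  # N column stays zero
        code = 4 * _BASE_INDEX[a] + _BASE_INDEX[b]
        # big-endian 4-bit column: row 0 is the most significant bit
        out[0, i] = (code >> 3) & 1
        out[1, i] = (code >> 2) & 1
        out[2, i] = (code >> 1) & 1
        out[3, i] = code & 1
    return out


def encode_onehot(window: str) -> np.ndarray:
    """Encode bases as a 4 x len(window) matrix of per-base one-hot columns."""
    window = window.upper()
    out = np.zeros((4, len(window)), dtype=np.int8)
    for i, base in enumerate(window):
        if base not in _ONEHOT:
            raise ValueError(f"unexpected base {base!r} at offset {i}")
        out[:, i] = _ONEHOT[base]
    return out


def _n_bad_columns(window: str) -> int:
    """Number of dinucleotide columns zeroed by an N."""
    return sum(
        1
        for i in range(len(window) - 1)
        if window[i] not in _BASE_INDEX or window[i + 1] not in _BASE_INDEX
    )


class _ChainIndex:
    """Covered-site positions and levels per chromosome, for fast neighbor lookup."""

    def __init__(self, methylome: Methylome):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in methylome.chromosomes:
            cov = methylome.coverage(chrom)
            mask = cov > 0
            pos = methylome.positions(chrom)[mask]
            lev = (methylome.meth(chrom)[mask] / cov[mask]).astype(np.float64)
            self._by_chrom[chrom] = (pos, lev)

    def chain(self, chrom: str, pos: int, k: int) -> tuple[np.ndarray, np.ndarray]:
        if chrom in self._by_chrom:
            cpos, clev = self._by_chrom[chrom]
        else:
            cpos = np.empty(0, dtype=np.int64)
            clev = np.empty(0)
        i = int(np.searchsorted(cpos, pos, side="left"))
        left = clev[max(0, i - k) : i]
        j = i + 1 if (i < len(cpos) and cpos[i] == pos) else i
        right = clev[j : j + k]
        chain = np.full(2 * k, PAD_LEVEL, dtype=np.float64)
        mask = np.zeros(2 * k, dtype=bool)
        # left side fills the inner entries next to the target; padding stays outer
        chain[k - len(left) : k] = left
        mask[k - len(left) : k] = True
        chain[k : k + len(right)] = right
        mask[k : k + len(right)] = True
        return chain, mask


def neighbor_chain(
    methylome: Methylome,
    chrom: str,
    pos: int,
    k: int = CHAIN_K,
    return_mask: bool = False,
):
    """Levels of the k nearest covered CpGs on each side of ``pos``.

    The 2k entries are ordered by genomic position with the target excluded;
    where a chromosome edge leaves fewer than k covered neighbors, the outer
    entries on that side are padded with ``PAD_LEVEL``. With ``return_mask``
    a boolean observed/padding mask is returned alongside.
    """
    chain, mask = _ChainIndex(methylome).chain(chrom, pos, k)
    return (chain, mask) if return_mask else chain


def neighbor_average(chain: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean of the chain's observed entries — the non-learned baseline predictor.

    Returns nan when every entry is padding.
    """
    chain = np.asarray(chain, dtype=np.float64)
    if mask is not None:
        chain = chain[np.asarray(mask, dtype=bool)]
    if chain.size == 0:
        return math.nan
    return float(chain.mean())


def assemble_features(
    genome: GenomeSequence,
    methylome: Methylome,
    sites: Sequence[tuple[str, int]],
    scheme: str = "2mer",
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (n, 5, 100, 1) feature array for a list of (chrom, pos) sites.

    Rows 1-4 come from the sequence encoder for ``scheme`` ("2mer" or
    "onehot"); row 5 is the neighbor methylation chain built from the
    observed methylome. Returns ``(features, n_bad_columns)`` where the
    second array counts N-zeroed sequence columns per site, so callers can
    drop windows dominated by unknown sequence.

    Every site must be the C of a CpG in the genome; this guards against
    off-by-one coordinate errors between the methylome and the reference.
    """
    if scheme not in ("2mer", "onehot"):
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    index = _ChainIndex(methylome)
    n = len(sites)
    X = np.zeros((n, *FEATURE_SHAPE), dtype=np.float32)
    n_bad = np.zeros(n, dtype=np.int64)
    for s, (chrom, pos) in enumerate(sites):
        if not genome.is_cpg_c(chrom, pos):
            raise ValueError(f"{chrom}:{pos} is not the C of a CpG in the genome")
        window = extract_window(genome, chrom, pos, FLANK)
        if scheme == "2mer":
            seq_rows = encode_2mer(window)
            n_bad[s] = _n_bad_columns(window)
        else:
            # drop the center base so 100 per-base columns keep the 5x100 shape
            reduced = window[:FLANK] + window[FLANK + 1 :]
            seq_rows = encode_onehot(reduced)
            n_bad[s] = reduced.count("N")
        chain, _ = index.chain(chrom, pos, CHAIN_K)
        X[s, :4, :, 0] = seq_rows
        X[s, 4, :, 0] = chain
    return X, n_bad
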