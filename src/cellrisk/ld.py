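"""Block-diagonal linkage-disequilibrium reference.

LD is stored as a list of dense signed-correlation blocks over contiguous
variant index ranges; correlation across blocks is exactly zero. This is the
structure produced by the synthetic genome generator and the one assumed by
the pruning/clumping and gene-statistic code, which only ever query pairs or
small submatrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BlockLDMatrix:
    """Signed pairwise correlation r, block-diagonal over variant indices.

    Parameters
    ----------
    block_starts
        Start index of each block; blocks are contiguous and cover
        ``0..n_variants`` without gaps.
    blocks
        One dense symmetric matrix of signed r per block, unit diagonal.
    """

    block_starts: np.ndarray
    blocks: list[np.ndarray]
    _block_of: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.block_starts = np.asarray(self.block_starts, dtype=np.int64)
        sizes = [b.shape[0] for b in self.blocks]
        if len(sizes) != len(self.block_starts):
            raise ValueError("block_starts and blocks length mismatch")
        ends = self.block_starts + np.asarray(sizes)
        if len(self.block_starts) > 1 and not np.array_equal(
            ends[:-1], self.block_starts[1:]
        ):
            raise ValueError("blocks must be contiguous")
        self._block_of = np.repeat(np.arange(len(sizes)), sizes)
        for b in self.blocks:
            if b.shape[0] != b.shape[1]:
                raise ValueError("LD blocks must be square")
            if not np.allclose(np.diag(b), 1.0, atol=1e-8):
                raise ValueError("LD blocks must have unit diagonal")
            if not np.allclose(b, b.T, atol=1e-8):
                raise ValueError("LD blocks must be symmetric")
            if np.any(np.abs(b) > 1 + 1e-8):
                raise ValueError("|r| must be <= 1")

    @property
    def n_variants(self) -> int:
        return int(self._block_of.shape[0])

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @classmethod
    def identity(cls, n: int) -> "BlockLDMatrix":
        """No-LD reference: every variant its own block."""
        return cls(np.arange(n), [np.ones((1, 1)) for _ in range(n)])

    def block_of(self, i: int) -> int:
        return int(self._block_of[i])

    def r(self, i: int, j: int) -> float:
        bi, bj = self._block_of[i], self._block_of[j]
        if bi != bj:
            return 0.0
        s = self.block_starts[bi]
        return float(self.blocks[bi][i - s, j - s])

    def r2(self, i: int, j: int) -> float:
        return self.r(i, j) ** 2

    def blockmates(self, i: int) -> np.ndarray:
        """All variant indices in i's block (including i)."""
        b = self._block_of[i]
        s = self.block_starts[b]
        return np.arange(s, s + self.blocks[b].shape[0])

    def neighbors(self, i: int, r2_min: float) -> np.ndarray:
        """Indices j != i with r2(i, j) > r2_min."""
        b = self._block_of[i]
        s = self.block_starts[b]
        row = self.blocks[b][i - s] ** 2
        idx = s + np.nonzero(row > r2_min)[0]
        return idx[idx != i]

    def proxy_counts(self, r2_min: float = 0.8) -> np.ndarray:
        """Per-variant count of distinct other variants with r2 > r2_min."""
        out = np.empty(self.n_variants, dtype=np.int64)
        for s, b in zip(self.block_starts, self.blocks):
            counts = ((b**2) > r2_min).sum(axis=1) - 1  # diagonal always > r2_min
            out[s : s + b.shape[0]] = counts
        return out

    def submatrix_r(self, idx: np.ndarray) -> np.ndarray:
        """Dense signed r over an arbitrary index set (zeros across blocks)."""
        idx = np.asarray(idx, dtype=np.int64)
        k = idx.shape[0]
        out = np.zeros((k, k))
        bl = self._block_of[idx]
        for b in np.unique(bl):
            sel = np.nonzero(bl == b)[0]
            local = idx[sel] - self.block_starts[b]
            out[np.ix_(sel, sel)] = self.blocks[b][np.ix_(local, local)]
        return out
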