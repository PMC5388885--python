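"""Per-position base-count profiles and consensus calling.

A :class:`ConsensusProfile` holds, for every position of an assembled
barcode, the number of reads contributing each of A, C, G, T and N.  The
consensus call at a position is the modal base over A/C/G/T (ties broken
alphabetically and flagged), coverage is the non-N depth, and agreement is
the percentage of covering reads that carry the consensus base.  Masked (N)
bases carry no evidence: they are excluded from both the vote and the
agreement denominator.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

#: Column order of the count matrix.
BASE_COLUMNS = ("A", "C", "G", "T", "N")

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes A=0 C=1 G=2 T=3 N=4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


class ConsensusProfile:
    """Immutable per-position base-count profile with derived consensus calls."""

    def __init__(self, counts: np.ndarray, n_reads_used: int = 0):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 5:
            raise ValueError("counts must be an (n_positions, 5) array")
        self.counts = counts
        self.n_reads_used = int(n_reads_used)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "ConsensusProfile":
        """Stack sequences left-anchored at position 0 and count bases."""
        encoded = [encode(s) for s in seqs]
        if not encoded:
            return cls(np.zeros((0, 5), dtype=np.int64), 0)
        length = max(len(e) for e in encoded)
        counts = np.zeros((length, 5), dtype=np.int64)
        for e in encoded:
            counts[np.arange(len(e)), e] += 1
        return cls(counts, n_reads_used=len(encoded))

    # -- derived quantities ------------------------------------------------
    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        """Non-N depth per position."""
        return self.counts[:, :4].sum(axis=1)

    @property
    def _top(self) -> np.ndarray:
        # argmax over A,C,G,T; numpy takes the first maximum, which is the
        # alphabetical tie-break (A<C<G<T)
        return self.counts[:, :4].argmax(axis=1).astype(np.uint8)

    @property
    def consensus(self) -> str:
        cov = self.coverage
        calls = np.where(cov > 0, self._top, np.uint8(4)).astype(np.uint8)
        return decode(calls)

    @property
    def agreement(self) -> np.ndarray:
        """Percent of covering reads matching the consensus call (0 where uncovered)."""
        cov = self.coverage
        top_count = self.counts[:, :4].max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(cov > 0, 100.0 * top_count / np.maximum(cov, 1), 0.0)
        return pct

    @property
    def tie(self) -> np.ndarray:
        """True where >1 base shares the maximal count (consensus flagged)."""
        c4 = self.counts[:, :4]
        top = c4.max(axis=1)
        return (self.coverage > 0) & ((c4 == top[:, None]).sum(axis=1) > 1)

    # -- transforms --------------------------------------------------------
    def reverse_complement(self) -> "ConsensusProfile":
        """Reverse position order and complement base counts (A<->T, C<->G)."""
        rc = self.counts[::-1][:, [3, 2, 1, 0, 4]]
        return ConsensusProfile(rc.copy(), self.n_reads_used)

    def __getitem__(self, sl: slice) -> "ConsensusProfile":
        if not isinstance(sl, slice):
            raise TypeError("profiles support slicing only")
        return ConsensusProfile(self.counts[sl].copy(), self.n_reads_used)

    # -- reporting ---------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Per-base table: 1-based position, counts, coverage, consensus, agreement."""
        cons = self.consensus
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self) + 1),
                "A": self.counts[:, 0],
                "C": self.counts[:, 1],
                "G": self.counts[:, 2],
                "T": self.counts[:, 3],
                "N": self.counts[:, 4],
                "coverage": self.coverage,
                "consensus": list(cons),
                "agreement_pct": np.round(self.agreement, 2),
                "tie": self.tie,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)
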