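"""Sonication micro-assembly: primer-seeded iterative consensus extension.

A long amplicon is sonicated into short fragments and sequenced; the
assembler rebuilds the amplicon consensus without a reference:

1. every read is quality-masked (Q < 30 -> N) and the read set is doubled by
   adding each read's reverse complement, so fragment orientation never
   matters;
2. reads starting exactly with the forward primer are stacked at position 0
   (the seed);
3. a cursor sweeps the growing profile; at each position the consensus of
   the ``window`` (default 20) bases immediately upstream is computed from
   live counts, and every hitherto-unmerged read whose first ``window``
   bases equal that w-mer is stacked there, extending the profile past its
   end; sweeps repeat until a full pass recruits nothing;
4. the forward primer and the reverse complement of the reverse primer are
   trimmed from the profile ends.

Matching is exact (substitution-only positional model, no indels); an N on
the read is a wildcard, since masked bases carry no evidence either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusProfile, decode, encode
from .errors import SeedFailureError, TrimFailureError
from .seqio import (
    PrimerPair,
    QualityRead,
    mask_low_quality,
    reverse_complement,
)

#: Suffix appended to the read id of the added reverse-complement copy.
RC_SUFFIX = "/rc"


@dataclass
class SMAConfig:
    q_min: int = 30
    window: int = 20
    max_length: int = 5000  # hard cap against runaway extension from chimeras
    trim_max_mismatch: int = 0


class AssemblyState:
    """Growing positional count matrix with an incrementally maintained consensus."""

    def __init__(self, window: int = 20, max_length: int = 5000):
        self.window = int(window)
        self.max_length = int(max_length)
        self.counts = np.zeros((self.max_length, 5), dtype=np.int64)
        self.consensus_codes = np.full(self.max_length, 4, dtype=np.uint8)
        self.length = 0
        self.merged_read_ids: set[str] = set()

    def add_read(self, read_id: str, codes: np.ndarray, start: int) -> None:
        """Stack a read's bases at ``start``; extends and re-calls the consensus."""
        if read_id in self.merged_read_ids:
            raise ValueError(f"read {read_id!r} already merged")
        end = min(start + len(codes), self.max_length)
        codes = codes[: end - start]
        self.counts[np.arange(start, end), codes] += 1
        self.length = max(self.length, end)
        self._refresh(start, end)
        self.merged_read_ids.add(read_id)

    def _refresh(self, start: int, end: int) -> None:
        c4 = self.counts[start:end, :4]
        cov = c4.sum(axis=1)
        top = c4.argmax(axis=1).astype(np.uint8)
        self.consensus_codes[start:end] = np.where(cov > 0, top, np.uint8(4))

    def window_at(self, p: int) -> np.ndarray:
        """Consensus codes of the ``window`` positions upstream of cursor ``p``."""
        return self.consensus_codes[p - self.window : p]

    def to_profile(self) -> ConsensusProfile:
        return ConsensusProfile(
            self.counts[: self.length].copy(), n_reads_used=len(self.merged_read_ids)
        )


def prepare_reads(reads, q_min: int = 30) -> list[QualityRead]:
    """Quality-mask every read, then double the set with reverse complements.

    The output holds each masked read followed by its reverse complement
    (id suffixed ``/rc``, qualities reversed): 2x the input size.
    """
    out: list[QualityRead] = []
    for read in reads:
        masked = mask_low_quality(read, q_min)
        out.append(masked)
        out.append(
            QualityRead(
                read_id=masked.read_id + RC_SUFFIX,
                bases=reverse_complement(masked.bases),
                quals=masked.quals[::-1],
                direction=masked.direction,
            )
        )
    return out


def seed_assembly(
    reads, forward_primer: str, window: int = 20, max_length: int = 5000
) -> AssemblyState:
    """Stack all reads starting exactly with the forward primer at position 0.

    An N on the read is a mismatch here (the primer is known sequence).
    Raises :class:`SeedFailureError` when no read qualifies.
    """
    if not forward_primer:
        raise ValueError("forward primer must be non-empty")
    state = AssemblyState(window=window, max_length=max_length)
    for read in reads:
        if read.bases.startswith(forward_primer):
            state.add_read(read.read_id, encode(read.bases), 0)
    if not state.merged_read_ids:
        raise SeedFailureError(
            f"no read starts with the forward primer {forward_primer!r}"
        )
    return state


class _ReadPool:
    """Unmerged doubled reads indexed by their first ``window`` bases."""

    def __init__(self, reads, window: int, skip_ids: set[str]):
        self.window = window
        self.by_prefix: dict[str, list[tuple[str, np.ndarray]]] = {}
        self.with_n: list[tuple[str, np.ndarray]] = []
        self.n_skipped_short = 0
        for read in reads:
            if read.read_id in skip_ids:
                continue
            if len(read) < window:
                self.n_skipped_short += 1
                continue
            prefix = read.bases[:window]
            entry = (read.read_id, encode(read.bases))
            if "N" in prefix:
                self.with_n.append(entry)
            else:
                self.by_prefix.setdefault(prefix, []).append(entry)

    def take_matching(self, wmer: np.ndarray) -> list[tuple[str, np.ndarray]]:
        """Pop every read whose prefix equals ``wmer`` (read N = wildcard)."""
        out: list[tuple[str, np.ndarray]] = []
        if not (wmer == 4).any():
            out.extend(self.by_prefix.pop(decode(wmer), []))
        else:
            # uncovered consensus position: fall back to a linear scan where
            # a consensus N matches any read base
            remaining: dict[str, list] = {}
            for prefix, entries in self.by_prefix.items():
                codes = encode(prefix)
                if bool(((codes == wmer) | (wmer == 4)).all()):
                    out.extend(entries)
                else:
                    remaining[prefix] = entries
            self.by_prefix = remaining
        if self.with_n:
            kept: list[tuple[str, np.ndarray]] = []
            for entry in self.with_n:
                prefix = entry[1][: self.window]
                ok = ((prefix == wmer) | (prefix == 4) | (wmer == 4)).all()
                (out if ok else kept).append(entry)
            self.with_n = kept
        return out


def extend_assembly(state: AssemblyState, reads, window: int | None = None) -> AssemblyState:
    """Iteratively recruit reads whose prefix matches the upstream window.

    The cursor sweeps p = window .. profile length; recruited reads are
    stacked starting at p - window and may extend the profile.  Sweeps repeat
    until a complete pass recruits no read.  An assembly that stops short is
    returned as-is, not raised.
    """
    w = state.window if window is None else int(window)
    if w != state.window:
        state.window = w
    pool = _ReadPool(reads, w, state.merged_read_ids)
    recruited = True
    while recruited:
        recruited = False
        p = w
        while p <= state.length:
            for read_id, codes in pool.take_matching(state.window_at(p)):
                state.add_read(read_id, codes, p - w)
                recruited = True
            p += 1
    return state


def _terminal_mismatches(consensus: str, expected: str) -> int:
    return sum(1 for a, b in zip(consensus, expected) if a != b)


def trim_primers(
    profile: ConsensusProfile, primers: PrimerPair, max_mismatch: int = 0
) -> ConsensusProfile:
    """Excise the forward primer at the start and revcomp(reverse) at the end.

    Raises :class:`TrimFailureError` (carrying the untrimmed profile) when a
    primer copy is absent within ``max_mismatch`` substitutions — e.g. when
    the assembly stopped short of the far terminus.
    """
    cons = profile.consensus
    fwd = primers.forward
    rev_rc = reverse_complement(primers.reverse)
    if len(cons) < len(fwd) + len(rev_rc):
        raise TrimFailureError(
            f"assembled length {len(cons)} shorter than the two primers", profile
        )
    if _terminal_mismatches(cons[: len(fwd)], fwd) > max_mismatch:
        raise TrimFailureError(
            "forward primer not found at the assembly start", profile
        )
    if _terminal_mismatches(cons[-len(rev_rc) :], rev_rc) > max_mismatch:
        raise TrimFailureError(
            "reverse primer not found at the assembly end", profile
        )
    return profile[len(fwd) : len(cons) - len(rev_rc)]


@dataclass
class SMAResult:
    profile: ConsensusProfile  # primer-trimmed
    untrimmed: ConsensusProfile
    stats: dict = field(default_factory=dict)

    @property
    def barcode(self) -> str:
        return self.profile.consensus


def _source_id(read_id: str) -> str:
    return read_id[: -len(RC_SUFFIX)] if read_id.endswith(RC_SUFFIX) else read_id


def sma_assemble(
    reads, primers: PrimerPair, config: SMAConfig | None = None
) -> SMAResult:
    """Full pipeline: prepare -> seed -> extend to convergence -> trim.

    ``stats`` reports source-read usage: a read and its added reverse
    complement count as one source read, recruited if either copy merged.
    """
    cfg = config or SMAConfig()
    reads = list(reads)
    doubled = prepare_reads(reads, cfg.q_min)
    state = seed_assembly(
        doubled, primers.forward, window=cfg.window, max_length=cfg.max_length
    )
    extend_assembly(state, doubled)
    untrimmed = state.to_profile()
    trimmed = trim_primers(untrimmed, primers, cfg.trim_max_mismatch)
    sources_used = {_source_id(rid) for rid in state.merged_read_ids}
    n_sources = len(reads)
    stats = {
        "reads_in": n_sources,
        "doubled_reads": len(doubled),
        "reads_recruited": len(sources_used),
        "fraction_used": len(sources_used) / n_sources if n_sources else 0.0,
        "assembled_length": len(untrimmed),
        "trimmed_length": len(trimmed),
    }
    return SMAResult(profile=trimmed, untrimmed=untrimmed, stats=stats)
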