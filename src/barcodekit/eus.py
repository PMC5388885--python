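"""Extended-unidirectional consensus assembly of amplicon barcodes.

The strategy: an amplicon is sequenced unidirectionally so that reads extend
far beyond the usual paired-end length.  Reads are quality-masked, filtered
for N content, split by which primer they start with, and stacked —
positionally registered at the primer terminus — into one consensus profile
per direction.  The reverse profile is reverse-complemented and merged with
the forward profile over their longest high-identity suffix/prefix overlap;
inside the overlap base calls from both directions are summed, so agreement
is recomputed from the pooled evidence.

Reads are anchored, not aligned: amplicon reads all start at the primer, so
positional registration is exact and indels are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusProfile, encode
from .errors import (
    AmbiguousDirectionError,
    InsufficientCoverageError,
    MergeError,
)
from .seqio import PrimerPair, QualityRead, mask_low_quality


@dataclass
class FilterReport:
    """Read counts per rejection reason for one colony-filter pass."""

    n_input: int = 0
    n_passed: int = 0
    n_failed_head: int = 0
    n_failed_total: int = 0
    n_too_short: int = 0


@dataclass
class MergeResult:
    """A merged forward+reverse consensus profile and its overlap geometry."""

    profile: ConsensusProfile
    overlap_length: int
    forward_span: tuple[int, int]  # 0-based half-open on the merged coordinates
    reverse_span: tuple[int, int]


@dataclass
class EUSConfig:
    q_min: int = 30
    head_len: int = 20
    max_head_n_frac: float = 0.05
    max_total_n_frac: float = 0.01
    max_primer_mismatch: int = 0
    min_coverage: int = 100
    min_overlap: int = 10
    min_overlap_identity: float = 0.9


@dataclass
class EUSResult:
    merge: MergeResult
    fwd_profile: ConsensusProfile
    rev_profile: ConsensusProfile
    stage_counts: dict = field(default_factory=dict)
    filter_report: FilterReport | None = None

    @property
    def barcode(self) -> str:
        return self.merge.profile.consensus

    @property
    def error_rate_pct(self) -> np.ndarray:
        """Per-position non-consensus base-call rate (percent)."""
        return 100.0 - self.merge.profile.agreement


def filter_colonies(
    reads,
    q_min: int = 30,
    head_len: int = 20,
    max_head_n_frac: float = 0.05,
    max_total_n_frac: float = 0.01,
) -> tuple[list[QualityRead], FilterReport]:
    """Retain quality-masked reads with few Ns at the 5' head and overall.

    A read passes when (Ns in the first ``head_len`` bases)/``head_len`` is
    strictly below ``max_head_n_frac`` AND (total Ns)/length is strictly
    below ``max_total_n_frac``.  Reads shorter than ``head_len`` are rejected
    and counted separately.  ``q_min`` documents the masking threshold the
    reads are expected to have been filtered with; masking itself is
    :func:`barcodekit.seqio.mask_low_quality`.
    """
    report = FilterReport()
    passed: list[QualityRead] = []
    for read in reads:
        report.n_input += 1
        if len(read) < head_len:
            report.n_too_short += 1
            continue
        head_n = read.bases[:head_len].count("N")
        if head_n / head_len >= max_head_n_frac:
            report.n_failed_head += 1
            continue
        total_n = read.bases.count("N")
        if total_n / len(read) >= max_total_n_frac:
            report.n_failed_total += 1
            continue
        passed.append(read)
        report.n_passed += 1
    return passed, report


def _prefix_mismatches(bases: str, primer: str) -> int:
    """Mismatches between a read prefix and a primer; N counts as a mismatch."""
    return sum(1 for a, b in zip(bases, primer) if a != b)


def assign_direction(
    read: QualityRead, primers: PrimerPair, max_mismatch: int = 0
) -> str:
    """Classify a read as forward/reverse/unknown by its primer prefix.

    Raises :class:`AmbiguousDirectionError` if the prefix matches both
    primers within ``max_mismatch`` (degenerate primer design).
    """
    if len(read) <= max(len(primers.forward), len(primers.reverse)):
        return "unknown"
    fwd = _prefix_mismatches(read.bases, primers.forward) <= max_mismatch
    rev = _prefix_mismatches(read.bases, primers.reverse) <= max_mismatch
    if fwd and rev:
        raise AmbiguousDirectionError(
            f"read {read.read_id!r} matches both primers of {primers.locus!r}"
        )
    if fwd:
        return "forward"
    if rev:
        return "reverse"
    return "unknown"


def build_directional_consensus(reads, min_coverage: int = 100) -> ConsensusProfile:
    """Stack same-direction, primer-anchored reads into a consensus profile.

    ``reads`` may be QualityReads or plain sequences; position 0 is the first
    base after the primer anchor.  The profile is truncated at the last
    position whose non-N coverage reaches ``min_coverage``.
    """
    seqs = [r.bases if isinstance(r, QualityRead) else r for r in reads]
    if not seqs:
        raise InsufficientCoverageError("no reads provided for consensus")
    profile = ConsensusProfile.from_sequences(seqs)
    covered = np.nonzero(profile.coverage >= min_coverage)[0]
    if covered.size == 0:
        raise InsufficientCoverageError(
            f"no position reaches coverage {min_coverage} with {len(seqs)} reads"
        )
    return profile[: covered[-1] + 1]


def merge_consensus(
    fwd: ConsensusProfile,
    rev: ConsensusProfile,
    min_overlap: int = 10,
    min_overlap_identity: float = 0.9,
) -> MergeResult:
    """Merge forward and reverse profiles over their best terminal overlap.

    The reverse profile is reverse-complemented; the longest suffix(fwd)/
    prefix(rev-RC) overlap of length >= ``min_overlap`` with consensus
    identity >= ``min_overlap_identity`` is selected.  Base counts are summed
    position-wise inside the overlap, so consensus and agreement there come
    from the pooled forward+reverse evidence.
    """
    if len(fwd) == 0 or len(rev) == 0:
        raise MergeError("cannot merge an empty profile")
    rev_rc = rev.reverse_complement()
    f = encode(fwd.consensus)
    r = encode(rev_rc.consensus)
    n_f, n_r = len(f), len(r)
    for length in range(min(n_f, n_r), min_overlap - 1, -1):
        matches = int((f[n_f - length :] == r[:length]).sum())
        if matches / length >= min_overlap_identity:
            break
    else:
        raise MergeError(
            f"no overlap of >= {min_overlap} bases with identity "
            f">= {min_overlap_identity:.0%} between forward and reverse consensus"
        )
    merged = np.vstack(
        [
            fwd.counts[: n_f - length],
            fwd.counts[n_f - length :] + rev_rc.counts[:length],
            rev_rc.counts[length:],
        ]
    )
    profile = ConsensusProfile(merged, fwd.n_reads_used + rev.n_reads_used)
    return MergeResult(
        profile=profile,
        overlap_length=length,
        forward_span=(0, n_f),
        reverse_span=(n_f - length, n_f - length + n_r),
    )


def eus_assemble(
    reads, primers: PrimerPair, config: EUSConfig | None = None
) -> EUSResult:
    """Full pipeline: mask -> filter -> orient -> per-direction consensus -> merge.

    Raises :class:`InsufficientCoverageError` (naming the direction) when one
    direction cannot sustain ``min_coverage``, and :class:`MergeError` when
    no qualifying forward/reverse overlap exists — the two failure modes are
    reported distinctly.
    """
    cfg = config or EUSConfig()
    masked = [mask_low_quality(r, cfg.q_min) for r in reads]
    passed, report = filter_colonies(
        masked,
        q_min=cfg.q_min,
        head_len=cfg.head_len,
        max_head_n_frac=cfg.max_head_n_frac,
        max_total_n_frac=cfg.max_total_n_frac,
    )
    fwd_seqs: list[str] = []
    rev_seqs: list[str] = []
    for read in passed:
        direction = assign_direction(read, primers, cfg.max_primer_mismatch)
        if direction == "forward":
            fwd_seqs.append(read.bases[len(primers.forward) :])
        elif direction == "reverse":
            rev_seqs.append(read.bases[len(primers.reverse) :])
    stage_counts = {
        "input": report.n_input,
        "passed_filter": report.n_passed,
        "forward": len(fwd_seqs),
        "reverse": len(rev_seqs),
        "unknown_direction": report.n_passed - len(fwd_seqs) - len(rev_seqs),
    }
    try:
        fwd_profile = build_directional_consensus(fwd_seqs, cfg.min_coverage)
    except InsufficientCoverageError as exc:
        raise InsufficientCoverageError(
            f"insufficient coverage in forward consensus: {exc}", "forward"
        ) from exc
    try:
        rev_profile = build_directional_consensus(rev_seqs, cfg.min_coverage)
    except InsufficientCoverageError as exc:
        raise InsufficientCoverageError(
            f"insufficient coverage in reverse consensus: {exc}", "reverse"
        ) from exc
    merge = merge_consensus(
        fwd_profile, rev_profile, cfg.min_overlap, cfg.min_overlap_identity
    )
    return EUSResult(
        merge=merge,
        fwd_profile=fwd_profile,
        rev_profile=rev_profile,
        stage_counts=stage_counts,
        filter_report=report,
    )
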