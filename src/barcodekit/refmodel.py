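"""Reference-database completeness simulation for DNA barcoding.

The model asks how the diagnostic value of a barcode locus changes while a
reference database is being built.  Three objects are involved:

* **CRB** (comprehensive reference barcode database): the ground-truth set of
  all barcodes and species names in a hypothetical region.
* **IRB** (incomplete reference barcode set): a partial snapshot of the CRB
  obtained by drawing individuals uniformly with replacement until a target
  number of distinct species ``N_s`` is reached.
* **ESS** (ecological study set): simulated field specimens, drawn from the
  CRB with replacement, to be identified against an IRB.

Barcodes in an IRB are classified as *perceived species-unique* (one species
name carries the sequence in the IRB), *ambiguous* (several do) or *false
species-unique* (unique in the IRB but shared by several species in the
CRB).  ESS specimens are identified against the IRB by exact sequence match
or by a percent-identity threshold; identifications are *perceived* (one
candidate species), *ambiguous* (several) or *unknown* (none), and perceived
calls are *true* or *false* according to whether the same matching against
the full CRB is also unambiguous.  A threshold scan finds the optimal
similarity threshold O_t that maximizes true identifications.

Decay of the species-unique fraction with database size is summarized by
least-squares fits of power (y = a·x^b) or exponential (y = a·e^(b·x))
curves on the log-linearized model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .errors import CRBBuildError
from .seqio import BarcodeRecord

COMBINED_LOCUS = "rbcL+matK"


# ---------------------------------------------------------------------------
# CRB construction
# ---------------------------------------------------------------------------


@dataclass
class CRBDatabase:
    """Ground-truth barcode database with per-locus sequence->species indexes."""

    records: list[BarcodeRecord]
    loci: set[str] = field(default_factory=set)
    species_index: dict[str, list[BarcodeRecord]] = field(default_factory=dict)
    barcode_index: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def __post_init__(self):
        self.loci = {r.locus for r in self.records}
        self.species_index = {}
        self.barcode_index = {locus: {} for locus in self.loci}
        self._by_specimen_locus: dict[tuple[str, str], BarcodeRecord] = {}
        self._records_by_specimen: dict[str, list[BarcodeRecord]] = {}
        for r in self.records:
            self.species_index.setdefault(r.species, []).append(r)
            self.barcode_index[r.locus].setdefault(r.sequence, set()).add(r.species)
            key = (r.specimen_id, r.locus)
            if key in self._by_specimen_locus:
                raise CRBBuildError(f"duplicate (specimen, locus) pair {key!r}")
            self._by_specimen_locus[key] = r
            self._records_by_specimen.setdefault(r.specimen_id, []).append(r)

    @property
    def species(self) -> list[str]:
        return sorted(self.species_index)

    @property
    def specimens(self) -> list[str]:
        return sorted({r.specimen_id for r in self.records})

    def n_species(self) -> int:
        return len(self.species_index)

    def record_for(self, specimen_id: str, locus: str) -> BarcodeRecord | None:
        return self._by_specimen_locus.get((specimen_id, locus))

    def records_for_specimen(self, specimen_id: str) -> list[BarcodeRecord]:
        return list(self._records_by_specimen.get(specimen_id, []))


def build_crb(
    records: Iterable[BarcodeRecord],
    combine: tuple[str, str] | None = ("rbcL", "matK"),
) -> CRBDatabase:
    """Index labelled barcodes into a CRB; materialize the combined locus.

    When both loci named in ``combine`` are present, every specimen carrying
    both gets an extra concatenated record under the locus ``"rbcL+matK"``
    (locus names joined with '+').  Duplicate (specimen, locus) pairs raise
    :class:`CRBBuildError`.
    """
    records = list(records)
    loci = {r.locus for r in records}
    if combine and set(combine) <= loci:
        first, second = combine
        by_key = {(r.specimen_id, r.locus): r for r in records}
        combined_name = f"{first}+{second}"
        for r in records:
            if r.locus != first:
                continue
            partner = by_key.get((r.specimen_id, second))
            if partner is None:
                continue
            if partner.species != r.species:
                raise CRBBuildError(
                    f"specimen {r.specimen_id!r} carries conflicting species labels"
                )
            records.append(
                BarcodeRecord(
                    species=r.species,
                    specimen_id=r.specimen_id,
                    locus=combined_name,
                    sequence=r.sequence + partner.sequence,
                )
            )
    return CRBDatabase(records=records)


def relabel_by_genus(crb: CRBDatabase) -> CRBDatabase:
    """A copy of the CRB with species labels collapsed to their genus."""
    relabelled = [
        BarcodeRecord(r.genus, r.specimen_id, r.locus, r.sequence)
        for r in crb.records
    ]
    return CRBDatabase(records=relabelled)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


@dataclass
class IRBSample:
    """An incomplete reference set: all records of the drawn specimens."""

    n_species: int
    records: list[BarcodeRecord]
    replicate_id: int = 0
    rng_seed: int | None = None

    def species(self) -> set[str]:
        return {r.species for r in self.records}


@dataclass
class ESSQuerySet:
    """Simulated field specimens: (specimen_id, true species) draws, duplicates kept."""

    samples: list[tuple[str, str]]
    n_species: int


def _draw_specimens(crb: CRBDatabase, n_species: int, rng: np.random.Generator):
    if not 1 <= n_species <= crb.n_species():
        raise ValueError(
            f"n_species={n_species} outside 1..{crb.n_species()} (CRB species count)"
        )
    specimens = crb.specimens
    species_of = {
        s: crb.records_for_specimen(s)[0].species for s in specimens
    }
    draws: list[str] = []
    seen_species: set[str] = set()
    while len(seen_species) < n_species:
        pick = specimens[int(rng.integers(len(specimens)))]
        draws.append(pick)
        seen_species.add(species_of[pick])
    return draws, species_of


def sample_irb(
    crb: CRBDatabase,
    n_species: int,
    rng: np.random.Generator,
    replicate_id: int = 0,
    rng_seed: int | None = None,
) -> IRBSample:
    """Draw individuals with replacement until ``n_species`` distinct species.

    Duplicate draws collapse; the sample holds every record (all loci) of the
    drawn specimens.  Deterministic for a given generator state.
    """
    draws, _ = _draw_specimens(crb, n_species, rng)
    chosen = sorted(set(draws))
    records = [r for s in chosen for r in crb.records_for_specimen(s)]
    return IRBSample(
        n_species=n_species,
        records=records,
        replicate_id=replicate_id,
        rng_seed=rng_seed,
    )


def sample_ess(
    crb: CRBDatabase, n_species: int, rng: np.random.Generator
) -> ESSQuerySet:
    """As :func:`sample_irb` but duplicates are retained as separate queries."""
    draws, species_of = _draw_specimens(crb, n_species, rng)
    return ESSQuerySet(
        samples=[(s, species_of[s]) for s in draws], n_species=n_species
    )


# ---------------------------------------------------------------------------
# Classification of IRB barcodes
# ---------------------------------------------------------------------------


@dataclass
class ClassificationSummary:
    """Category percentages over distinct IRB barcode sequences of one locus."""

    locus: str
    n_barcodes: int
    pct_perceived: float
    pct_ambiguous: float
    pct_false: float


def classify_barcodes(
    irb: IRBSample, crb: CRBDatabase, locus: str
) -> ClassificationSummary:
    """Classify distinct IRB barcodes as perceived/ambiguous/false species-unique.

    Perceived: carried by exactly one IRB species.  Ambiguous: by more than
    one.  False: perceived in the IRB yet carried by more than one species in
    the CRB.  Percentages are over distinct IRB sequences.
    """
    if locus not in crb.loci:
        raise ValueError(f"locus {locus!r} not present in the CRB")
    irb_seqs: dict[str, set[str]] = {}
    for r in irb.records:
        if r.locus == locus:
            irb_seqs.setdefault(r.sequence, set()).add(r.species)
    if not irb_seqs:
        raise ValueError(f"IRB holds no records for locus {locus!r}")
    n = len(irb_seqs)
    crb_index = crb.barcode_index[locus]
    n_perceived = n_ambiguous = n_false = 0
    for seq, species in irb_seqs.items():
        if len(species) == 1:
            n_perceived += 1
            if len(crb_index[seq]) > 1:
                n_false += 1
        else:
            n_ambiguous += 1
    return ClassificationSummary(
        locus=locus,
        n_barcodes=n,
        pct_perceived=100.0 * n_perceived / n,
        pct_ambiguous=100.0 * n_ambiguous / n,
        pct_false=100.0 * n_false / n,
    )


# ---------------------------------------------------------------------------
# Percent identity
# ---------------------------------------------------------------------------


def percent_identity(a: str, b: str) -> float:
    """Percent identity between two sequences.

    Equal lengths: matching positions / columns, with any column containing
    an N excluded from both numerator and denominator.  Unequal lengths:
    global (Needleman-Wunsch) alignment via edlib; identity = matching
    columns / alignment columns.
    """
    if len(a) == len(b):
        ca = np.frombuffer(a.encode(), dtype=np.uint8)
        cb = np.frombuffer(b.encode(), dtype=np.uint8)
        n_code = ord("N")
        valid = (ca != n_code) & (cb != n_code)
        denom = int(valid.sum())
        if denom == 0:
            return 0.0
        return 100.0 * int((ca[valid] == cb[valid]).sum()) / denom
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    matched = nice["matched_aligned"]
    return 100.0 * matched.count("|") / len(matched)


def _identity_matrix(queries: Sequence[str], refs: Sequence[str]) -> np.ndarray:
    """Pairwise percent identity, vectorized over equal-length reference groups."""
    out = np.zeros((len(queries), len(refs)))
    n_code = ord("N")
    by_len: dict[int, list[int]] = {}
    for j, r in enumerate(refs):
        by_len.setdefault(len(r), []).append(j)
    ref_arrays = {
        length: np.frombuffer(
            "".join(refs[j] for j in idx).encode(), dtype=np.uint8
        ).reshape(len(idx), length)
        for length, idx in by_len.items()
    }
    for i, q in enumerate(queries):
        cq = np.frombuffer(q.encode(), dtype=np.uint8)
        for length, idx in by_len.items():
            if length == len(q):
                mat = ref_arrays[length]
                valid = (mat != n_code) & (cq != n_code)[None, :]
                denom = valid.sum(axis=1)
                matches = ((mat == cq[None, :]) & valid).sum(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ids = np.where(denom > 0, 100.0 * matches / np.maximum(denom, 1), 0.0)
                out[i, idx] = ids
            else:
                for j in idx:
                    out[i, j] = percent_identity(q, refs[j])
    return out


# ---------------------------------------------------------------------------
# Identification of ESS specimens
# ---------------------------------------------------------------------------


@dataclass
class IdentificationSummary:
    """Outcome percentages for one ESS-vs-IRB identification run."""

    pct_perceived: float
    pct_ambiguous: float
    pct_unknown: float
    pct_true: float
    pct_false: float
    threshold: float | str  # percent identity, or "exact"


def _locus_index(records: Iterable[BarcodeRecord], locus: str) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for r in records:
        if r.locus == locus:
            index.setdefault(r.sequence, set()).add(r.species)
    return index


def _query_sequences(ess: ESSQuerySet, crb: CRBDatabase, locus: str) -> list[str]:
    seqs = []
    for specimen_id, _species in ess.samples:
        rec = crb.record_for(specimen_id, locus)
        if rec is None:
            raise ValueError(
                f"specimen {specimen_id!r} has no {locus!r} record in the CRB"
            )
        seqs.append(rec.sequence)
    return seqs


def _summarize(
    query_seqs: list[str],
    irb_candidates,
    crb_candidates,
    threshold,
) -> IdentificationSummary:
    n = len(query_seqs)
    n_perc = n_amb = n_unk = n_true = n_false = 0
    for q in query_seqs:
        cand = irb_candidates(q)
        if len(cand) == 0:
            n_unk += 1
        elif len(cand) > 1:
            n_amb += 1
        else:
            n_perc += 1
            if len(crb_candidates(q)) > 1:
                n_false += 1
            else:
                n_true += 1
    return IdentificationSummary(
        pct_perceived=100.0 * n_perc / n,
        pct_ambiguous=100.0 * n_amb / n,
        pct_unknown=100.0 * n_unk / n,
        pct_true=100.0 * n_true / n,
        pct_false=100.0 * n_false / n,
        threshold=threshold,
    )


def identify(
    ess: ESSQuerySet,
    irb: IRBSample,
    crb: CRBDatabase,
    locus: str,
    mode: str = "exact",
    threshold: float | None = None,
) -> IdentificationSummary:
    """Identify each ESS specimen against the IRB; audit truth against the CRB.

    ``mode="exact"`` requires sequence equality; ``mode="threshold"`` accepts
    any IRB barcode with percent identity >= ``threshold``.  A query with one
    candidate species is perceived, several is ambiguous, none is unknown.
    A perceived query whose candidate set under the *same* matching against
    the full CRB contains more than one species is a false identification.
    """
    if mode == "threshold":
        if threshold is None or not 90.0 <= threshold <= 100.0:
            raise ValueError("threshold mode needs a threshold in [90, 100]")
    elif mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    query_seqs = _query_sequences(ess, crb, locus)
    irb_index = _locus_index(irb.records, locus)
    crb_index = crb.barcode_index[locus]
    if mode == "exact":
        irb_cand = lambda q: irb_index.get(q, set())
        crb_cand = lambda q: crb_index.get(q, set())
        return _summarize(query_seqs, irb_cand, crb_cand, "exact")

    distinct_q = sorted(set(query_seqs))
    irb_refs = sorted(irb_index)
    crb_refs = sorted(crb_index)
    m_irb = _identity_matrix(distinct_q, irb_refs)
    m_crb = _identity_matrix(distinct_q, crb_refs)
    qi = {q: i for i, q in enumerate(distinct_q)}

    def irb_cand(q):
        hits = np.nonzero(m_irb[qi[q]] >= threshold)[0]
        return set().union(*(irb_index[irb_refs[j]] for j in hits)) if hits.size else set()

    def crb_cand(q):
        hits = np.nonzero(m_crb[qi[q]] >= threshold)[0]
        return set().union(*(crb_index[crb_refs[j]] for j in hits)) if hits.size else set()

    return _summarize(query_seqs, irb_cand, crb_cand, float(threshold))


# ---------------------------------------------------------------------------
# Threshold scan
# ---------------------------------------------------------------------------


@dataclass
class ThresholdScan:
    grid: list[float]
    summaries: list[IdentificationSummary]
    o_t: float


def default_threshold_grid() -> list[float]:
    """97.0 .. 99.9 percent identity in 0.1 steps."""
    return [round(97.0 + 0.1 * i, 1) for i in range(30)]


def scan_thresholds(
    ess: ESSQuerySet,
    irb: IRBSample,
    crb: CRBDatabase,
    locus: str,
    grid: Sequence[float] | None = None,
) -> ThresholdScan:
    """Run threshold identification over a grid; O_t maximizes pct_true.

    Ties are broken toward the highest (most stringent) threshold.  Identity
    matrices are computed once and reused across the grid.
    """
    grid = list(grid) if grid is not None else default_threshold_grid()
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    query_seqs = _query_sequences(ess, crb, locus)
    irb_index = _locus_index(irb.records, locus)
    crb_index = crb.barcode_index[locus]
    distinct_q = sorted(set(query_seqs))
    irb_refs = sorted(irb_index)
    crb_refs = sorted(crb_index)
    m_irb = _identity_matrix(distinct_q, irb_refs)
    m_crb = _identity_matrix(distinct_q, crb_refs)
    qi = {q: i for i, q in enumerate(distinct_q)}
    summaries = []
    for t in grid:
        def irb_cand(q, t=t):
            hits = np.nonzero(m_irb[qi[q]] >= t)[0]
            return set().union(*(irb_index[irb_refs[j]] for j in hits)) if hits.size else set()

        def crb_cand(q, t=t):
            hits = np.nonzero(m_crb[qi[q]] >= t)[0]
            return set().union(*(crb_index[crb_refs[j]] for j in hits)) if hits.size else set()

        summaries.append(_summarize(query_seqs, irb_cand, crb_cand, float(t)))
    best = max(range(len(grid)), key=lambda i: (summaries[i].pct_true, grid[i]))
    return ThresholdScan(grid=grid, summaries=summaries, o_t=grid[best])


# ---------------------------------------------------------------------------
# IRB-size experiment
# ---------------------------------------------------------------------------


def run_irb_size_experiment(
    crb: CRBDatabase,
    locus: str,
    n_grid: Sequence[int],
    replicates: int = 200,
    base_seed: int = 0,
    genus_level: bool = False,
) -> pd.DataFrame:
    """Mean/SD classification percentages over replicate IRBs per N_s.

    Each replicate uses an independent generator seeded ``base_seed +
    replicate_id`` so replicates are reproducible in isolation.  With
    ``genus_level`` the CRB is relabelled to genera before sampling.
    """
    db = relabel_by_genus(crb) if genus_level else crb
    rows = []
    for n in n_grid:
        per_rep = []
        for rep in range(replicates):
            seed = base_seed + rep
            rng = np.random.default_rng(seed)
            irb = sample_irb(db, n, rng, replicate_id=rep, rng_seed=seed)
            s = classify_barcodes(irb, db, locus)
            per_rep.append((s.pct_perceived, s.pct_ambiguous, s.pct_false))
        arr = np.array(per_rep)
        rows.append(
            {
                "n_species": n,
                "pct_perceived_mean": arr[:, 0].mean(),
                "pct_perceived_sd": arr[:, 0].std(ddof=1) if len(arr) > 1 else 0.0,
                "pct_ambiguous_mean": arr[:, 1].mean(),
                "pct_ambiguous_sd": arr[:, 1].std(ddof=1) if len(arr) > 1 else 0.0,
                "pct_false_mean": arr[:, 2].mean(),
                "pct_false_sd": arr[:, 2].std(ddof=1) if len(arr) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decay-curve fitting and worked arithmetic
# ---------------------------------------------------------------------------


@dataclass
class DecayFit:
    """Least-squares fit of y = a·x^b (power) or y = a·e^(b·x) (exponential)."""

    model: str
    a: float
    b: float
    r_squared: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.model == "power":
            return self.a * x**self.b
        return self.a * np.exp(self.b * x)


def fit_decay_curve(xs, ys, model: str = "power") -> DecayFit:
    """Fit a decay curve by linear least squares on the log-transformed model.

    Power: ln y regressed on ln x.  Exponential: ln y regressed on x.
    R² is reported on the log scale.  Non-positive data raise ValueError.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 3:
        raise ValueError("xs and ys must be equal-length with at least 3 points")
    if (xs <= 0).any() or (ys <= 0).any():
        raise ValueError("decay-curve fitting requires strictly positive data")
    if model == "power":
        design = np.log(xs)
    elif model == "exponential":
        design = xs
    else:
        raise ValueError(f"unknown model {model!r}")
    logy = np.log(ys)
    b, log_a = np.polyfit(design, logy, 1)
    fitted = log_a + b * design
    ss_res = float(((logy - fitted) ** 2).sum())
    ss_tot = float(((logy - logy.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DecayFit(model=model, a=float(np.exp(log_a)), b=float(b), r_squared=r2)


def shared_overlap(intervals: Sequence[tuple[int, int]]) -> int:
    """Length of the intersection of half-open locus intervals (0 if empty)."""
    intervals = list(intervals)
    if not intervals:
        raise ValueError("need at least one interval")
    for start, end in intervals:
        if end <= start:
            raise ValueError(f"invalid interval ({start}, {end})")
    lo = max(s for s, _ in intervals)
    hi = min(e for _, e in intervals)
    return max(0, hi - lo)


def filter_by_length(
    records: Sequence[BarcodeRecord], min_len: int
) -> tuple[list[BarcodeRecord], float]:
    """Drop records shorter than ``min_len``; report the percentage removed."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [r for r in records if len(r.sequence) >= min_len]
    pct_removed = (
        100.0 * (len(records) - len(kept)) / len(records) if records else 0.0
    )
    return kept, pct_removed


def coverage_projection(
    n_both_barcodes: int, n_total_species: int, years_elapsed: float
) -> dict:
    """Project years to complete species coverage at the historical accession rate.

    Coverage and the per-annum rate are rounded to the nearest integer as in
    back-of-envelope reporting; the remaining time is the integer part of
    (missing species)/rate, to be read as a ">= that many years" bound.
    """
    if n_total_species <= 0 or years_elapsed <= 0:
        raise ValueError("species total and elapsed years must be positive")
    rate = round(n_both_barcodes / years_elapsed)
    if rate == 0:
        raise ValueError("accession rate rounds to zero; projection undefined")
    coverage_pct = round(100.0 * n_both_barcodes / n_total_species)
    years_remaining = int((n_total_species - n_both_barcodes) / rate)
    return {
        "coverage_pct": coverage_pct,
        "rate_per_annum": rate,
        "years_remaining": years_remaining,
    }
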