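"""Synthetic barcode databases and sequencer reads.

Everything here is a pure function of its seed: identical configurations
produce byte-identical output, so every downstream component can be tested
against a known generating truth without external data.

The database generator emulates a regional flora: each species' barcode
derives from a common root sequence by per-site substitution at the
interspecific rate, intraspecific variants re-mutate the species sequence at
a (much lower) intraspecific rate, and with a configurable probability a
species instead copies an earlier species' barcodes verbatim — deliberately
non-diagnostic barcodes whose sharing structure is recorded exactly in a
truth report.

The read generators emulate two library types:

* extended unidirectional amplicon reads — exact template prefixes (forward
  strand or reverse-complement strand) with a substitution probability that
  interpolates linearly from the 5' to the 3' end of the read, emulating the
  rising error of long sequencing runs;
* sonicated fragments — each template molecule is cut end-to-end into
  fragments with Normal-distributed lengths, each fragment is read (possibly
  flipped) with a flat substitution rate.

Quality values are two-valued: 38, or 20 with probability ``p_lowq`` (below
the Q30 masking threshold), which is sufficient to exercise threshold-based
masking.  The error model is substitution-only, matching the positional
counting assumption of both assemblers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .refmodel import CRBDatabase, build_crb
from .seqio import BarcodeRecord, QualityRead, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

HIGH_Q = 38
LOW_Q = 20


@dataclass
class SynthConfig:
    """Parameters of the synthetic reference-database generator."""

    n_species: int = 50
    variants_per_species: int = 2
    loci: dict[str, int] = field(
        default_factory=lambda: {"rbcL": 599, "matK": 899}
    )
    d_inter: float = 0.02  # per-site interspecific substitution probability
    d_intra: float = 0.001  # per-site intraspecific substitution probability
    p_share: float = 0.0  # probability a species copies an earlier species
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("d_inter", "d_intra", "p_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(length <= 0 for length in self.loci.values()):
            raise ValueError("locus lengths must be positive")


@dataclass
class ReadSimConfig:
    """Parameters of the read simulators."""

    n_reads: int = 1000
    read_length: int = 300
    error_rate_5prime: float = 0.005
    error_rate_3prime: float = 0.025
    p_lowq: float = 0.005
    fragment_mean: float = 280.0
    fragment_sd: float = 60.0
    orientation_mix: float = 0.5  # fraction of reads in the forward direction
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("error_rate_5prime", "error_rate_3prime", "p_lowq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.orientation_mix <= 1.0:
            raise ValueError("orientation_mix outside [0, 1]")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT sequence."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``rate`` to a different base."""
    if rate == 0.0:
        return seq
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(codes)) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != codes[i]]
        codes[i] = choices[rng.integers(0, len(choices))]
    return codes.tobytes().decode("ascii")


def simulate_crb(config: SynthConfig) -> tuple[CRBDatabase, list[set[str]]]:
    """Generate a labelled CRB plus the exact shared-barcode truth report.

    Returns ``(crb, shared_sets)`` where ``shared_sets`` lists every group of
    >= 2 species whose canonical barcodes are identical by construction
    (verbatim copies injected with probability ``p_share``).
    """
    rng = np.random.default_rng(config.rng_seed)
    roots = {
        locus: random_sequence(length, rng) for locus, length in config.loci.items()
    }
    species_names = [f"Genus{1 + i // 5} species{i + 1}" for i in range(config.n_species)]
    canonical: list[dict[str, str]] = []
    source_of: list[int] = []  # index of the species whose barcode set was copied
    for i in range(config.n_species):
        if i > 0 and rng.random() < config.p_share:
            donor = int(rng.integers(0, i))
            canonical.append(canonical[donor])
            source_of.append(source_of[donor])
        else:
            canonical.append(
                {
                    locus: mutate(root, config.d_inter, rng)
                    for locus, root in roots.items()
                }
            )
            source_of.append(i)
    records: list[BarcodeRecord] = []
    for i, name in enumerate(species_names):
        for v in range(config.variants_per_species):
            specimen = f"sp{i + 1}_v{v + 1}"
            for locus in config.loci:
                seq = canonical[i][locus]
                if v > 0:
                    seq = mutate(seq, config.d_intra, rng)
                records.append(BarcodeRecord(name, specimen, locus, seq))
    groups: dict[int, set[str]] = {}
    for i, src in enumerate(source_of):
        groups.setdefault(src, set()).add(species_names[i])
    shared_sets = [g for g in groups.values() if len(g) > 1]
    return build_crb(records), shared_sets


def _apply_errors(
    codes: np.ndarray, error_prob: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    hit = np.nonzero(rng.random(len(codes)) < error_prob)[0]
    if hit.size:
        codes = codes.copy()
        for i in hit:
            choices = _BASES[_BASES != codes[i]]
            codes[i] = choices[rng.integers(0, len(choices))]
    return codes


def _qualities(length: int, p_lowq: float, rng: np.random.Generator) -> np.ndarray:
    quals = np.full(length, HIGH_Q, dtype=int)
    quals[rng.random(length) < p_lowq] = LOW_Q
    return quals


def simulate_eus_reads(
    template: str, config: ReadSimConfig
) -> tuple[list[QualityRead], list[QualityRead]]:
    """Simulate extended unidirectional reads of a primer-flanked amplicon.

    Forward reads copy the template 5' prefix, reverse reads the 5' prefix of
    the reverse-complement strand.  The substitution probability interpolates
    linearly from ``error_rate_5prime`` to ``error_rate_3prime`` along the
    read.  Returns ``(forward_reads, reverse_reads)`` with
    ``len(forward) == round(n_reads * orientation_mix)``.
    """
    if config.read_length > len(template):
        raise ValueError("read_length exceeds the template length")
    rng = np.random.default_rng(config.rng_seed)
    error_prob = np.linspace(
        config.error_rate_5prime, config.error_rate_3prime, config.read_length
    )
    fwd_template = np.frombuffer(
        template[: config.read_length].encode(), dtype=np.uint8
    )
    rev_template = np.frombuffer(
        reverse_complement(template)[: config.read_length].encode(), dtype=np.uint8
    )
    n_fwd = round(config.n_reads * config.orientation_mix)
    fwd, rev = [], []
    for i in range(config.n_reads):
        forward = i < n_fwd
        base = fwd_template if forward else rev_template
        codes = _apply_errors(base, error_prob, rng)
        quals = _qualities(config.read_length, config.p_lowq, rng)
        read = QualityRead(
            read_id=f"eus_{'f' if forward else 'r'}{i + 1}",
            bases=codes.tobytes().decode("ascii"),
            quals=tuple(quals),
            direction="forward" if forward else "reverse",
        )
        (fwd if forward else rev).append(read)
    return fwd, rev


def simulate_sma_reads(
    template: str, config: ReadSimConfig, min_fragment: int = 21
) -> list[QualityRead]:
    """Simulate sonicated-fragment reads of a template amplicon.

    Template molecules are fragmented one at a time: cut points advance from
    the 5' end by Normal(fragment_mean, fragment_sd) draws (clipped to
    [min_fragment, template length]) until the molecule is exhausted, so
    every molecule yields fragments flush with both amplicon ends — the
    primer-anchored reads the micro-assembler seeds from.  Each fragment is
    read up to ``read_length`` bases, flipped to the reverse strand with
    probability 0.5, with flat substitution rate ``error_rate_5prime``.
    Fragments shorter than ``min_fragment`` (terminal offcuts) are dropped.
    """
    rng = np.random.default_rng(config.rng_seed)
    t_codes = np.frombuffer(template.encode(), dtype=np.uint8)
    length = len(template)
    reads: list[QualityRead] = []
    flat_rate = np.full(config.read_length, config.error_rate_5prime)
    i = 0
    while len(reads) < config.n_reads:
        # fragment one molecule end-to-end
        pos = 0
        while pos < length and len(reads) < config.n_reads:
            frag_len = int(
                np.clip(
                    rng.normal(config.fragment_mean, config.fragment_sd),
                    min_fragment,
                    length,
                )
            )
            end = min(pos + frag_len, length)
            if end - pos >= min_fragment:
                codes = t_codes[pos:end][: config.read_length]
                codes = _apply_errors(codes, flat_rate[: len(codes)], rng)
                bases = codes.tobytes().decode("ascii")
                if rng.random() < 0.5:
                    bases = reverse_complement(bases)
                quals = _qualities(len(bases), config.p_lowq, rng)
                i += 1
                reads.append(
                    QualityRead(
                        read_id=f"sma_{i}", bases=bases, quals=tuple(quals)
                    )
                )
            pos = end
    return reads
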