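# Methods

This note records the models implemented in `barcodekit`, their
assumptions, the defaults that matter, and the design choices made where
several readings were defensible.

## Sequence handling

All sequences are normalized to `{A, C, G, T, N}`: lowercase is uppercased
and every other character (IUPAC ambiguity codes, `U`, gaps) becomes `N`.
Both assemblers and the database model are defined only over this alphabet,
so ambiguity codes would otherwise require arbitrary semantics in the
positional counting.

Quality masking replaces every base with Phred quality strictly below 30
with `N` and leaves the quality string untouched, making the operation
idempotent. Q30 (one error per thousand bases) is the conventional
good-base cut-off for Illumina data; Q = 30 itself is kept. The same
masking rule is used by both assembly pipelines. FASTQ input is assumed
Phred+33; the offset is configurable (`offset=64` for legacy encodings).

Coordinates are 0-based half-open internally; user-facing tables (per-base
TSV profiles) are 1-based inclusive.

## Consensus profiles

A consensus profile is an `(L, 5)` count matrix over A/C/G/T/N. Coverage
at a position is the non-N depth; the consensus call is the modal base over
A/C/G/T; agreement is `100 · modal count / coverage`. Masked bases (`N`)
are excluded from both the vote and the agreement denominator, because a
masked base carries no evidence for or against any call. Modal ties are
broken alphabetically (A < C < G < T) and flagged in the output table; at
the coverage depths these pipelines are built for (≥ 100×), ties occur
only at essentially uncovered positions.

## Extended-unidirectional (EUS) assembly

Assumptions: all reads of a sample come from one amplicon; every read
begins at a primer; read errors are substitutions (no indels), so a read is
positionally registered by its primer anchor and never aligned.

Pipeline: mask → N-content filter → orientation assignment →
per-direction consensus → reverse-complement merge.

* **Colony filter.** A read passes when `< 5%` of its first 20 bases and
  `< 1%` of all its bases are N — strict inequalities, so a single masked
  base in the 20-base head (5%) already rejects. Reads shorter than the
  head window are rejected and counted separately.
* **Orientation.** A read is forward/reverse if its prefix equals the
  forward/reverse primer within `max_primer_mismatch` (default 0; read-side
  N counts as a mismatch, the primer being known sequence). A prefix
  matching both primers raises an error — that is a primer-design problem,
  not a data problem.
* **Directional consensus.** Reads are stacked at position 0 = first base
  after the primer. The profile is truncated at the last position whose
  coverage reaches `min_coverage` (default 100, the depth at which the
  protocol's failures were defined; toy tests lower it). Zero usable reads
  in a direction is reported as an insufficient-coverage failure naming the
  direction, distinct from a merge failure.
* **Merge.** The reverse profile is reverse-complemented (row order
  reversed, A↔T and C↔G columns swapped). Candidate overlaps are scored on
  the two consensus strings — the high per-direction agreement is what makes
  merging on consensus rather than on raw reads sound — and the longest
  suffix/prefix overlap with length ≥ `min_overlap` (default 10, the lower
  end of overlaps observed in practice) and identity ≥ 90% is chosen.
  Inside the overlap the two count matrices are summed and consensus,
  coverage and agreement are recomputed from the pooled counts, so the
  overlap region ends up better supported than either direction alone.

## Sonication micro-assembly (SMA)

Assumptions: fragments densely tile the amplicon; at least one fragment
starts exactly at the forward primer; errors are substitutions.

* **Prepare.** Mask, then double the read set by appending each read's
  reverse complement (qualities reversed). Fragment orientation is unknown
  after library preparation; doubling guarantees the forward-strand copy of
  every fragment exists.
* **Seed.** All reads whose prefix equals the forward primer exactly are
  stacked at position 0. No seed reads is a hard failure.
* **Extend.** A cursor sweeps positions `window … L`. At cursor `p` the
  consensus of the `window` (default 20) positions upstream is taken from
  the live counts — it can change as reads are added — and every unmerged
  read whose **first** `window` bases equal that w-mer is stacked starting
  at `p − window`, possibly extending the profile. Prefix anchoring is the
  minimal reading of "reads matching the upstream window" and makes the
  placement offset unambiguous. A read-side N matches any base (a masked
  base should not block recruitment); mismatches are not allowed by default
  (`window` errors would otherwise admit wrong placements; the flag exists
  but only 0 is implemented). Sweeps repeat until a full pass recruits
  nothing; the merged-read set guarantees termination, and a hard cap
  (default 5,000 positions) aborts runaway extension from chimeric input.
  An assembly that stops short is returned and reported, not raised.
* **Trim.** The forward primer must sit at the profile start and the
  reverse complement of the reverse primer at its end, within
  `trim_max_mismatch` (default 0); both are excised. A missing terminus
  (assembly stopped short) raises a trim failure that carries the untrimmed
  profile.
* **Usage statistic.** The fraction of reads used counts *source* reads: a
  read and its added reverse complement count once, recruited if either
  copy merged. Under a 1% substitution error, the expected fraction is
  ≈ 0.99²⁰ ≈ 0.82 — reads with an error inside the 20-base anchor prefix
  are never recruited — which matches the recruitment levels reported for
  the protocol in practice.

Coverage is reported, never enforced: minimum reportable coverage is 1.

## Reference-database model

The comprehensive reference barcode database (CRB) is the ground truth for
a hypothetical region: every record carries species, specimen, locus and
sequence. Indexes map each distinct sequence per locus to the set of
species carrying it. When both `rbcL` and `matK` are present, a combined
`rbcL+matK` locus is materialized by concatenating the two sequences of any
specimen carrying both.

* **IRB sampling** draws whole specimens uniformly with replacement until
  the target number of distinct species `N_s` is reached; duplicate draws
  collapse. Sampling specimens (rather than single-locus records) means one
  IRB replicate can be classified for every locus at the same `N_s`.
* **Classification** is over *distinct* IRB sequences of a locus:
  *perceived species-unique* (one IRB species), *ambiguous* (> 1),
  *false species-unique* (perceived, but > 1 species in the CRB index).
  Distinct sequences are counted because duplicate records add no
  diagnostic information. Note that with intraspecific variants an
  `N_s = max` IRB is not the CRB (it has all species, not all specimens), so
  the false fraction approaches but need not reach zero until the IRB
  literally equals the CRB.
* **ESS identification**: field specimens are drawn like an IRB but
  duplicates are kept as separate queries (they are separate field
  collections). A query's candidate species are those owning ≥ 1 IRB
  barcode that matches it — exactly, or with percent identity ≥ t. One
  candidate → perceived; several → ambiguous; none → unknown. Truth is
  audited by re-running the *same* matching against the full CRB: a
  perceived query whose CRB candidate set holds > 1 species is false. (An
  alternative truth — compare to the query's source label — is a
  one-line change but is not the default, since the CRB audit generalizes
  the exact-match definition to thresholds.)
* **Percent identity**: equal-length sequences are compared position-wise
  with any column containing an N dropped from numerator and denominator;
  unequal lengths fall back to global Needleman–Wunsch alignment (edlib)
  with identity = matching columns / alignment columns. Synthetic loci are
  equal-length, so the alignment path is the fallback.
* **Threshold scan**: identification is run over a grid (default 97.0–99.9%
  in 0.1 steps); the optimal threshold `O_t` maximizes the true-identification
  percentage, ties broken toward the most stringent threshold (stringency is
  the safer error direction for reference databases).
* **IRB-size experiment**: per `N_s`, `replicates` (default 200) IRBs are
  sampled and classified; means and standard deviations are tabulated.
  Replicate r uses its own generator seeded `base_seed + r`, so any single
  replicate is reproducible in isolation. A genus-level mode relabels every
  record to the first whitespace token of its species name before sampling.
* **Decay fits**: `y = a·x^b` and `y = a·e^(b·x)` are fit by ordinary least
  squares on the log-linearized form (ln y vs ln x, or ln y vs x); R² is
  reported on the log scale. Non-positive data are rejected rather than
  silently dropped. On noise-free generated data the printed coefficients
  are recovered to numerical precision.
* **Auxiliary arithmetic**: `shared_overlap` intersects half-open alignment
  intervals; `filter_by_length` removes short records and reports the
  percentage lost; `coverage_projection` turns (species with both core
  barcodes, total species, elapsed years) into a coverage percentage, an
  integer accession rate per annum and the integer part of the remaining
  years — read as a "more than" bound, since accession rates decline as the
  easy species are exhausted.

## Synthetic data

The generators are pure functions of their seed (byte-identical reruns).

* **Database**: one random root sequence per locus; each species mutates
  every site independently with probability `d_inter` (default 0.02, giving
  ≈ 4% pairwise interspecific divergence); each additional intraspecific
  variant re-mutates its species sequence at `d_intra` (default 0.001, the
  ≈ 0.1% scale of conspecific plastid variation); with probability
  `p_share` a species instead copies an earlier species' barcodes verbatim.
  Sharing by verbatim copy (not convergent mutation) makes the
  shared-barcode truth report exact by construction; the first specimen of
  each species carries the canonical sequence.
* **Extended unidirectional reads** copy the template 5' prefix (forward)
  or the reverse-complement strand's 5' prefix (reverse); the substitution
  probability interpolates linearly from `error_rate_5prime` (default
  0.005) to `error_rate_3prime` (default 0.025), emulating the rising error
  of long unidirectional runs — lowest near the primers, highest in the
  merge region.
* **Fragment reads** are generated by molecule-level fragmentation: each
  template molecule is cut end-to-end into pieces whose lengths are drawn
  from Normal(`fragment_mean` = 280, `fragment_sd` = 60), clipped below at
  21 bases; terminal offcuts shorter than that are discarded. Cutting whole
  molecules (rather than sampling fragment starts uniformly) reflects how
  shearing actually behaves and guarantees a steady supply of fragments
  flush with the amplicon ends — the primer-anchored reads the
  micro-assembler seeds from. Fragment reads use a flat substitution rate
  (`error_rate_5prime`; 0.01 in the shipped examples, the scale consistent
  with the 1–4% non-consensus call rates seen in fragment data). Each
  fragment is read up to `read_length` bases and flipped to the reverse
  strand with probability 0.5.
* **Quality model** is two-valued: Phred 38, or 20 with probability
  `p_lowq` (default 0.005). The masking logic is threshold-based, so two
  levels exercise it fully.

What the generators do **not** emulate: indels and homopolymer artefacts
(both assemblers are substitution-only by design), phylogenetic structure
(no tree, no rate heterogeneity, no base-composition bias), chimeric reads,
locus length variation within a database, and correlated error between
reads of one cluster. Passing tests therefore demonstrate correctness of
the algorithms under their stated model, not robustness to indel-rich or
structurally biased real data.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale: 599–1,600-base
templates, 400–800 extended reads or 1,500–3,000 fragment reads per
assembly (≥ 150× coverage), 50-species databases with 200 IRB replicates —
sizes chosen so the full suite completes in well under a minute per
component while keeping every coverage-dependent code path (filter
boundaries, overlap search, threshold scans) in its intended regime.

## Known limitations

* No indel handling anywhere in the assemblers; a single insertion in a
  high-frequency read subpopulation would corrupt downstream consensus.
* The micro-assembler's exact 20-base window match loses all reads with an
  error in their anchor prefix (≈ 18% at 1% error); recall could be
  improved with mismatch-tolerant anchoring at the cost of placement risk.
* Identification truth requires the CRB; with real (incomplete) data the
  model's "false" category is unobservable — that is the model's point.
* `run_irb_size_experiment` is exact Monte Carlo, not a closed form; means
  at small `N_s` have visible replicate noise (SDs are reported).
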