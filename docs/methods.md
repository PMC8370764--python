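# Methods

`tcroverlap` quantifies how strongly the clonal composition of two T-cell
receptor β (TCRβ) repertoires overlaps, in the setting where the two
repertoires are the germinal-center follicular helper T cells (GC-Tfh) of
the left and right popliteal lymph nodes of one mouse after the same
antigen was injected into both hind footpads. This note documents the
statistical procedures, the defaults and their rationale, the generative
model behind the synthetic data, and what the synthetic results do and do
not establish about real data.

## Clonotype model and filtering

A *clonotype* is a unique TCRβ rearrangement. The default identity key is
the CDR3 nucleotide sequence together with the V and J segment calls
(`nt_vj`); amino-acid-level (`aa_vj`) and nucleotide-only (`nt_only`) keys
are available. Nucleotide-level identity with segment context is the
stricter choice and matches the convention of the upstream clonotype
callers whose tables this package consumes; the key mode is recorded in
every output. Gene calls are normalized to IMGT segment names on ingest —
allele suffixes (`*01`) are stripped because every analysis here is at
segment resolution.

Records are reduced to clonotypes by summing read counts per key, then two
filters run in a fixed order:

1. **Annotation filter.** Keep in-frame (productive) clonotypes with copy
   number ≥ 2. Out-of-frame rearrangements and singletons are the typical
   products of PCR/sequencing error. A clonotype assembled from records
   with contradictory frame status is a data error and raises, rather than
   being silently resolved.
2. **Above-median abundance filter.** Compute the median of the surviving
   clonotype read counts (midpoint convention for even counts) and keep
   clonotypes *strictly above* it. "Above" is read literally; the boundary
   behavior is pinned by tests (counts {5,4,3,2,2} → 2 survivors; {2,2,2}
   → none; a single clonotype → none). The filter is applied exactly once
   — it is not idempotent. Thresholding read counts or relative abundances
   is equivalent because the per-sample total is constant; counts avoid
   floating-point median artifacts.

Frequencies are renormalized over the survivors of each filter, every
filter appends a provenance entry (`rule, clonotypes before, after`), and
a sample legitimately emptied by filtering propagates as an *empty
repertoire* with a logged warning — not as an error — until a similarity
index is requested of it (see below).

## Overlap statistics

**Morisita–Horn index (MHI).** For relative frequencies p_i, q_i over the
union of clonotypes,

    MHI = 2 Σ p_i q_i / (Σ p_i² + Σ q_i²)  ∈ [0, 1].

It is abundance-weighted: a handful of expanded clones shared at similar
frequencies dominates it, which is exactly the feature of interest for
dominant-clone overlap. MHI of an empty repertoire raises
`UndefinedSimilarityError` rather than returning 0 — a 0 would fabricate
"no overlap" from a filtering artifact. The implementation is a vectorized
outer join; tests require agreement with a naive double-loop evaluation to
1e-12, identity pairs to give exactly 1 and disjoint pairs exactly 0.

**Dot-plot table and regression.** Shared clonotypes with both frequencies
in percent, ordered deterministically; ordinary least squares of one
node's frequencies on the other's, either on the percent scale
(`percent_linear`, the default, matching a 0–10 % dot-plot axis) or on
log10-transformed percentages. The published axis convention for such
plots is ambiguous, so both transforms are provided and the choice is
recorded in the report; neither is asserted as canonical.

**Top-N intersection.** `top_n` takes the N most frequent clonotypes (ties
broken lexicographically, shortfalls logged); `relative_intersection` is
the percentage of them present anywhere in another repertoire. This is
directional and presence-based, deliberately insensitive to frequency
changes — it is the statistic that shows dominant clones *persisting at
reduced frequency*.

**Sharing spectrum.** Per group, each mouse's clonotype set is the union
of its two node repertoires; the spectrum counts clonotypes present in
exactly k of n mice, with member lists and a TRBV breakdown per k, plus a
7-region Venn decomposition for n = 3. Sharing uses presence/absence, not
frequencies.

**Group tests.** Groups of MHI values are compared with the Mann–Whitney U
test (exact when both groups have ≤ 8 observations and no ties — the
typical paired-node design has 3–5 mice per group — normal approximation
with tie correction otherwise) or Kruskal–Wallis for > 2 groups.

## Segment usage

Usage is computed against a strain-specific *gene panel*: SJL mice carry
germline deletions of several TRBV families, and a deleted segment must be
a structural zero, not an unobserved one, and must not dilute the
multiple-testing correction. The shipped panels (SJL, H2s-congenic
C57BL/6) are editable TSV resources; the SJL deletion list follows the
classic Vβ-family deletions mapped to IMGT names and is an illustrative
default, not an authoritative locus annotation.

Default weighting is `read_weighted` (clonotype frequency mass per
segment) because dominance of expanded clones is the phenomenon of
interest; `clonotype_weighted` (unique clonotypes per segment) is provided
since the published figure convention is not stated. Off-panel segments
warn and pool under `off_panel`.

Group comparison is per-segment with a Sidak family-wise correction,
p_adj = 1 − (1 − p)^m, m the number of *testable* segments. Three test
modes:

* `welch` (default): per-segment Welch t tests — the simplest faithful
  stand-in when only the group factor varies;
* `anova`: per-segment contrasts using the pooled residual variance of the
  saturated group × segment cell-means fit — the classic two-way-ANOVA
  multiple-comparison design. With few mice and a heavy-tailed dominant
  block the per-segment variance estimate at the boosted segment is very
  noisy, and pooling across segments is what gives the design its power;
  the enrichment-recovery check therefore uses this mode;
* `mannwhitney`: exact rank tests.

Segments constant and equal in both groups are untestable (p = NaN,
excluded from m). Segments constant within both groups but unequal between
them have no defined parametric statistic; the exact Mann–Whitney p
(complete separation) is substituted.

## The generative model

The synthetic module is first-class, tested code; its defaults *are* the
study conditions and are not tuned per test.

Per antigen-driven mouse: D = 20 **dominant clonotypes** carry total
frequency mass s = 0.6, present in both nodes. Frequencies follow a Zipf
law over dominant ranks (α = 1), with per-side log-normal jitter of
standard deviation (1 − ρ) around the shared latent size; ρ = 0.5 by
default. The **background** is 3 × 10³ clonotypes per node (the order of
the reported unique-clonotype counts), Zipf-distributed with ranks offset
below the dominant block so the dominant clones occupy the top of the
repertoire by construction; a log-normal size law is available. A fraction
(0.1) of background clones is drawn from a finite **public pool** (500
clones) shared across sides, mice and groups, so control overlap is small
but nonzero. Adjuvant-only (PBS-like) mice have s = 0 by construction; the
foreign-carrier (GST-like) group defaults to a smaller, less correlated
dominant block (s = 0.25, ρ = 0.4). Dominant clones of the antigen group
draw their TRBV segment from an enriched distribution (TRBV3 with
probability 0.6 by default).

Calibration of ρ: the abundance-weighted MHI between the two nodes is
governed almost entirely by the dominant-block jitter, not by s — once a
correlated dominant block exists, MHI saturates toward 1 as the jitter
vanishes. ρ = 0.5 places the expected within-mouse MHI of the antigen
defaults near 0.7–0.85, the band reported for antigen-driven paired-node
Tfh repertoires across capture and annotation methods, while leaving
presence/absence sharing of the top 20 near-complete.

**Sequencing** is a single multinomial draw of 10⁶ reads (the order of the
reported totals) over the latent frequencies; clones sampled zero times
are absent. Configurable decoys exercise the filters: out-of-frame clones
(5 % of the universe, CDR3 length not a multiple of 3, expected counts
2–20) and in-frame singletons (5 %, expected count 1). CDR3s are random
in-frame codon strings of 11–17 amino acids (33–51 nt); the exact length
distribution is immaterial to every statistic in scope.

**Temporal decay** multiplies the dominant-block mass by d (default 0.3)
at a later timepoint; the freed mass is split equally between D newly
drawn *late* dominants, private per side, and the background. Early
dominants are never deleted — they persist at reduced frequency. This
reproduces the directional asymmetry: the early top-20 is still found in
the late repertoire, the late top-20 is largely absent early.

**Determinism.** Every sample's RNG stream derives from the master seed
and the (group, mouse, side, timepoint) coordinates via `SeedSequence`;
identical configs give byte-identical AIRR tables, and adding samples
never perturbs existing ones. The public pool derives from the master seed
alone (it models the strain's naive repertoire, shared across groups),
while per-mouse streams mix in a group code so different groups draw
disjoint private clones.

## Problem sizes used in tests and the acceptance script

Unit tests run scaled-down generator configs (≈ 250 background clones,
3 × 10⁴ reads) since they check structure, not power. The acceptance-level
checks run the study-scale defaults: 50 replicates per dominant-mass
setting for the monotonicity check (with common random numbers across
settings), 10 mice per arm for the antigen/control separation, 200
replicates for dominant-sharing recovery, 100 for the temporal asymmetry,
and 20 runs of a 3 + 3-mouse design for TRBV3 recovery. The acceptance
script reports means over 10 synthetic mice per arm (3 per group for the
sharing and usage analyses, mirroring the 3-littermate design).

## Known limitations

* Cross-mouse sharing is driven solely by the group-independent public
  pool; dominant clones are private per mouse. The model therefore does
  **not** reproduce an antigen-vs-control contrast in the sharing
  spectrum (real antigen-specific responses share convergent clonotypes
  across littermates). The sharing statistics themselves are validated
  against brute force, but their group contrast on synthetic data is
  uninformative.
* The read-weighted usage comparison flags not only the boosted TRBV3 but
  also compensatory decreases in other segments — a real consequence of
  compositional data, worth remembering when interpreting such tables.
* Multinomial sampling has no sequencing error model, no PCR amplification
  bias and no UMI structure; the filters' error-removal behavior is
  exercised by stylized decoys only.
* Passing synthetic checks shows the statistics recover known structure at
  realistic scale; it does not validate upstream clonotype calling, nor
  the biological model of clonal selection itself.

## Degenerate inputs and numerical choices

Empty record collections aggregate to empty repertoires; filters pass them
through with logged provenance. Similarity of an empty repertoire raises;
regression needs ≥ 2 shared clonotypes; group tests need ≥ 2 groups with
≥ 2 values. All orderings (overlap tables, top-N ties) are deterministic
with lexicographic tie-breaks. Frequencies sum to 1 within 1e-9 after
every renormalization; MHI agreement with brute force is required to
1e-12; output files are written with fixed float formatting so identical
runs are byte-identical.
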