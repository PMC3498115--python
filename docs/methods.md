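# Methods

This note documents the models and procedures the package implements, the
defaults that matter, what the synthetic generator does and does not emulate,
and the design choices made where the design was genuinely open.

## The domain model

The p25alpha domain is represented as ordered segments with fixed geometry:
an optional ~50 aa N-terminal tail, a 119 aa core, a 31 aa partial core
(carrying exactly one `GXGXGXXGR` Rossmann-like motif, placed so the motif
*ends* the block), and a 14 aa extension that follows the motif immediately.
Core + partial core = 150 aa, inside the 140–160 aa band of complete long
domains. Each segment is a per-position log-odds profile,

    score(pos, a) = log((count(pos, a) + c) / (n + 20c)) − log(1/20),

with uniform background 1/20 and pseudocount c = 0.1 by default. The packaged
default model is built from single-sequence "alignments" of a **designed
synthetic consensus** (`data/synthetic_domain.json`), constructed once at
design time and frozen:

- the core is hydrophobic-enriched and R-free (so it cannot contain the
  motif) with windowed fold index > 0 everywhere — predicted ordered;
- the N-tail, partial core and extension are E/K/S/G/D/Q-enriched with fold
  index < 0 — predicted disordered;
- two fixed core variants exist for the generator: `short_core` (20%
  divergence; the short type is a distinct outparalog, not a noisy long
  core) and `truncated_core` (5% divergence; truncated TPPPs derive from the
  long type, so their long-core affinity stays high);
- five foreign-domain marker blocks (DCX, EFh, IQ, Kelch, Znf_BBOX) with
  distinct compositions stand in for real Pfam domains.

This consensus is not copied from any database sequence; it exists so every
stated length and composition constraint is testable without downloads.

## Scanning

Scanning is gapless: the segment profile is slid across the sequence and
scored at every offset; the normalized score is the raw score divided by the
maximum attainable column sum, so a perfect consensus match scores 1.0. Hits
at or above a floor (default 0.5) are reported with overlaps resolved in
favour of the higher score, leftmost on ties — a deterministic rule. Tiers
strong ≥ 0.80 and weak ≥ 0.55 stand in for the BLAST E-value strata the
original search protocol used (1e−10 strict; up to 1 investigated; 1e−2 for
multidomain searches); E-values are aligner-specific and not portable, so
the tiers are config-exposed normalized-score cutoffs instead.

Multidomain proteins carry domain *fragments* of ~70–140 aa whose N-terminal
part is always present. `scan_fragments` therefore scores every prefix of
the core+partial profile in that length range at every offset and keeps, per
locus, the longest prefix among the best-scoring ones. On noise-free
sequences this re-measures the planted fragment length exactly, except that
flanking residues that coincidentally match the consensus continuation can
be absorbed (the longest-on-ties rule is taking a genuine match); re-measured
lengths are capped at the 140 aa bound.

An indel inside a scanned segment breaks a gapless window badly; affine-gap
scanning is a possible extension, not implemented. The generator accordingly
confines indels to linkers (below).

## Classification

Decision order (first match wins):

1. partial block + DCX annotation → `apicortin` (precedence over the long
   rule; a conflicting core hit is logged);
2. core and partial hits contiguous (|gap| ≤ 10 aa), merged span in
   [140, 160], no foreign domains → `long_type`; the N-tail flag is set when
   ≥ 40 unmatched residues precede the core;
3. exactly one core hit, no partial hit, no foreign domains, and no fragment
   hit elsewhere on the sequence → `short_type`, or `truncated` when the
   normalized core score is ≥ 0.85 **and** the caller-supplied taxon is
   metazoan. The survey separates these two subfamilies by phylogeny, not by
   sequence, so sequence-only input defaults to `short_type` and the
   ambiguity is recorded in the call's notes;
4. fragment(s) of 70–140 aa with foreign domains, or ≥ 2 fragments →
   `multidomain`;
5. partial hits only → `partial_only`, with per-copy Rossmann flags (motif
   inside the hit) and the extension flag;
6. otherwise `none`.

The 0.85 truncated-affinity threshold sits between the fixed divergences of
the two generator variants (5% ≈ 0.94 normalized; 20% ≈ 0.75) with margin
for 5% mutation noise; it was fixed from those stated divergences, not tuned
against test outcomes. Foreign domains always come from annotations
(fixtures or generator markers): re-implementing Pfam/CDD detection is out
of scope, and the printed survey tables provide the annotations.

Known limitation: a single near-complete fragment (≥ ~130 aa) with no
foreign domain is indistinguishable from a long domain by sequence alone;
the generator never emits that architecture (its single-fragment proteins
always carry a foreign domain, matching the printed multidomain lists).

## Pairwise statistics and orthology

Identity/similarity come from a global affine-gap BLOSUM62 alignment
(Biopython `PairwiseAligner`; default gap open 11, extend 1): identity =
identical pairs / alignment columns excluding terminal gaps; similarity
additionally credits substitutions within the conventional strong groups
{ILVM}, {FYW}, {KRH}, {DE}, {ST}, {NQ}, {AG} (the original analysis used a
ClustalW-style notion without specifying groups; these are fixed and
documented here). Reciprocal best hits use the same aligner's score, with
argmax ties broken toward the lexicographically smaller id and logged.

## Phyletics

Species map to (supergroup, megagroup, sub-taxa path) via a packaged table
covering every fixture species; unknown species go to an explicit
"unassigned" row, never dropped. Apusozoa is counted in the unikont
megagroup (its one representative is a proposed opisthokont sister group).
Two printed-table quirks are preserved rather than resolved: the partial-
domain list has 20 rows while the printed summary totals 15 (5) — the five
stramenopile partial rows are absent from the summary's partial column; they
are tabulated here under Chromalveolata and the discrepancy surfaced. And
the truncated list footnotes two accessions as questionable while the
summary's count of 21 keeps the arthropod one and drops only the flatworm;
headline counts here keep all rows (the 21 is the Arthropoda taxon count)
and questionable rows are listed in a footnote section.

## Disorder stand-in

Per residue, over a sliding window (default 21, odd, truncated at termini):
⟨H⟩ = mean Kyte–Doolittle hydropathy rescaled to [0, 1], ⟨R⟩ = mean net
charge (K, R = +1; D, E = −1), fold index f = 2.785·⟨H⟩ − |⟨R⟩| − 1.151,
disorder score = 1/(1 + exp(10·f)) so f = 0 maps to 0.5; a residue is
disordered above 0.5. The logistic steepness 10 only sets contrast sharpness
around the boundary; the sign structure comes from f. This is an explicitly
labelled charge–hydropathy stand-in, **not** a reimplementation of
pairwise-energy or learned predictors; it supports the qualitative contrast
(long-type and partial-domain proteins disordered; short and truncated
ordered) on the composition-coupled synthetic classes, and nothing more. On
natural proteins it is only a rough first pass.

Monotonicity caveat: replacing a residue by a more hydrophobic one is only
guaranteed not to raise the disorder score when the substitution is charge-
neutral; substitutions that change charge can trade hydropathy against
|⟨R⟩| (e.g. D→H). The property test asserts the charge-neutral statement.

## Phylogenetics

Distances are 1 − identity/100 from the global alignment; trees come from
scikit-bio's neighbor joining with negative branch lengths clamped to zero
(warned). Bayesian MCMC inference is deliberately out of scope: the clade
claims under test (truncated TPPPs monophyletic and adjacent to the long
type; long/short separated) are topological separations that NJ on identity
distances can assess deterministically at desk scale. Monophyly of a leaf
set is tested as the existence of an edge that, viewed from a designated
outgroup leaf, separates exactly that set.

## Synthetic generator

The generator emits the six architectures with the stated geometry
(sections above) plus disordered linkers (5–25 aa, from an R-free
charged/polar pool, so no spurious motif can arise). Defaults: partial-copy
count sampled uniformly from 1–4; multidomain proteins have 1–2 fragments of
uniform length 70–140 aa, single-fragment ones always with ≥ 1 non-DCX
marker; apicortins are partial + extension + DCX. Noise: substitutions at
the requested rate everywhere except Rossmann-motif positions; indels only
in linkers/tails. Both protections are *guarantees that the emitted truth
label remains valid*, not realism claims. Default taxa (one species per
class, all in the packaged taxonomy) make the downstream tabulation and the
metazoan test for `truncated` deterministic.

What the generator does not emulate: real domain sequence variation
(profiles are single-sequence), insertions/deletions within domains,
compositional drift, EST truncation artifacts, or real foreign-domain
sequences. A green classification test therefore establishes the internal
consistency of scanner + classifier on the stated geometry — not performance
on natural proteins, which would require curated sequence sets.

## Numerical and policy choices

- Coordinates 0-based half-open everywhere.
- Scan floor default 0.5; tiers 0.80/0.55; truncated affinity 0.85; long
  span gap tolerance ±10 aa; N-tail minimum 40 aa; all exposed in
  `ClassifyConfig`/`RunConfig` and logged by the pipeline.
- Ties: overlapping equal-scoring hits → leftmost; fragment prefixes at
  equal normalized score → longest; RBH argmax ties → lexicographic id.
- Non-standard residues (B, Z, U, J, O, `*`) map to X with a warning; X
  scores as background (log-odds 0) in profiles and as hydropathy 0/charge 0
  in the disorder stand-in.
- Degenerate inputs: empty FASTA → empty report with a warning; sequence
  shorter than a profile → no hits; sequence shorter than the disorder
  window → one whole-sequence window with a warning; empty region for a
  disorder fraction → error.
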