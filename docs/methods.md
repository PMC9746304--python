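# Methods

This note documents the models and procedures behind micromine, the
defaults that matter, and what the synthetic benchmarks do and do not
demonstrate.

## Gene calling and deduplication

The built-in ORF caller scans all six frames for ORFs running from a start
codon (ATG/GTG/TTG) to the next in-frame stop, translating with code 11
and reporting the initiator as Met. The stop codon is required (partial
ORFs at contig edges are skipped) and included in the reported
coordinates, which are 1-based and inclusive on the forward strand —
bit-compatible with the Prodigal `.faa` header dialect used by the import
path. Ambiguous codons (containing N) translate to X; such proteins are
retained and flagged. The caller is deliberately simple — it has no
GC-frame or RBS model — because downstream screening, not gene prediction,
is the subject of this package; for production surveys Prodigal
predictions can be imported directly.

Proteins are deduplicated per sample under `v1_` + the first 24 hex digits
of the SHA-256 of the uppercased sequence. Any stable content hash serves
the purpose (cross-referencing identical proteins across loci); SHA-256
truncated to 96 bits makes collisions implausible at per-sample scale and
is identical across platforms and processes.

## Pairwise search statistics

Local alignment is optimal Smith–Waterman under BLOSUM62 with affine gap
costs (a gap of length *g* costs 11 + *g*; i.e. the BLASTP 11/1
convention), computed by Biopython's C aligner. The traceback is the
aligner's canonical first alignment, which is deterministic across runs;
co-optimal tracebacks can differ from other implementations, so percent
identity on heavily gapped hits is reproducible but convention-dependent.
Percent identity is identities over aligned columns *including* gap
columns, which is the convention the verified/novel distinction needs.
E-values use the Karlin–Altschul form `E = K·m·n·exp(−λS)` with the
standard gapped BLOSUM62/11/1 constants λ = 0.267 nats, K = 0.041; the
database size *n* is the summed length of the training sequences.
Ambiguity codes (X/B/Z) score as the matrix minimum — a conservative
choice that can only suppress, never create, hits.

## Profile HMM

A simplified plan7-style profile without local/glocal mode switching:

- **Match states**: alignment columns with gap fraction < 0.5.
- **Emissions**: residue counts per match column with Laplace (+1)
  pseudocounts, normalized, then converted to log-odds against the
  BLOSUM62 marginal background. Insert states emit at background (zero
  log-odds), so the forward recursion accumulates log-odds directly.
- **Transitions**: counted from the implied M/I/D state paths of the
  alignment rows, Laplace-smoothed and normalized per source state.
  Nonexistent states (D₀, deletes beyond the last match state) get zero
  probability.
- **Score**: forward-algorithm log-odds in bits (log-sum-exp over all
  paths, delete chains solved by a running log-sum along the state axis).
- **E-value**: a Gumbel is fitted by the method of moments to forward
  scores of `calibration_n` (default 200) residue shuffles of the query,
  generated from a fixed seed (default 1234) so results are reproducible;
  the tail probability is scaled by the size of the screened per-sample
  database. The acceptance cutoff is E ≤ 10, a deliberately permissive
  reporting threshold — the pairwise prescreen (E ≤ 10⁻³) does the heavy
  filtering, and the profile stage mainly confirms family-wide support.

This construction is documented as implemented; it is not claimed to be
numerically identical to any external profile-HMM package (effective
sequence weighting and entropy weighting, in particular, are not
implemented). The scorer sits behind a small surface (`build_phmm`,
`phmm_score`) so a full HMMER binding could be substituted. Models
serialize to a versioned text format (`micromine-phmm v1`).

## Reference-MSA projection ("keeplength")

Transporter candidates are aligned globally to the column profile of the
reference MSA (expected BLOSUM62 score of the candidate residue against
each column's residue frequencies; same 11/1 gap costs; numba-compiled
DP). The reference column set is never altered: every candidate residue is
either assigned to a column or marked an insertion, every column either
receives a residue or is a gap. Overlap filtering then computes

- `gap_fraction` = gapped reference columns / reference columns,
- `unaligned_fraction` = insertion residues / candidate length,

and rejects when either exceeds 0.10 (default rule
`either_exceeds_rejects`). The literal conjunctive reading — reject only
when *both* exceed 10% — is preserved as `both_exceed_rejects`, because
the two phrasings of the rule in circulation genuinely disagree; the
disjunctive default is the stricter filter and matches the intent of
retaining only hits that match the rest of the alignment.

The PCAT catalytic triad check maps reference positions 32/105/121
(1-based over the ungapped reference transporter row, initiator Met = 1)
to MSA columns and requires the candidate to carry exactly Cys, His and
Asp there — no conservative substitutions, and a gap fails. If the
reference row itself lacks the expected residues the data are treated as
corrupt and the run errors out, which also guards against off-by-one
numbering conventions.

## Immunity candidates

Neighbor distance is measured in gene ranks, not base pairs, and is
strand-agnostic: the three protein-coding genes on each side of the best
microcin hit per contig are candidates if 30–250 aa long. The
transmembrane annotation is a transparent hydropathy heuristic: mean
Kyte–Doolittle over a 19-residue window, threshold 1.6, overlapping
qualifying windows merged into one helix. It exists to rank candidates for
human inspection and is pluggable; it is never a screening criterion.

## Synthetic benchmarks

`make_family` draws one ancestor per component (lengths: precursor 75–120
aa with an 18-residue leader ending in GG/GA, immunity 51–216, PCAT
600–800 with the triad fixed at 32/105/121, MFP 375–450) and derives
members by per-position substitution at rate 0.15, leaving the initiator,
leader motif and triad invariant. Ten precursors/immunity proteins and
eight PCAT/MFP pairs mirror the sizes of the real verified sets. Because
mutation is substitution-only, the generative alignment is the ungapped
stack of members and is used as the reference MSA.

`plant_genome` back-translates (uniform synonymous codons, code 11) the
operon genes — PCAT, MFP, microcin, adjacent immunity — mutated to an
exact substitution count matching the identity target, embeds them in
i.i.d. uniform background with random decoy genes, and precedes every
planted ORF by in-frame stop codons so the caller recovers exactly the
planted coordinates. Fragmentation introduces random breakpoints; genes
spanning a break are marked non-intact in the manifest.

What this does *not* emulate: real intergenic composition and codon bias,
insertions/deletions within homologs (indel robustness is exercised
separately through the overlap-filter tests), operon rearrangements,
horizontal transfer, and the contamination profile of draft assemblies.
Passing the synthetic benchmarks therefore demonstrates the pipeline's
filter logic, determinism and detection sensitivity over divergence — not
field performance on real genomes, which depends on training-set coverage.

## Statistics

One-way and two-way chi-square tests use no continuity correction (the
published one-way habitat statistic, 241.17 at df 6, is reproduced exactly
under this choice). Pearson residuals are (O − E)/√E, and their squares
sum to the statistic. Enrichment per category is log₁₀ of the category's
positive proportion over the global proportion; zero-positive categories
report −inf and should be treated as missing. Pairwise Fisher tests are
two-sided by summing hypergeometric probabilities not exceeding the
observed table's; the FDR correction is Benjamini–Hochberg (the method
parameter accepts the scipy alternatives). A per-category summary tests
each category against all others pooled, BH-adjusted across categories.

Recomputing the one-way phylogroup test from the bundled totals
(292, 278, 304, 16, 174, 57, 71, 32) gives 702.86 at df 7, whereas the
figure reported alongside those counts in the source survey is 700.2; the
counts and the reported statistic are mutually inconsistent at the third
digit, and this package reports the formula value. The corresponding
two-way habitat statistic cannot be recomputed because per-habitat
positive counts were not published; the habitat dataset therefore ships
totals only.

## Problem sizes

The bundled benchmarks use one operon plus a handful of decoy genes per
~5–10 kb contig, five genomes for self-recovery, five seeded replicates
per identity level on the 100/90/80/60/40% divergence grid, and twenty
operon-free genomes as negative controls. These sizes give stable 0/1
recall outcomes and exact negative controls while keeping a full run in
minutes on one core; they are scaled-down study conditions, not estimates
of survey-scale throughput.

## Known limitations

- The pairwise stage is exact Smith–Waterman with no seeding heuristics;
  throughput is adequate for per-sample screening after the length gates
  but far from DIAMOND/BLAST on survey scale.
- The profile HMM has no local alignment mode, so heavily truncated
  homologs score poorly; the length gates make this mostly moot.
- Immunity-candidate ranks can be shifted by spurious ORF calls between
  the microcin and the true immunity gene; the ±3-gene window absorbs the
  common cases.
- `best_hit_per_contig` undercounts when several distinct microcins share
  a contig — a reporting convention inherited from the surveyed output
  format, not a detection limit.
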