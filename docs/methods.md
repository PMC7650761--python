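# Methods

## Scope and data model

The package operates downstream of read trimming, assembly and homology
search: its inputs are assembled contigs (FASTA), homology hits in the
12-column BLAST tabular dialect, conserved-domain hits, per-library
virus read counts, library metadata and a reference-virus annotation
table (closest relative, host category, genome length, clade, group,
nucleic-acid type). Phylogenetic placement is consumed as that
precomputed closest-relative annotation, not inferred. All in-memory
coordinates are 0-based half-open; the 1-based inclusive convention of
the tabular dialect is converted only at the I/O boundary, and
minus-strand rows (qstart > qend) are normalised to a forward-strand
span with a strand flag.

## Candidate filtering

A contig is retained iff its best e-value against any viral subject is
strictly below 1e-5 and no conserved-domain hit on it is tagged
non-viral. The viral/non-viral tag on domain hits is taken from the
table when present and otherwise falls back to a keyword map over domain
descriptions (overridable), since that curation is inherently manual.
When a contig has both nucleotide- and protein-level hits, both are kept
and the best e-value decides retention; clade and group are inherited
from the best-bitscore annotated hit.

## Genetic codes and ORF structure

Translation tables 1 (standard), 3 (yeast mitochondrial), 4
(mold/protozoan mitochondrial) and 5 (invertebrate mitochondrial) are
packaged as explicit 64-codon maps — 3, 4 and 5 all read UGA as
tryptophan, which some sobemo-like and mitovirus-like genomes require
for an intact replicase. ORFs are reported stop-to-stop with the first
in-frame AUG as start, on both strands by default (assembly orientation
of ssRNA contigs is arbitrary); the span includes the terminal stop
codon, the protein does not. Codons containing N translate to X. The
per-contig code is the one whose single longest ORF covers the largest
fraction of the replicase homology span, ties broken toward the
standard table, so a genome with no internal UGA always reports code 1.

A homology region counts as *interrupted* when no single ORF covers at
least 90% of it (configurable). The break count is the number of ORFs a
greedy tiling needs to reach that coverage, minus one.

## Exclusion rules

Three classes of candidate are flagged out of the final virome:
known cross-contaminants (closest relative named bovine viral diarrhea
virus 1 or human picobirnavirus; list configurable), all hits to DNA
viruses (DNA-virus genes are not reliably separable from host genes at
this stage), and endogenized copies. The endogenization rule is:
interrupted replicase ORF AND NOT (completeness ≥ 0.8 AND high
abundance). The rescue clause reads "complete genome in high abundance"
as a conjunction; the alternative reading (high abundance alone
rescues) is selectable via `TriageThresholds.rescue_on_abundance_only`.
Completeness is contig length over the relative's genome length and the
0.8 threshold is a package choice — "close to complete" is not
otherwise quantified. A list of Mono–Chu relatives that repeatedly
produce endogenized copies in termite assemblies is packaged as a
suspect list that forces the ORF check but never auto-excludes.

## Abundance quantification

Multi-mapped reads are resolved by a small EM in the spirit of RSEM.
The model: a read picks a contig with probability θᵢ/N (θ = expected
counts, N total reads) and a start position uniformly over the
effective length ℓᵢ, so a read class r compatible with a contig set has
likelihood Σ_{i∈r} (θᵢ/N)/ℓᵢ. The E-step therefore splits each class
proportionally to θᵢ/ℓᵢ over its compatible contigs; the M-step sets θ
to the expected counts. Iteration stops when max|Δθ| < tol (default
1e-10). Expected counts always sum to N and the log-likelihood is
non-decreasing (asserted in tests against a brute-force fixed-point
oracle). Effective length is the contig length — no fragment-length
correction, a documented simplification of the full RSEM model.

TPMᵢ = (cᵢ/ℓᵢ)/Σⱼ(cⱼ/ℓⱼ)·10⁶, summing to 10⁶ per library (an all-zero
library reports all-zero TPM rather than erroring). A virus's abundance
is 100·(its read count)/(library total reads); tiers are high > 0.01%,
moderate in (0.001%, 0.01%], low ≤ 0.001% — the boundary values read
strictly, so exactly 0.01% is moderate and exactly 0.001% is low.

## Index-hop filtering

A detection (virus v, library L) is removed iff its count is positive
and below 0.1% of the reference count of v outside L. The reference is
the pooled (summed) count over the other libraries by default; the
single largest count is available as `mode="max"`. The pooled default
is deliberate: the rule's canonical worked example (326 reads against
~180,000 in each of two other libraries) only produces a removal when
the outside counts are pooled (0.1% of 360,000 = 360 > 326), whereas a
literal single-library maximum of ~180,000 gives a 180-read cutoff that
keeps the detection. Removed cells are zeroed and itemized; a virus
seen in a single library is never removed.

## Species, hosts, summaries

Replicase proteins are aligned globally with BLOSUM62 substitution
scores and a linear gap penalty of −4; identity is matches over aligned
columns excluding terminal gaps. Pairs strictly above 95% identity are
edges; species are single-linkage connected components, so identity
exactly 95% keeps two species. At threshold 0 everything is one
species; at 100, all singletons.

Host inference is an ordered rule list evaluated on: clade, group, the
relative's host category, the virus's maximum abundance tier, and the
sampling procedures of the libraries it appears in. Rule order encodes
narrative reasoning that is genuinely case-by-case in the source
material; putting the phage, fungal and dietary rules before the
high-abundance/arthropod rule resolves the overlaps deterministically,
and permuting the input never changes a prediction. The rules are plain
dictionaries (loadable from YAML), so the policy is editable without
touching code. Confidence is ordinal (none < cautious < suggested);
the termite rule starts cautious and is raised when any detection comes
from a head-only library, where gut symbionts are excluded.

Clade summaries average percent-of-total over the clade's *detections*
(virus × library observations), not over viruses — the published
two-library clade means only reproduce under that definition. Mean
abundance is rounded half-away-from-zero to 2 significant figures
(0.135 → 0.14, 0.165 → 0.17) and mean identity to 1 decimal; rounding
uses decimal arithmetic on the printed representation to avoid
binary-float artifacts at the halfway points.

## Ecology

Richness counts viruses with nonzero reads; diversity is Shannon
entropy in natural log units (the index base is not dictated by the
source analysis; Gini–Simpson is provided as an alternative);
dissimilarity is Bray–Curtis. Variance explained by a library factor is
a one-way Gaussian linear model: R² = 1 − SS_res/SS_tot, p from the
likelihood-ratio chi-square against the intercept-only model (ANOVA-of-
GLM style; the classical F-test is an option — the LRT is slightly
liberal at n ≈ 20, which the type-I-error test accounts for). Factor
pairs in which each level of one determines the other (e.g. procedure
vs country when every whole-body library is from one country) are
refused with a diagnostic instead of silently fitted.

## Synthetic data

The generator is the package's study stand-in, at desk scale: 10
libraries with 2·10⁵–10⁶ total reads, 20 exogenous viruses on contigs
of 1–12 kb drawn around reference genome lengths (completeness
0.85–1.0), a 30/40/30 high/moderate/low tier mix, 3 endogenized copies,
2 index hops at fraction 5·10⁻⁴, 15% of genomes requiring UGA=Trp, and
a 40% head-only procedure split with country confounded with procedure
(all whole-body libraries are Australian) — mirroring the survey's
structure while running in seconds. Genomes are random-uniform sequence
with one planted replicase ORF; homology e-values, identities
(20–45%) and bitscores are drawn from ranges rather than computed by
alignment, because triage consumes hit tables, not searches. A single
seeded generator drives everything; identical seeds give byte-identical
bundles.

Planted structure is chosen to be *exactly* recoverable, and this
shapes three choices. Multi-library residents of one virus share a tier
with per-library spread ≤2×, so no genuine detection can fall under the
0.1% pooled cutoff (library totals differ ≤5×, keeping worst-case count
ratios far from 1000×). Index-hop source viruses are planted at 1–3% of
reads so a sub-0.1% hop still rounds to ≥1 read and stays below its
removal cutoff. Endogenized copies are truncated to 40–55% of the
source genome and then degraded with 2–4 single-base indels inside the
replicase span; because a nearby insertion/deletion pair can restore
the reading frame with no stop in the garbled gap, indel placement is
verified (interruption under both stop-codon repertoires, longest
surviving ORF < 0.7 of the span) and deterministically redrawn if the
draw fails. A single frameshift necessarily leaves one flank plus
stop-readthrough intact, so ~0.7 — not 0.5 — is the honest bound on
what one indel can leave behind.

What the generator does **not** emulate: read-level errors and quality,
assembly chimeras and fragmentation, genuine sequence homology between
planted genomes and their references (hit statistics are drawn, not
computed), multi-segment genomes, and any correlation between virome
composition and host phylogeny or procedure. Passing recovery tests
therefore demonstrates that the *rules* are implemented and composed
correctly — not that the rules themselves are robust to noisy homology
evidence, which only the real survey data could show. The survey-scale
headline numbers (67 novel viruses; procedure R² of 0.33–0.61) depend
on those raw libraries and appendix tables and are deliberately not
targets; the corresponding machinery is validated by parameter-recovery
and null-calibration tests instead.

## Numerical choices and degenerate inputs

EM tolerance 1e-10 on max|Δθ| (oracle comparisons at 1e-12); read
classes whose contigs all reach zero abundance split uniformly. An
all-zero count vector yields all-zero TPM, richness 0 and Shannon 0
(flagged, since a one-virus library also has entropy 0). Zero-length
homology spans report coverage 0 under every code and fall back to code
1. Alignment of empty proteins is an error, as is a count matrix with
negative, fractional or missing cells — readers reject rather than
coerce, with file and line in the message. Virus naming draws
pronounceable 3–4-letter prefixes (consonant/vowel alternation) from a
seeded stream onto the "-systermes virus" suffix, regenerating on
collision, with a ~12,000-prefix namespace guarded against exhaustion.

## Problem sizes

The default test and acceptance runs use the 10-library/20-virus bundle
(seconds per run), 40 random EM instances of ≤4 contigs and ≤6 read
classes, 200 replicates for effect recovery and 1000 for the type-I
error of the LRT — sizes chosen so the whole suite stays interactive
while estimates like the null rejection rate carry binomial standard
errors below one percentage point.
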