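# Methods

## The model

The suite treats each genome as evidence about its own proteins. A
*target* family is defined by one profile HMM and a full-sequence
bit-score cutoff; one or more *attribute* families, each with its own
HMM and thresholds, define genome-level criteria. A genome is
**YES-eligible** when every YES group in the rule file has at least one
satisfied presence clause (`HMM>score`: some hit strictly above),
**NO** when every absence clause is satisfied (`HMM<score`: no hit at or
above), and **indeterminate** otherwise. Mirroring the trusted/noise
cutoff convention of curated HMM libraries, the gap between the NO and
YES thresholds is a gray zone, and gray-zone genomes contribute nothing:
a deliberately lossy but low-noise labeling.

With a distance constraint `[d]` on a YES group, only target genes
within *d* base pairs of a qualifying attribute gene go to YES; the
remaining targets of that genome go to FAR — and only if the genome
contributed at least one YES record. A YES-eligible genome whose targets
are all distant contributes nothing, since its labels would be pure
guesswork.

Scanning scores each query window by the minimum binomial upper tail
over prefixes of the ranked hit list (see the README for the formula).
The binomial — sampling *with* replacement at the YES prior
p = Y/(Y+N) — is the model by construction, not an approximation we
failed to improve: ranked homologs are phylogenetically correlated, so
neither binomial nor hypergeometric tails are calibrated p-values, and
scores are meaningful only as comparisons across regions of one query
(or across queries sharing one database and color scale).

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| identity threshold (clustering) | 0.80 | fraction | redundancy above ~80% identity double-counts near-clones as independent observations |
| `min_length` | 6 | residues | shortest window the scan will score; 9+ avoids the least reliable ultra-short searches |
| `length_step` (-j), `position_step` (-w) | 1, 1 | residues | full resolution; `-j 3 -w 3` is ~9× cheaper at some cost in localization |
| `max_hits` | uncapped | hits | prefix depth cap; uncapped because the informative minimum usually sits at the depth of the last consecutive YES hit |
| heritability *h* | 0.93 | fraction | parent-share in rescoring; near 1 means strong smoothing that carries plume signal down to short windows |
| residue window *W* | 30 | residues | each residue is averaged over up to *W* windows of length *W* |

Threshold comparisons are deliberately strict: `>` is strictly greater
(presence), `<` requires *all* hits strictly below (absence), and the
target cutoff uses strictly greater. Users mirroring library TC/NC
values get exactly those semantics.

## Search backends

The builtin backend computes score-only Smith–Waterman (BLOSUM62, gap
open −11 / extend −1) against every database record and ranks by raw
score, ties broken by record id. It makes the whole pipeline executable
and deterministic with no external tools, and serves as the reference
ordering in backend-agreement tests. The external backend shells out to
NCBI `makeblastdb`/`blastp` (E-value ranking, best HSP per subject,
E-value ceiling 10, composition-based statistics off, `blastp-short`
under 30 residues) for full-size runs. Both return at most one entry per
database record, because the unit being sampled by the statistic is a
labeled sequence, not an HSP.

## The rescoring recurrence

The inheritance tool replaces each window's score in a single
longest-to-shortest sweep:

    new(s, L) = (1 − h) · raw(s, L) + h · mean(new(parents))

where the parents of (s, L) are the windows at the next longer length
present in the grid whose spans contain [s, s+L−1] — at full resolution
(s−1, L+1) and (s, L+1); edge windows use their single parent; the
longest length keeps raw scores. The exact blend coefficients were a
genuinely open choice; this form was picked because *h* → 1 then means
"fully inherited", matching the name and the strong smoothing expected
at h = 0.93, and it makes rescored values convex combinations of raw
scores (bounded, monotone — both property-tested). Averaging the two
parents before blending, rather than weighting them individually, is
the simplest symmetric reading.

## The rule-file grammar

The grammar implemented is the minimal one covering the two published
styles of rule file: `KEY: VALUE` lines with `TARGET`, `TARGET SCORE`,
`NO` (AND-ed absence clauses), `YES` (AND-ed groups; commas inside
parentheses OR clauses; an optional `[N]` distance prefix), `#`
comments. Nesting beyond one parenthesis level and mixed AND/OR within
one line are undefined and rejected. Which GFF3 attribute links a CDS to
its protein accession varies by annotation source, so the reader takes
an ordered key list (default `protein_id`, then `ID`).

## What the synthetic generator emulates — and what it does not

`FixtureSpec` defaults define the study conditions used throughout the
tests and the acceptance script: 40 genomes; attribute-positive genomes
a minority (p = 0.3, echoing the premise that the attribute marks a
small fraction of genomes); on average 2.7 target paralogs per
attribute-positive genome and 1.5 per attribute-free genome; a 10%
gray-zone genome rate; 140-residue targets diverged 20–50% from a shared
consensus; a 15-residue signature motif at residues 61–75 carried only
by the one attribute-adjacent target per positive genome, each copy
mutated at 10%; gene layouts placing that target within 100 bp of the
attribute gene and everything else 5 kb apart, against a 500 bp rule.

Two deliberate design features matter for interpretation. First,
per-record divergences follow a golden-ratio ladder rather than iid
draws, so the YES and NO classes have matched distance-to-consensus
profiles; without the matching, whichever class happened to draw the
least-diverged members would top every hit ranking — a lineage-depth
confound unrelated to the planted signal. Second, hit tables are
generated directly from the truth table rather than by running a
profile-HMM search, so the rule engine is tested independently of any
external executable.

What the generator does **not** emulate: real phylogenetic tree
structure (records are star-shaped around one consensus), indels and
domain-architecture variation, genome-scale paralog counts, biased amino
acid composition, or annotation noise in feature files. Passing the
planted-signature tests therefore shows the machinery is correct and
the statistic behaves as designed under controlled enrichment; it does
not show that any particular real family will yield a clean plume.

## Problem sizes and numerical choices

End-to-end runs (tests and the acceptance script) scan window lengths
30 to the 140-residue query in steps of 6 at every start position
(~1,100 windows against ~50 training sequences) and extrapolate residues
at W = 30. Lengths below ~30 are excluded from the *study* scans
because integer-valued alignment scores of very short windows produce
tie-dominated rankings whose label order is essentially arbitrary — the
same reason single-residue extrapolations are labeled approximations.
The scan itself supports `min_length` down to 6.

Other numerics: the binomial tail is computed by `scipy`'s regularized
incomplete beta (verified against exact rational enumeration to 1e−12
for k ≤ 12); ranking ties break by (significance, score, record id) so
serial, parallel and re-run outputs are byte-identical; alignment
identity excludes terminal-gap columns so domain cuts with unequal
flanks still cluster; clustering processes sequences longest-first with
input-order tie-break; an empty hit list scores 0; a flat scan renders
uniform blue rather than erroring (floor defaults to the data minimum);
scan tables round-trip losslessly at 6 decimal places (scores) and 6
significant figures (probabilities).

One property sometimes assumed of prefix statistics does **not** hold
and is not claimed: duplicating every database record leaves p unchanged
but interleaves duplicates in the ranking, which changes prefix tails
(e.g. a single YES at p = 0.5 gives 0.5; duplicated, the depth-2 prefix
gives 0.25). Deduplication is the clustering step's job, which is why it
is "optional but strongly recommended" in the workflow.

## Known limitations

- Scores are comparative, not significance-calibrated; no
  multiple-testing control is attempted.
- The external BLAST backend's E-values on 6–10-residue windows are
  unreliable even with short-query settings; the builtin backend ranks
  such windows deterministically but cannot make them informative.
- Genome retrieval is out of scope: the builder consumes local FASTA,
  GFF3 and HMMER tabular files (or invokes a local `hmmsearch`), never
  the network.
- Single-host parallelism only (`--jobs N` over windows); grid or
  cluster submission is left to wrapper scripts.
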