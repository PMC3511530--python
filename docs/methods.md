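# Methods

## The genome-context model

A TetR-family regulator (TFR) gene is classified by its orientation to its
two immediate chromosomal neighbors, taken in coordinate order:

- **DIVERGENT** — the gene is head-to-head with the adjacent gene: a `+`
  strand gene whose left neighbor is on `-`, or a `-` strand gene whose
  right neighbor is on `+`. The two translational starts face a shared
  intergenic region containing both promoters. Divergence is declared at
  *any* separation; distance enters only at the prediction step. The
  geometry is single-sided, so a gene can have at most one divergent
  neighbor.
- **OPERONIC** — a same-strand immediate neighbor on either side lies
  within `operon_gap_max` (default **35 bp**) measured between ORF
  extremes (stop of one to start of the next, signed; annotated overlaps
  count as within the gap). Co-transcription concerns ORF spacing, which
  is why this gap, unlike the separation, is not measured between
  translational starts.
- **OTHER** — neither relationship.

When both conditions hold (a divergent neighbor one side, a co-transcribed
neighbor the other) the call is DIVERGENT with `mixed_flag` set; this keeps
the three groups a strict partition of the regulator set.

**Separation.** For a divergent pair, `raw_bp` counts the bases strictly
between the first bases of the two start codons:
`start(right) − start(left) − 1` with the left gene on `-` and the right
gene on `+`. Translational starts stand in for transcription starts, which
are unknown for nearly all of these genes. Annotated starts that abut or
overlap give raw values ≤ 0; the reported `clamped_bp` floors at 0 and the
signed value is retained for diagnostics.

**Prediction.** One prediction per divergent call: the neighbor is a
probable direct regulatory target when `clamped_bp ≤ target_distance_max`
(default **200 bp**, inclusive). Inclusive vs strict is configurable
(`threshold_inclusive`); no characterized pair sits exactly at 200 bp, so
the two conventions are indistinguishable on the reference panel, and the
inclusive reading matches how separation ranges are usually binned
("≤200 bp"). Beyond the threshold the pair is kept as a `weak` tier
candidate without a directional claim — long-gap regulators are often
autoregulatory only, and one panel member (AtrA, 425 bp) is an activator.

**Topology.** Streptomycete chromosomes are linear; replicon ends simply
have an absent outward neighbor. Circular replicons are supported: the
neighbor relation wraps, and gaps/separations spanning the origin get a
modular correction (`+ length`).

## Product typing

Target products are sorted into the survey categories — enzymes by
top-level EC class (1 oxidoreductases … 6 ligases), membrane transporters
by family (MFS/ABC/RND/other), other membrane proteins, other proteins,
unknowns — by a priority-ordered rule table. Rules match a conserved-domain
accession exactly, a domain-name substring, or a product-text keyword; the
lowest priority number wins, and duplicate priorities are rejected so the
outcome never depends on file order. The packaged table places transporter
rules ahead of enzyme rules: ABC pumps carry nucleotide-binding domains
that look enzymatic but are counted as membrane transporters. EC classes
come from explicit "EC n" tokens, from mapped superfamilies (Rossmann-fold
`cl09931` and acyl-CoA-dehydrogenase `cl09933` → EC 1), or from standard
activity keywords; no four-digit EC inference and no sequence-based domain
detection is attempted — hit tables are consumed as given. Membrane
proteins without transporter motifs require an explicit transmembrane
keyword; the tool does not predict TM segments.

## Operator scanning

TFR dimers bind palindromic operators: a left arm, an unconstrained loop,
and a right arm equal to the reverse complement of the left up to a few
mismatches. The scanner enumerates every center — an arm boundary plus a
loop of 0..`max_loop` bases — and extends the arms outward one pair at a
time while cumulative mismatches stay within `max_mismatch`. `N` never
pairs. A candidate is emitted only when maximal: any site whose span is
covered by another candidate with at least the same arm length and at most
the same mismatches is suppressed. This collapses both nested shorter arms
at one center and equal-span re-renderings of one palindrome under a wider
loop (a 15-mer with arm 7 / loop 1 also parses as arm 6 / loop 3; only the
longest-armed rendering is reported). Within one center the surviving
sites form the Pareto frontier over (arm length, mismatches), so a clean
short site is not hidden by a longer but dirtier extension.

Default parameters `min_arm 5, max_loop 6, max_mismatch 2` recover an
inverted repeat in every one of the fourteen packaged footprinted operator
sequences (arms 5–9, loops 0–4, 0–2 mismatches); those sequences ship as
regression fixtures. Mismatch counting is arm-pairwise only; loop content
is unconstrained, as observed loops vary freely.

Consensus handling: `build_consensus` emits the base on unanimity and `N`
otherwise (the convention behind `TGGAACGNCGTTCCA`); an optional
strict-IUPAC mode emits the minimal degenerate code covering the observed
bases. `match_consensus` is case-insensitive IUPAC matching, optionally on
both strands; `U` is rejected. Operator placement within an intergenic
region is reported as the site midpoint divided by the region length,
measured from the regulator's start toward the target's, zoned by thirds
(regulator-proximal / central / target-proximal) with configurable cuts.

## Synthetic genomes

The generator lays out one gene cassette per regulator along a replicon,
separated by 100–300 bp so no unplanned divergent or operonic relationship
involves a regulator. Group counts follow the requested mix by
largest-remainder apportionment; cassettes are randomly mirrored so both
strands are exercised. Defaults emulate the survey conditions: mix
0.67/0.15/0.18, separations uniform on 0–1123 bp (the observed range),
operon gaps uniform on 0–35 bp, background i.i.d. sequence at GC 0.72
(streptomycete-like), linear topology, gene lengths 300–900 bp, start
codons rendered `ATG` (codon realism is out of scope). A chromosome plus a
small plasmid can be emitted behind a flag.

Planted operators are perfect palindromes written into divergent
intergenic regions at recorded offsets, with the immediately flanking
bases set to a non-pairing combination — at GC 0.72 a random flanking pair
complements ~30% of the time, which would silently lengthen the planted
arm and make exact-arm recovery impossible to guarantee. Incidental
background palindromes are permitted; recovery is scored only at planted
offsets (exact offset and exact arm).

What passing synthetic tests shows: the classifier, separation arithmetic,
and scanner are exact on annotations whose geometry is known. What it does
not show: robustness to real-annotation pathology (mis-called starts,
nested or duplicated features, RNA genes between neighbors) or anything
about the biological truth of the 200 bp rule itself — that evidence is
the characterized panel, where the rule separates the five repressing
regulators from the four non-repressing ones exactly.

## Numerical and interface conventions

- Coordinates are 1-based inclusive in memory (GenBank/GFF3 native); BED
  output converts to 0-based half-open at write time. Compound (joined)
  CDS locations collapse to their extremes; only CDS features are genes by
  default, with a flag admitting all feature kinds.
- Gene order within a replicon is by start coordinate with locus-tag
  tie-break; neighbor search skips exact-coordinate duplicates of the
  query gene. All traversals are deterministic.
- Features lacking a locus tag are skipped with a counted warning;
  malformed files raise naming the file; GFF3 seqids missing from a
  supplied FASTA raise listing the offenders.
- Input files are recorded by sha256 checksum, since public annotation
  releases differ and no specific release is assumed.
- Survey reports bin separations as [0,100], (100,200], … (width
  configurable) so the ≤200 bp count is the first two bins; regional
  regulator densities report both the raw value and a rounded
  per-megabase display figure. A consistency pass (partition, histogram
  and sub-count reconciliation) runs before any report is written.

## Problem sizes

The test suite and the acceptance script run on synthetic replicons of
20–40 regulators (tens of kilobases), 20 generator seeds for recovery
statistics, and 500 random 60-mers for scanner/oracle agreement — sizes at
which the brute-force oracles are exact and fast while still exercising
every code path; the pipeline itself handles full-genome annotations
(thousands of genes) without special handling.

## Known limitations

- No promoter or transcription-start prediction; separations are
  translational-start proxies by design.
- Predictions are regulatory-relationship calls, not mechanism calls:
  activation vs repression is not claimed, and known long-gap repressors
  (e.g. 280–900 bp cases in other genera) are deliberately non-predictions
  under the default rule.
- Direct (non-inverted) repeat detection and "extended operator"
  semantics are out of scope; so are PWM/information-content motif
  discovery and binding-affinity modelling.
- Product typing is only as good as the supplied product text and hit
  tables; a genome annotated with bare "hypothetical protein" strings
  types everything unknown.
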