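# Methods

## Coordinates and sequence model

All intervals are 0-based and half-open on the + strand of the source
sequence. Positions inside a protospacer are PAM-relative negative
integers: −1 is the base immediately 5′-adjacent to the first PAM base, so
in the standard 20-nt protospacer C−18 is protospacer offset 2 and the
mapping offset ↔ offset − 20 is a bijection between {0..19} and
{−20..−1}. The protospacer length defaults to 20 (the SpCas9 standard) and
is configurable in `find_guide_sites`.

IUPAC support is restricted to the codes the decision table and PAM panel
actually use — A, C, G, T, N (any), D (not C), R (A/G), Y (C/T) — and any
other code raises rather than silently matching. An ambiguous N in an
*input* sequence is handled conservatively: it matches pattern-N only,
never a literal or degenerate code, so site calling never relies on an
unknown base.

Guide-site discovery enumerates every motif of every Cas variant at every
offset on both strands; overlapping and nested motifs (an NG inside an
NGG) are reported independently per variant, because recommendations are
variant-specific. The minus strand is scanned by running the same forward
algorithm on the reverse complement and mapping coordinates back, which
makes the strand-symmetry property (scanning the reverse complement yields
the mirrored site set) hold by construction; the test suite nevertheless
checks it, and full equivalence, against an independently written
every-offset oracle.

## Editor profiles

Each editor profile carries: deaminase family (APOBEC1, CDA1, A3A),
compatible Cas9 PAM specificities, a closed PAM-relative activity window,
an ordered list of preferred positions (most-preferred first), an optional
trinucleotide context preference (TCR for eA3A), and a provenance flag.
Three provenance tiers keep the knowledge base honest:

* `paper-stated` — the window or preference is quantified in the study's
  text (e.g. full-length CDA1 editing C−14..C−20; A3A-BE3 editing
  non-selectively across nine nucleotides; the A3A truncations preferring
  C−16 ≥ C−15).
* `figure-informed-default` — read off figure-level evidence and chosen
  here as a defensible default (most truncation windows). Override these
  freely via a user catalog (`load_catalog`); the built-in file
  `src/beprecision/data/catalog.yaml` is plain YAML.
* `external-citation` — editors recommendable by name only (YEE-BE3,
  BE-PAPAPAP) carry no window and cannot be bystander-assessed; asking for
  a report raises a capability error.

Two window defaults deserve explanation. nCDA1Δ198-BE3, the mildest CDA1
truncation, is set to −20..−14: the decision table recommends it in every
distance bucket from <−19 through −15, and its "no bystander" eligibility
must therefore be revoked by a bystander C anywhere in that distal-to-mid
range (this is also what makes the YCC−15 gap case come back with no
editor). A3A-NL-BE3 (the linker-free A3A fusion) is set to −20..−11,
slightly broader and more PAM-distal than A3A-BE3's nine-nucleotide
window, which is why it is the A3A-family option for very distal targets.

`truncation_removed_residues` performs the construct-name arithmetic: a
ΔK construct retains residues 1..K, so the removed count is the full
deaminase length minus K, with CDA1 = 208 aa and A3A = 199 aa.

## The editor-selection decision table

The table has 19 cells, each keyed by a distance bucket (<−19, −19 … −14,
>−14) and a bystander context — either the sentinel "no-bystander" or an
anchored IUPAC motif whose target-C offset is stored explicitly (a
plain-text table cannot carry an underline, so the anchorings are encoded
in the config and are overridable). Evaluation follows how a practitioner
reads such a table:

1. **Bystander presence.** Motif cells are consulted only if some
   non-target C lies within the union of the cataloged activity windows
   (−20..−11). Degenerate codes admit a bystander but do not require one
   (NCN matches any −18 context), so without this gate the motif cells
   would swallow the bystander-free cases; conversely a C at, say, −2 is
   unreachable by every editor and correctly falls to the "no bystander"
   cell.
2. **Motif cells fire first.** All matching motif cells of the bucket are
   collected, ordered by specificity (count of non-N positions,
   descending) and then table order, and their editor lists concatenated
   with deduplication. Order within a cell is preserved from the source
   and is not a ranking.
3. **"No bystander" cells fire only when no motif cell did**, and then
   per editor: an editor stays eligible only if no C other than the target
   lies inside *that editor's own* window. This per-editor reading follows
   the table's footnote; a global reading would be either vacuous or
   impossible to satisfy.
4. An empty match yields `precise=False` with a warning — the YCC−15
   context (Y = C/T at −17, bystander C at −16, target at −15) is the
   documented gap for which no available editor discriminates.

`recommend` is deterministic for a fixed guide, target and catalog, and
appends a reduced-activity warning when a recommended editor carries a
context preference (eA3A's TCR) that the local sequence does not satisfy.

## Pathogenic-variant scanning

A variant record holds ≥25-nt flanks around a focal base whose disease
allele carries a C on at least one strand (T>C on the given strand, A>G
meaning the C is on the complement). The scanner builds the disease
sequence, finds all guide sites of all cataloged Cas variants on both
strands, and keeps every placement where the focal base reads as C on the
protospacer strand inside the union of editor windows. Each candidate gets
a recommendation and a bystander-risk figure (the minimum count of
high-tier bystanders over the profiled recommended editors — the
practitioner picks the least risky editor). Candidates are ranked:

1. precise recommendation before imprecise;
2. position priority −18 > −17 > −19 > −16 > −15 (the stated CDA1-era
   triple, extended by the A3A positions in the editors' own preference
   order C−16 before C−15; positions outside the list rank after it);
3. fewest high-tier bystanders; then |position| (PAM-proximal first), +
   strand before −, and PAM coordinate for determinism.

Precise-first ordering is deliberate: relaxed NG PAMs also match the GG
inside every NGG site one base downstream, producing a shifted candidate
whose position may outrank the natural one; preferring precise
recommendations keeps the scanner's verdicts aligned with how the editors
are actually chosen, and the priority list then decides among precise
options. A consequence worth knowing: for a TCAC target C at −15 of an
AGG PAM the scanner may report the equivalent −16 reading under SpCas9-NG
— same physical cytidine, same recommended A3A truncation editors.

Verdicts: `precisely-correctable` (best candidate precise with zero
high-tier bystanders), `bystander-prone` (placements exist but none
clean), `not-targetable` (no placement). Records with short flanks or no
C on either strand are skipped with a per-record warning, never an abort.
Scanning is strand-consistent: the reverse-complement representation of a
variant yields the same verdict, position and editors.

## Amplicon quantification

Reads (single-end or pre-merged) are anchored by *exact* matches to the
two `flank_length`-nt (default 10) reference flanks of the protospacer,
checked in both orientations; the intervening segment must have exactly
the protospacer length. Discards are tallied by reason (short / indel /
no_anchor) and conservation (usable + discarded = total) holds for every
run. The denominator of every percentage is the usable (anchored,
indel-free) read count — raw totals are reported alongside so both
conventions are visible. No base-quality filtering is applied: anchoring
two exact 10-mers already bounds the error rate of accepted reads, and
simulated qualities are constant. There is no mismatch-tolerant alignment;
reads whose flanks carry a sequencing error are dropped (a ~0.1%·2·10
effect at Illumina-like error rates), which leaves conversion estimates
unbiased.

Conversion at each reference C is 100 × (usable reads with T) / usable
reads; C→A and C→G are tallied separately as "other". With zero usable
reads the table is defined with zero counts and no division. The window
summary reports the closed interval of positions at or above a threshold
(default 10%), the predominant (argmax) position — ties break toward the
position closest to −18, the headline position of the CDA1 precision
series, then toward the more PAM-distal — and the predominance ratio
top/second (an infinite sentinel when the runner-up is zero). The window
is monotone in the threshold by construction.

The canavanine mutation frequency is the ratio of selective to
non-selective colony counts; a zero denominator is an error and a ratio
above one elicits a warning but is returned (plating noise can produce
it).

## Off-target tallies

A call is an SNV iff REF and ALT are both single bases; length-changing
allele pairs are indels; equal-length multi-base pairs (MNVs) are counted
in a separate "other" bucket outside the spectrum, and symbolic or
malformed alleles are skipped with a tally. Multi-allelic records are
split per alternate. The spectrum collapses to the six strand-symmetric
classes standard in mutation-spectrum work (C>T/G>A etc., pyrimidine
first); complementing every SNV leaves it invariant, and a 12-class
uncollapsed mode is available. `compare_summaries` lays summaries side by
side with pairwise count differences; no significance testing is provided
— the appropriate test depends on the experimental design and is left to
the user.

## Synthetic data

The read simulator emulates the measurement model behind per-position
conversion percentages: each read spans the full amplicon; each listed
reference C converts with its per-read probability (independent mode,
the default, matching the per-position readout) or, in linked mode, a
read is edited as a whole with probability q and converts each listed C
with rate/q capped at one, emulating processive co-editing — real
editors co-edit within the window, but the correlation structure is not
quantifiable from printed per-position data, so linked-mode parameters
are user-set and off by default. Uniform substitution errors are applied
per base; with probability `indel_rate` a read receives a 1-nt insertion
or deletion at a uniform position inside the protospacer (editing-induced
indels arise at the target site, and this guarantees the truth label
"indel" coincides with what anchoring should discard). Qualities are
constant (Q40) since the quantifier ignores them. The simulator does not
model platform-specific error profiles, quality decay along the read, PCR
duplicates or chimeras — so passing recovery tests demonstrates
correctness of the estimator under its own measurement model, not
robustness to real-world artefacts.

The variant-table generator builds targetable records constructively: a
protospacer with the focal C at a chosen priority position, a controlled
context ("clean" single-C; "tcac" = the TCAC motif at −15; "ycc15" = the
deliberately ambiguous gap context, labelled as such), an NGA PAM (chosen
over NGG to avoid the internal NG re-reading), a C directly after the PAM
to block GAA/GAT re-readings, and a G-free "PAM zone" downstream of the
focal base so no competing placement exists; a bounded verification loop
re-draws the rare pathological construct. Non-targetable records scrub
every G from the window-reachable PAM zone, which provably excludes all
five PAM specificities. Half of all records are emitted in the
complementary-strand (A>G) representation. The call-set generator emits
exactly the requested class composition (shuffled), so the tally round
trip is exact by design.

All generators take an integer seed and are byte-reproducible; truth
tables are pandas DataFrames written as TSV by the CLI.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 300-nt random sequences ×
100 seeds for oracle equivalence; a 43-nt amplicon with read depths of
1,000 and 10,000 across conversion rates {0.05, 0.2, 0.5, 0.9} × 100
replicates (800 runs) for quantifier recovery, judged at three binomial
standard errors (computed from the usable-read count) plus a 0.001
absolute allowance for the sequencing-error floor; 200 synthetic variants
for scanner/truth agreement. These sizes give sub-minute runs while
keeping the binomial bands tight enough to detect estimator bias well
below one percentage point.

Degenerate inputs are defined rather than special-cased: an empty call
set tallies to zeros with zero frequencies; an all-zero editing table has
an empty window and no predominant position; a variant with no qualifying
PAM is a verdict, not an error.

## Known limitations

* Editing *magnitudes* are not modelled — only windows, preferences and
  contexts; the recommender cannot trade efficiency against precision.
* Window extents beyond the positions probed by polyC assays are
  figure-informed defaults, flagged as such in the catalog.
* Guide specificity (off-target MIT/CFD-style scoring) and genome-scale
  indexing are out of scope; inputs are amplicon/locus scale.
* The quantifier requires exact flank matches — it is not an aligner and
  does not handle paired-end merging or demultiplexing.
* Variant calling, read mapping and statistical testing of tally
  differences are out of scope; the tally module consumes existing calls.
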