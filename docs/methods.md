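# Methods

This note documents the models implemented in `intronkit`, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic data does and does not show.

## Spliced protein-to-genome alignment (`annotate`)

**Model.** A local alignment of a reference protein against genomic DNA
in codon units. The dynamic program has states
*(protein index i, genomic index j, mode)* with modes

* **match** — residue *i* aligned to the codon ending at *j*;
* **genomic gap** — a codon of the genome aligned to no residue (it
  remains coding in the resulting gene model);
* **protein gap** — a residue aligned to no codons;
* **intron at phase 0/1/2** — entered only at a `GT` dinucleotide,
  left only after an `AG`, with the *p* nucleotides preceding the donor
  completing a codon with the 3−*p* nucleotides following the acceptor.

Alignments start and end on a matched codon (gaps and introns at the
ends can only lower the score, as in any local alignment). The score is
substitution-matrix units: BLOSUM62 by default, affine gaps, a flat
intron penalty independent of intron length within the configured
bounds. A best score ≤ 0 is reported as an explicit empty result.

**Why a flat intron penalty.** Intron lengths vary over three orders of
magnitude within one gene; length-proportional costs would make long
introns unfindable. The bounds do the length work:
`min_intron_len = 40` nt (shorter spliceosomal introns are vanishingly
rare), `max_intron_len = 25 000` nt (chosen to cover loci where a
downstream interaction-motif exon sits >20 kb from the upstream exon).

**Gap charging.** Protein-side gaps cost `gap_open` (11) plus
`gap_extend` (1) per additional residue — the usual protein convention.
Genomic-side gaps are charged per *nucleotide* beyond the first codon
(3·`gap_extend` per additional codon). This keeps the model
self-consistent: skipping a 60-nt intron as a genomic gap costs
11 + 57 = 68, safely above the intron penalty of 40, so real introns are
modeled as introns; conversely a 2-codon genomic insertion costs 14,
well below 40, so small indels are not forced into spurious introns.
With per-codon extension the ordering would invert for introns under
~90 nt.

**Tie-breaking.** The traceback prefers a contiguous codon over an
intron at equal score (fewer introns) and the leftmost eligible donor
among equal-scoring intron placements; endpoint ties resolve to the
smallest (protein, genomic) coordinates. With `strand=None` both
strands are aligned and ties go to `+`.

**Exactness.** The DP is optimal over its model by construction and is
cross-checked against an independent brute-force enumeration of every
ungapped local placement with ≤ 1 intron on small instances
(`tests/oracles.py`); on those instances gap moves are strictly
dominated, so the enumeration is exhaustive over the whole model.

**Simplifications.**

* An intron always adjoins a matched (possibly split) codon; a gap
  cannot directly follow an intron. Splice-adjacent indels between two
  homologues are rare, and no tested scenario requires them.
* Only one intron per codon.
* Only literal `GT`/`AG` signals; non-canonical `GC..AG` introns are
  out of scope.
* No heuristic seeding or banding: run time is O(protein × genomic)
  with a modest constant, intended for desk-scale loci (single contigs
  up to tens of kb), not whole genomes.

A practical consequence of the similarity-evidence model: a terminal
exon is included only if its alignment score exceeds the intron
penalty, i.e. roughly ≥ 10 well-matched residues at the defaults.
Shorter terminal exons (a 5-codon final exon, say) are silently merged
into the flanking region — exactly the situation in which a human
annotator would also have no evidence to call the boundary.

## Translation conventions (`seqio`)

Standard genetic code; codons containing `N` translate to `X` (WGS
contigs contain gaps; failing would be worse than flagging). Stop
handling is explicit: `truncate` cuts at the first stop, `retain` keeps
`*`, `readthrough` converts internal stops to `X` and continues — the
mode used to examine conservation beyond an annotated stop codon.
Coordinates are 0-based half-open everywhere; GFF3 export converts to
1-based closed and fills the CDS phase column from cumulative coding
length. Minus-strand models keep exons on the forward strand in
ascending order; transcription order is derived, never stored twice.
Ambiguity codes beyond `N` are rejected rather than guessed.

## Pairwise and multiple alignment (`align`)

Global and local pairwise alignment delegate to
`Bio.Align.PairwiseAligner` (BLOSUM62, open 11, extend 1; a gap of
length L costs 11 + (L−1)); the first-reported optimum makes tracebacks
deterministic. Percent identity uses the gap-excluded denominator
(columns where both rows bear residues) — printed identity values are
algorithm- and parameter-dependent, which is why family comparisons
should quote the scoring model as done here.

The progressive MSA builds a UPGMA guide tree from cosine distances
between 3-mer count vectors (average linkage, ties by input order) and
merges profiles bottom-up with an affine profile–profile aligner whose
column score is the mean substitution score over non-gap residue pairs.
No iterative refinement: determinism and transparency are worth more
here than the last few percent of alignment quality, and on families at
≤ 20% divergence the truth-column recovery is ≥ 90% (tested). Row order
is restored to input order and all-gap columns are dropped.

`local_search` ranks a user-provided sequence collection by local
alignment score — a deliberately network-free stand-in for a translated
database search; it reports raw scores, not E-values.

## Intron-position conservation (`intron_map`)

A mark anchors an intron to the residue of its interrupted codon
(phase 1/2) or the following residue (phase 0); `phase = coding
nucleotides before the intron mod 3`. Marks are mapped to alignment
columns through each row's residue→column map.

Two marks are "the same position" only when column *and* phase agree
(`phase_strict=True` default): introns of different phase cannot
descend from one ancestral intron, whatever the alignment says. The
flag exists because published comparisons do not always state whether
phase was enforced.

`neighbor_column_tolerance` merges equal-phase classes within *tol*
columns by transitive closure — a robustness knob for alignment jitter
near gaps. Default 0; the pipeline reports tol 0 and tol 1 side by
side rather than hiding the choice.

## Motifs, charge, isoelectric point (`motifs`)

The strict tetra-peptide pattern is Φ–W–Φ–P with
Φ = {A,V,L,I,M,F,W,Y,C}; the relaxed preset widens position 1 to
Φ ∪ {T,S} and position 2 to {W,M,F}, accommodating the observed family
variants (TWVP, LWVP, TMVP, TFVP) while keeping VWWP a strict match.
"Hydrophobic" has no universal definition, so both presets are explicit
configuration, and every window's match count against the supplied
pattern is reported.

Net charge is the Henderson–Hasselbalch sum over D, E, C, Y, H, K, R
side chains and the termini; it is strictly decreasing in pH, so the pI
is the unique root, found by bisection on [0, 14] to 1e−8 pH units
(|charge| at the root < 1e−4 by construction). pKa sets: EMBOSS
(default) and Bjellqvist; a protein's pI shifts by a few tenths of a
unit between sets, which is why reported pI values carry a ±0.2 band.

Basic stretches (NLS candidates) are maximal merges of sliding windows
(default 7 residues) holding ≥ 4 K/R — there is no published rule here,
so the heuristic is small, visible and configurable.

## Synthetic families (`synthetic_data`)

The generator emulates the comparative setting the toolkit is built
for: an ancestral multi-domain protein — default layout PET (110 aa),
linker (20), LIM (60), linker (15), LIM (60); 265 residues — diverged
along a star tree, reverse-translated and interrupted by introns.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| taxa | 3, star tree | the family comparisons are three-way; arbitrary trees are expressible but untested |
| substitutions | 0.05 /site /branch | ≈ ≤10% pairwise divergence, the regime where exact boundary recovery is expected |
| substitution model | replacement ∝ exp(0.5·BLOSUM62) | keeps homology detectable; crude but sufficient for alignment truth |
| indels | 0.004 events/site, geometric mean 2 aa | sparse, as in closely related families; never at motifs or splice-adjacent codons, so truth stays well defined |
| introns | 5–7, lengths 60–500 nt, AT 0.6 | compact invertebrate-like introns |
| intron placement | interrupted codons ≥ 10 residues apart, ≥ 14 from termini | no micro-exons; terminal exons carry enough alignment evidence to pay the intron penalty (see annotate) |
| acceptor context | no `AG` within 10 nt upstream of the true acceptor | keeps re-entry unambiguous for small-instance oracle comparisons |
| codons | uniform synonymous choice | codon bias is irrelevant to every tested property |
| trailer | 300 nt at AT 0.7, plus 120-nt flanks | the AT-rich untranslated-trailer signal the scanner targets |

Every emitted taxon carries its truth: gene model (validated by
translation round-trip), intron marks, motif positions and the
residue-homology column map (insertions get their own columns).
`corrupt_model` produces negative controls (boundary shift ±3 nt,
intron drop / exon merge with frame-preserving trim) for recovery
metrics; `boundary_recovery` scores exact splice-boundary
precision/recall/F1.

**What passing tests show — and don't.** Recovery at 100% on these
families demonstrates correctness of the algorithmic chain under its
own model: uniform substitution rates, clean GT..AG splice signals, no
sequencing error, no paralogy, no alternative splicing, star topology.
Real loci add splice-site context, rate heterogeneity, assembly gaps
and isoform ambiguity (intron sets depend on the chosen splice
variant — pin isoforms when comparing real genes); expect recovery
below the synthetic ceiling there.

## Pipeline and determinism

`run_pipeline` annotates every genomic target with the best-scoring
reference, characterizes the predicted proteins, aligns the family,
classifies intron conservation (tol 0 and 1) and writes
GFF3/FASTA/TSV plus one `summary.json` with every parameter echoed.
There are no timestamps and no unseeded randomness anywhere, so re-runs
are byte-identical — the property the original manual analyses lacked.
Any stage failure halts with the stage name and input id.

## Problem sizes

Test and acceptance runs use 265-residue proteins on ~2.5–3 kb contigs;
the oracle sweeps use 7–10-residue peptides on ≤ 120-nt genomic
fragments (100 instances) and ≤ 7-residue peptide pairs for the global
aligner (60 pairs); recovery statistics use 20 seeded families. These
sizes make every claimed quantity recomputable in well under a minute
each while exercising all states of the aligner.

## Known limitations

* No splice-site scoring beyond the GT/AG literal rule; no GC..AG.
* No E-values for local search; scores only.
* The MSA is progressive without refinement; deep or gappy families
  deserve a dedicated aligner, then feed the result into
  `intron_map` directly.
* No statistical test of intron-position sharing against a null of
  independent gain — the counts are descriptive, as in the analyses
  they reproduce; a Poisson-style null would be a natural extension.
* The DP stores full score matrices (three doubles per cell); a 600-aa
  protein against 25 kb uses ~360 MB. Fine at desk scale, wasteful
  beyond it.
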