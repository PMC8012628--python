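# Methods

This note documents the models and conventions behind each stage, the
defaults that matter, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Repeat detection and architecture

MYB repeats are found with a gap-free position-specific scoring matrix
(PSSM) rather than a profile HMM. Column frequencies are estimated from a
seed alignment of repeat instances as `(count + c) / (occupancy + 20c)`
with pseudocount `c = 0.5` (gaps excluded; all-gap columns dropped), and a
window of length `L` scores `sum log2(f_i(aa_i) / b(aa_i))` bits against a
uniform background. The discriminating signal for family membership is the
presence and spacing of ~50-aa repeats, not fine alignment, so insert and
delete states buy nothing here while the gap-free scorer is exactly
checkable against a brute-force window enumeration (and is, in the tests).

- `threshold_bits = 15`: genuine repeats in the synthetic families score
  ~150–200 bits while random 50-mers score far below zero, so the
  threshold sits in a wide empty margin; it is configurable for real,
  more divergent families.
- Overlapping candidate windows are resolved greedily by descending score,
  ties to the leftmost start — deterministic and oracle-checkable.
- Architecture = longest chain of hits whose consecutive gaps are
  ≤ `tandem_gap_max = 30` residues (R2–R3 linkers are short): 1 → R3,
  2 → R2R3, 3 → 3R, ≥4 → 4R. Records with more than four chained hits or
  hits outside the N-terminal half are flagged for manual review instead
  of being silently reclassified (fused gene models and MYB-related genes
  are a curation problem, not a scoring one).
- Unknown residues (X, and read-through stops rendered as `*`) contribute
  0 bits — they are uninformative rather than penalised.

## Functional calling and frame repair

Gene models are non-functional when a defect lies inside the repeat
domain. Frame-0 translation under the standard nuclear code finds
premature termination codons; a reference pairwise nucleotide alignment,
when available, reveals frameshifts as gap runs whose length is not a
multiple of 3. An `N` inside a codon that decides the stop verdict yields
an explicit `ambiguous` status (functional = None) rather than a guess.

A frameshift garbles the downstream native translation, which would hide
genuine repeats from the scanner. `repair_frame` therefore rebuilds a
frame-coherent CDS from the reference alignment — deletions are filled
from the reference, insertions dropped, substitutions kept — and the
architecture scan runs on the repaired conceptual translation. This
mirrors codon-alignment-guided curation of defective gene models:
architecture reflects the underlying gene; the defect list explains why
the product is non-functional.

Coordinates are 0-based half-open internally and 1-based in all reports
(codon index for stops, alignment column for frameshifts).

## Conservation and window discovery

Per-column identity is the frequency of the modal symbol. The tier
convention follows the standard alignment-colouring scheme exactly:
identity 1.0 → `full`, 0.30 ≤ identity < 1.0 → `mid`, < 0.30 → `low`.
Consensus ties break alphabetically. Information content is
`log2(K) − H` with gaps always excluded (K = 20 for protein, 4 for
nucleotide columns).

Gap handling for identity is configurable because the right choice is
context-dependent: for consensus/logo purposes gaps are ignored (a column
seen in two sequences is scored over those two); for window discovery the
default counts gaps as a symbol, since losing a motif entirely is signal.
The cost of that default is visible in the worked example: the ragged
gap-padded alignment tail shows up as a "conserved" window and must be —
and is — rejected by the order/composition evidence downstream.

"More conserved than average" is operationalised as: baseline = mean
identity over the C-terminal region (by default every column after the
last repeat hit); all windows of 15–17 columns whose mean identity exceeds
baseline + `margin` (default 0.10) are kept and overlapping keepers merge
into maximal runs labelled W1, W2, … left to right. The margin default
reflects that the criterion is qualitative in origin; it is exposed in the
config and the brute-force window oracle in the tests pins the semantics.

The dendrogram uses p-distances (mismatches over columns where neither row
is gapped) and classical Saitou–Nei neighbour joining: minimise
`Q(i,j) = (n−2)d(i,j) − r_i − r_j`, ties to the lowest index pair,
negative branch lengths clamped to zero with a warning. NJ is exact on
additive matrices, which the acceptance run verifies to 1e-9 on random
5–8-taxon trees. Likelihood phylogenetics (codon models, bootstrap) is
deliberately out of scope.

## Disorder stand-in and MoRF evidence

The per-residue disorder score is a windowed average (window 21, odd,
edges truncated) of the TOP-IDP propensity scale, min–max rescaled to
[0, 1] over the scale's range so that 0.5 is the order/disorder boundary:
poly-(P/E/S/Q/K) stretches score above 0.5 and poly-(I/L/V/F/W) below.
This is a composition-based stand-in, not a re-implementation of any
trained predictor; the analysis only needs a *relative-order contrast*
with the conventional 0.5 cut, and `scale_id` records provenance in every
profile. Absolute values are not comparable to machine-learned predictors
and no binding-probability curve is produced.

A conserved window is called a MoRF candidate when all three hold:

1. **conserved** — its mean identity is ≥ 0.5 (windows arrive from the
   discovery step already above the regional baseline);
2. **ordered dip** — `mean(flank) − mean(span) ≥ 0.05` (flank = 25
   residues each side, truncated at termini, ≥5 required on one side) in
   at least half of the activator records. Rows more than 50% gapped in
   the window abstain from voting;
3. **enriched** — the pooled activator span composition is enriched in
   hydrophobic ∪ acidic residues (defaults {A,C,F,I,L,M,V,W,Y} ∪ {D,E};
   the sets are conventions and exposed in config) at α = 0.05 by a
   one-sided binomial tail against the pooled non-span background of the
   same records. With at most a handful of windows per family no
   multiplicity correction is applied by default; a Bonferroni switch
   exists.

`near_cterm` is informational: set when the span ends within 30 aa of the
C-terminus in at least one record. Activators are records with colour
score > 1 (scores 0–8 are assay inputs, never computed from sequence).
Divergence from the activator consensus (column-wise modal residue among
activators, ties alphabetical) is reported per non-activator as 1-based
mismatch positions, gaps counting as mismatches.

## Pattern engine

PROSITE notation is parsed into element lists (residue class × bounded
repeat) with optional `<`/`>` anchors and a terminal alternative
`((A) | (B))`; a branch of `(*)` carries a C-terminal anchor, which is how
"occurs at the N- or C-terminal end" motifs are modelled — as branch
anchors, not global flags. Matching enumerates distinct (start, end)
spans by dynamic programming over reachable positions; overlapping spans
are all reported but multiple internal repeat decompositions of one span
collapse to a single match, because motif biology reasons about sites,
not parses. Input is case-insensitive; ambiguity codes U/B/Z/J/O are
rejected explicitly. The matcher is verified against an independent
regex-based oracle over a dense short-peptide sweep and random 30-mers.

## Engineering

Chimeras are defined on a shared codon alignment so donor and acceptor
coordinates cannot drift: codon columns in span ± flank come from the
donor (donor gaps delete), all others from the acceptor, with per-column
provenance recorded and the design rejected if the swap introduces an
internal stop. Flanks are measured in alignment columns for the same
reason. Substitutions between aligned variants are named `XnY` with n in
the ungapped reference; indels are listed separately, and applying the
substitution list to the reference reconstructs the variant exactly.

Domestication removes BsaI `GGTCTC` (and its reverse complement
`GAGACC`) by recoding one codon per occurrence: among synonymous codons
that destroy the occurrence without raising the total site count, the one
changing the most bases inside the site footprint wins, ties broken by a
packaged codon-usage ranking then lexicographically (the synonymous-choice
rule is this package's own; usage values only order ties). Iteration runs
to a fixed point; a site covered only by Met/Trp codons fails loudly with
its position. Translation invariance is asserted on every call. For BsaI
specifically an unfixable occurrence cannot arise (the site contains C/T,
absent from ATG/TGG), but the failure path matters for other site tables.

## Synthetic families

Each record is leader (8 aa) + two ~50-aa repeats from a fixed
tryptophan-anchored consensus (2% per-site substitution) joined by a 6-aa
linker + a disordered C-terminus: 10-aa entry linker, then three planted
motifs (15/16/17 aa, drawn from hydrophobic+acidic composition) each
preceded by a 30-aa disordered spacer, then a variable tail, total
C-terminus 148–200 aa. The disordered background alphabet {P,E,S,Q,K,G,R,D}
and the motif alphabet {I,L,V,F,W,A,M}+{D,E} are chosen so the propensity
stand-in separates regions by construction. Motifs substitute at 5% per
position in activators and 50% in non-activators; activator colour scores
are uniform on {2..8}, non-activators on {0,1}. The default family has 12
activators and 4 non-activators; loss-of-function injection (TAA
substitution, or ±1–2-base frameshift) is off by default and exercised by
the architecture panel, which cycles {none, R3, R2R3, 3R} with seeded
in-domain defects. CDS are sampled reverse-translations (codon-usage
weighted) with a terminal stop; the alignment shipped is the generative
truth, with gaps only in the ragged tail, and loss-of-function records are
excluded from it (their translations no longer fit the family rows).

What this does **not** emulate: tree-structured evolution (substitutions
are iid, so there is no phylogenetic correlation between records), indels
inside the homologous region, alignment error (the truth alignment stands
in for an aligner), compositional drift between families, or any coupling
between sequence and phenotype scores. Passing the planted-recovery tests
therefore shows the pipeline is correct and well-calibrated *under its own
stated assumptions* — conserved, relatively ordered, compositionally
distinct motifs inside a disordered tail — not that it would achieve the
same sensitivity on real families with alignment noise and phylogenetic
structure.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; reruns with the same config are byte-identical
and the pipeline summary embeds the config hash and seed. The benchmark
sizes used by the tests and the acceptance script — 100 simulated
families for motif recovery, a 100-record architecture panel, 100 random
additive trees, 100 domesticated CDS, a dense pattern sweep (all peptides
to length 5–6 over a 5-letter alphabet) plus ~400–1000 random 30-mers —
were chosen to estimate each rate with enough resolution to see a single
failure while keeping the whole suite under a minute.

## Known limitations

- The PSSM has no insert/delete states; strongly indel-divergent repeats
  would need the manual-review pathway (the iterative search rescue used
  for divergent R3 MYBs in genome-scale curation is not automated here).
- The disorder stand-in is composition-blind to context (no interaction
  energies, no learned features); only relative contrasts are meaningful.
- Window discovery assumes the motif region is alignable; it inherits any
  alignment error untouched.
- The NJ tree is a similarity dendrogram, not an inference of evolutionary
  history.
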