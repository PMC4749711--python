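# Methods

`spacertyper` analyses the intergenic spacer (ITS) between the 16S and
23S rRNA genes of bacterial rRNA operons, the marker of choice when 16S
sequences are too conserved to separate closely related strains (the
motivating system is sphingomonads from drinking-water surveys). This
note records the models, the tunable parameters and their defaults, the
numerical choices, and what the synthetic panels do and do not show.

## Spacer excision

The spacer is excised by in-silico PCR. Degenerate primers (IUPAC
codes) are matched ungapped against the template; a position matches
when the expansion sets of the two symbols intersect, and a site is
accepted with at most `max_mismatch` mismatches (default 2, a typical
tolerance for Sanger-era primers). Reverse primers are matched as
reverse complements. Product lengths are bounded by `[200, 2000]` bp,
bracketing the 415–849 bp spacers this marker produces. The ITS proper
is the sub-sequence *strictly between* the two primer footprints: the
forward primer sits in the conserved 16S 3' end and the reverse primer
in the 23S 5' start, so the excised spacer is directly comparable
across strains. The packaged primer table carries both assay sets
(a sphingomonad-specific 16S assay and two ITS primer pairs); either
ITS pair can be selected per run.

Templates are assumed to be oriented 16S→23S; a `both_strands` flag
relaxes this for unoriented input.

## tRNA gene detection

Spacer tRNA genes are found with a rule-based cloverleaf scanner rather
than a covariance model. Every window of 70–95 nt is tested against an
exhaustive enumeration of arm-size assignments:

| element | size |
|---|---|
| acceptor stem | 6–7 bp |
| D stem / D loop | 3–4 bp / 4–12 nt |
| anticodon stem / loop | exactly 5 bp / exactly 7 nt |
| variable loop | 3–12 nt |
| T stem / T loop | exactly 5 bp / 6–9 nt, loop must contain `TTC` |

Each stem base pair scores GC 3, AT 2, GT 1; a `TTC` T-loop adds a +2
bonus. A window is a hit when ≥80 % of stem positions pair, the score
reaches `min_score`, and at most one hard constraint is violated. A
candidate that passes the score threshold while violating exactly one
hard constraint (broken anticodon stem — fewer than 4 of 5 pairs
intact — wrong anticodon loop size, or missing T-loop motif) is
reported as a **pseudo-tRNA**; this is an operational definition chosen
because the source survey names pseudo genes without defining them.
Overlapping candidates are resolved greedily by score (ties leftmost).
The anticodon is read at cloverleaf positions 34–36; `TGC` → Ala,
`GAT` → Ile, anything else → "other" (labelled by the standard genetic
code in reports).

`min_score = 50` was calibrated once against the generator: the null
distribution of best window scores on random 800-nt sequences tops out
near 44, while planted canonical genes score 65 and pseudo genes 56,
so shuffled spacers scan clean (the required ≥90 % shuffle-rejection
holds with margin) and every planted gene passes. The scanner is *not*
equivalent to covariance-model search on real genomic edge cases
(unusual D-loops, introns); it recovers position, isotype and length on
canonical bacterial genes, which is all the typing needs.

## ITS typing and partitioning

Spacers are typed by their 5'→3' tRNA content: `ITS_none`, `ITS_Ala`,
`ITS_AlaIle`, `ITS_IleAla`, `ITS_IlePseudo` — the five arrangements
seen in sphingomonads — with `ITS_other` for anything else (reported,
never coerced). Two gene-like features (pseudo genes count, since they
divide the spacer the same way) split the spacer into ITS-1 / ITS-2 /
ITS-3; a single gene yields `spacer-a`/`spacer-b`, which are excluded
from ITS-2 statistics because ITS-2 is defined only between two genes.
ITS-2 lengths are binned into the survey's size groups: 16–19, 60–61,
122–138 nt, otherwise `other(n)`.

## Alignment and conservation

A global affine-gap aligner (match +1, mismatch −1, gap open −5, gap
extend −1; a run of k gaps costs `open + k·extend`) is extended to
profile–profile alignment for the progressive stage; the guide tree is
UPGMA on a 3-mer distance. This emulates a production MSA tool *in
role only* — column-for-column agreement with external aligners is a
non-goal — but optimality is tested against exhaustive enumeration on
small inputs, and gap-stripping every row reproduces its input exactly.

Percent identity between two rows is `100 × matches / columns where at
least one row is non-gap`, i.e. indels count as differences; the
alternative denominator (both rows non-gap) is available because the
survey does not define its "percent sequence conservation" precisely.
Conservation summaries report mean/SD (n−1) over upper-triangle
pairwise identities. Conserved blocks are maximal runs of gap-free
columns whose majority residue reaches a threshold (ties become IUPAC
union symbols); indel events are maximal gap runs of a focus row versus
the rest; group-level length stretches are column runs present in one
group and gapped in another.

## Phylogeny

Figure-style tree inference: complete deletion (only columns where
every row is an unambiguous A/C/G/T survive) → JC69 distances
(`d = −¾ ln(1 − 4p/3)`, entries with p ≥ ¾ flagged saturated and capped
at 5.0 substitutions/site) → Saitou–Nei neighbor joining (negative
branch lengths clamped to zero, deficit moved to the sibling;
deterministic index-order tie-breaking) → maximum-likelihood branch
lengths on the NJ topology by coordinate ascent, each branch optimised
exactly against fresh Felsenstein partials (per-column likelihood is
`α + β·e^(−4t/3)` given the inside/outside partials, optimised by
bounded scalar search; the total log-likelihood never decreases).
The bootstrap resamples alignment columns with replacement under a
single integer seed; each replicate runs distances → NJ → branch ML
(2 ascent sweeps — supports depend only on topology, so deeper
optimisation inside replicates buys nothing); majority-rule (>50 %)
consensus supports are bipartition frequencies in percent.

Deliberate deviation: the original analysis seeded its ML search with
NJ on *Maximum Composite Likelihood* distances (a MEGA-specific
choice). Here NJ runs on JC distances — the same model family as the
likelihood stage — which keeps the pipeline self-consistent. No
topology search (NNI) is performed by default: the tree is the NJ
topology with ML branch lengths.

## ITS-2 hairpin folding

A Nussinov-style DP over nested pairs with integer weights (GC −3,
AT −2, GT wobble −1), a −1 bonus per stacked pair, and a minimum loop
of 3 nt (steric floor). The resulting *stability* is explicitly
unitless and only ordering-comparable — the unnamed folding tool behind
the original figures printed kcal/mol values that are out of scope
here. Structures with a longest helix ≥8 bp are `long_stem`; 3–7 bp are
`short_hairpin` and flagged as putative RNase III processing targets;
anything else is `unstructured`. Traceback is deterministic (prefer
pairing, leftmost partner, stacked continuation). Note that with
wobble pairs enabled the fold score is *not* exactly invariant under
reverse complement (G:T complements to A:C, which cannot pair); the
exact symmetry holds in the Watson–Crick-only mode (`allow_wobble=False`).

## Synthetic panels

The generator emulates the survey's statistical structure with full
ground truth. Defaults are the study conditions:

- 14 reference clade templates + 23 isolate descendants (37 operons);
- ITS lengths drawn inside 415–849 bp (templates use a 15 bp interior
  margin so isolate indels cannot leave the envelope);
- G+C tuned per-operon to a target inside 42.2–57.9 mol% (1.3 mol%
  interior margin) by composing filler with an exact G/C count;
- arrangement mix dominated by Ala+Ile (0.60), with Ile+Ala, Ile+pseudo,
  Ala-only and tRNA-free spacers at 0.10 each;
- ITS-2 size groups: short 0.20, mid 0.20, long 0.15, other 0.45;
- `CCAACCAT` and `TGGT` planted at the ITS-2 boundaries, and two
  panel-conserved blocks (a 24-nt leader after the 16S terminus and a
  20-nt run before the 23S start) that give the complete-deletion stage
  alignable columns across unrelated clades, as the conserved boxA-like
  elements do in real spacers;
- one canonical Ala (73 nt) and Ile (74 nt) gene per panel, stems drawn
  as perfect GC pairs so the detector scores are deterministic; the
  pseudo relic is an Ala gene with three anticodon-stem substitutions,
  validated against the detector (and redrawn, seed-deterministically,
  when a disrupted window happens to admit an alternative intact
  cloverleaf reading);
- isolates evolve from their template by JC substitutions
  (`isolate_divergence = 0.02`), Poisson(1) indels with geometric
  lengths (cap 10 nt), and a hypervariable ITS-2 core.

ITS-2 divergence is governed by one panel-wide scale,
`its2_divergence`: each size group has an ancestral core, clade
templates diverge from it at that scale, and isolate cores diverge from
their template at a fixed 0.25× ratio — ITS-2 being the fastest-evolving
region is precisely what makes it the discriminating marker. The
default (3.0 substitutions/site, i.e. near-saturated between clades) is
a one-time calibrated constant chosen with `scripts/calibrate.py` so
the default panel's mean pairwise ITS-2 identity reproduces the
survey's 22.5 % headline (measured 22.8 % over seeds 1–5).
Substitutions draw replacement bases from the template's composition
and a small filler-only repair step cancels residual G+C drift, so the
envelope holds even under heavy core divergence.

Planted genes, boundary motifs and primer footprints are protected from
mutation — mirroring the strict length/structure conservation of real
spacer tRNAs — which is why ground-truth recovery of type, gene
positions and size group is exactly 100 % on default panels: the tests
demonstrate the pipeline's bookkeeping, detection and typing, not its
robustness to within-gene sequence divergence.

What the panels do **not** model: rRNA secondary structure in the
flanking scaffolds, recombination, within-gene tRNA divergence,
composition heterogeneity across lineages, and near-identical
within-clade ITS-2 pairs (the calibrated default trades the survey's
96 % maximum pairwise identity for its 22.5 % mean; if you need
near-identical close relatives, lower `its2_divergence` or the 0.25×
within-clade factor and accept a higher panel mean).

## Problem sizes

Default analysis scales, chosen as sensible desk-scale settings: the
simulated survey is 37 operons of ~0.8–1.2 kb; bootstrap consensus
trees use 100 replicates in the shipped tests and acceptance script
(the pipeline default remains 1000, the figure-standard count);
exhaustive oracles run at ≤10 nt (folding) and ≤8 nt (alignment), where
enumeration is exact.

## Known limitations

- The cloverleaf scanner's hard constraints encode canonical bacterial
  geometry; genes with unusual arm sizes would be missed.
- Progressive MSA quality degrades for very low-identity pairs, as for
  any guide-tree aligner; conservation statistics inherit this.
- NJ + ML branch lengths without topology search can keep a suboptimal
  topology when the distance signal is weak.
- The fold model has no thermodynamics: stability orderings are
  meaningful, magnitudes are not.
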