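# Methods

## Domain architectures

A BGC's biosynthetic domain architecture (BDA) is the ordered sequence of its
biosynthetic domain labels. Ordering convention: CDSs sorted by genomic start; within
a CDS, domains follow translation order, i.e. reverse genomic order on the minus
strand. This reflects assembly-line order, which is what architecture comparison is
meant to capture; for `NRPS_PKS` qualifiers the within-protein coordinates give that
order directly, for `sec_met_domain` qualifiers the listing order is used.

Labels are normalized to a canonical vocabulary (whitespace stripped, separators
unified to underscores, case preserved) through an alias table, because the two
antiSMASH qualifier dialects spell the same domain differently (`PP-binding` vs
`PP_bind`, `Condensation_LCL` vs `Cond_LCL`). The alias table covers the domains that
drive modular-BGC comparison (condensation subtypes, carrier proteins, KS subtypes,
AT/KR/DH/ER, TE, NAD-binding); unknown labels pass through unchanged rather than
erroring, so exotic vocabularies degrade gracefully.

Post-processing defaults: clusters on contigs shorter than 10 kb are removed
(strictly `< 10000`); regions are trimmed to the span of domain-bearing CDSs; a
trimmed region overlapping `[0, 20 kb)` or the last 20 kb of its contig is flagged
contig-edge. Coordinates are 0-based half-open internally and converted at the
GenBank boundary. Candidate product labels map NRPS/NRPS-like → NRPS, T1/T2PKS →
modular PKS, T3PKS → type III PKS, terpene → TPS; mixed products resolve by priority
NRPS > modular PKS > type III PKS > TPS, except that an NRPS/PKS hybrid carrying an
iterative-KS domain is forced to modular PKS (iterative PKS machinery dominates such
hybrids). Reference (MIBiG-style) entries are kept only when complete and backed by
at least one piece of experimental evidence; their class labels are non-exclusive,
and a Polyketide entry whose only PKS subclass is "type III" is never modular PKS.

## Co-emission scoring

The scoring matrix entry for two domains is derived from their profile HMMs. Only
match-state emissions are used; insert/delete structure is parsed but ignored — the
comparison is a column-level log-odds co-emission score

    s(c1, c2) = log Σ_a e1(a) · e2(a) / bg(a),

maximized over monotone column alignments by dynamic programming with a per-column
gap cost (default 0) and floored at 0. The background is the average of the two
profiles' backgrounds (uniform 1/20 unless a COMPO line supplies one; COMPO values
are floored at 1e-6 so background odds stay finite). Raw scores are normalized by
the geometric mean of the self-scores (`--norm max` divides by the larger self-score
instead), clipped to [0, 1]; identical profiles score exactly 1 and profiles that
cannot co-emit any sequence score 0. Entries at or below an epsilon (default 0)
become −1 in the matrix. A profile whose self-score is not positive (e.g. uniform
columns) cannot be normalized and is reported by name. A user-supplied matrix TSV
can bypass scoring entirely, which also supports importing scores from external
profile-comparison tools.

## Alignment

BDA pairs are aligned by exact Needleman–Wunsch with linear gap cost 0 (end gaps
free by construction, so leading/trailing shifts are free). Similarity is M/N over
the reported traceback: M = gap-free columns, N = all columns. Degenerate optima are
ubiquitous at gap cost 0, so the traceback tie-break is fixed and documented: prefer
the diagonal when the pair score is positive, else gap the first sequence, else the
second. This maximizes matched columns without admitting −1 columns. Because a gap
column costs 0 and a −1 column strictly lowers the score, no optimal traceback
contains a −1 column — the −1 floor eliminates misalignment entirely in the exact
DP. Heuristic text aligners used for the same task do retain a small misalignment
rate; that behaviour is a property of the heuristic, not of this scoring model, and
is deliberately not reproduced. The misalignment audit (`count_misaligned`) exists
for forced or imported alignments, where the count can be nonzero.

Cluster re-alignment for visualization is progressive: the most similar pair seeds
the profile, then the BDA with the highest similarity to any included member joins
next; profile columns score as the mean pair score over non-gap token pairs. Rows
all have equal length and stripping gaps recovers each input.

Unknown tokens are a strict error by default; an opt-in mode scores them −1 against
everything (including other unknowns), which keeps them gapped rather than matched.

## Clustering and status

Clusters are the connected components of the graph with edges at similarity ≥ 0.8
(single linkage; greedy accretion and connected components coincide, which the tests
verify against an independent union-find). The threshold is inclusive. A candidate
is a *hit* only with a direct ≥-threshold edge to a reference — not by mere cluster
co-membership, because transitive chains through other candidates are weaker
evidence; such candidates stay *clustered* and are flagged `in_reference_cluster`
for transparency. *Orphans* have no qualifying edge at all.

## Transporter context

Only complete (non contig-edge) candidates are analysed; each contributes the
trimmed cluster span plus 20 kb flanks clipped at contig bounds. Genes are assigned
to regions by interval overlap with in-cluster priority for straddlers, and to 1 kb
windows by start coordinate (midpoint/overlap weighting would shift few genes at
typical gene sizes; start-coordinate assignment is the simplest deterministic rule).
Partial terminal windows are kept with width weighting. Per family, windows of one
region are compared with all other windows of the class by a Wilcoxon rank-sum test:
exact enumeration of rank assignments when the pooled sample has ≤ 10 observations,
tie-corrected normal approximation otherwise; all values identical gives p = 1.
Families are flagged enriched at raw p < 0.05 (two-sided, no multiplicity
correction by default; Benjamini–Hochberg is available behind a flag) and exclusive
when all their genes fall in one region. Windows are pooled per-BGC within a class
rather than merged into one genomic union, so overlapping flanks of neighbouring
clusters are counted per cluster.

## Synthetic data

The fixtures emulate every input with known truth. Profile-HMM families descend
from point-mass-column ancestors; members resample each column with the divergence
probability, and families draw from disjoint alphabet subsets so cross-family
co-emission is exactly zero. Grammar BDAs concatenate canonical modules —
condensation–adenylation–carrier for NRPS, the seven-domain iterative
KS–AT–DH–ER–KR–carrier–NAD-binding module for modular PKS — with optional
adenylation–carrier starter and thioesterase terminator. Perturbation substitutes
tokens within their homology group (condensation subtypes, carriers {PCP, ACP,
PP_bind}, KS subtypes), deletes, and inserts at configurable rates. GenBank and
MIBiG-style JSON writers round-trip exactly through the parsers. Transporter
layouts place genes per window with Poisson counts at a default density of
0.3 genes/kb — a deliberately generous transporter density that gives the rank-sum
test non-degenerate window counts at desk scale — and optional per-(family, region)
multipliers for constructing enriched fixtures.

What the fixtures do not emulate: real nucleotide/protein sequence content (CDSs
are placeholder), antiSMASH's full qualifier zoo beyond the two parsed kinds,
correlated gene placement, or the long-tailed domain-count distributions of real
reference databases. Passing tests therefore demonstrate correctness of the
algorithms and the I/O contracts, not recovery rates on real survey data.

## Problem sizes and determinism

The test and acceptance workloads are desk-scale by design: oracle equivalence runs
200 random BDA pairs (length ≤ 6, against exhaustive enumeration of monotone
matchings) and 100 random similarity graphs; family recovery uses 3 grammar
families × 20 members; enrichment calibration uses 8 BGCs × 1000 uniformly placed
families plus 25 replicates of a 5× in-cluster fixture. Every stochastic component
takes an explicit integer seed (numpy `default_rng`); pipeline outputs embed a
config hash and are byte-identical across reruns.

## Known limitations

- The co-emission scorer is a match-column model, not a full pair-HMM forward
  algorithm; scores from external profile-comparison tools can be imported via the
  matrix TSV but will not be numerically identical.
- Alignment is restricted to modular classes (NRPS, modular PKS); non-modular
  classes have architectures dominated by one enzyme and M/N similarity is not
  informative there.
- The normalization choice ("geometric" vs "max") changes off-diagonal matrix
  values; geometric is the default because it is symmetric in the two self-scores
  and reproduces 1 for identical profiles under any column scaling.
- MIBiG parsing targets the 3.x JSON shape (cluster/loci/compounds); other shapes
  need flattening first.
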