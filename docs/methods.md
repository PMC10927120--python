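# Methods

This note documents the models and procedures implemented in `afdomain`, the
assumptions behind them, the parameters that matter, what the synthetic data
generator does and does not emulate, and the choices made where the design
was genuinely open.

## Inputs and conventions

A predicted model is one chain: a one-letter sequence, a Cα trace (Å),
per-residue plDDT in [0, 100] read from the B-factor column (files whose
B-factors exceed 100 are rejected as not following that convention), and an
n×n PAE matrix (Å) from the JSON payload dialect whose entries cap at 31.75.
Residue indices are 1-based inclusive everywhere, written as
`start-end[,start-end...]` range strings; multi-segment ranges represent
discontinuous domains. PAE asymmetry is preserved at read time and
symmetrized — mean of (i,j) and (j,i) — only when features are computed.
Table floats are written at 4 decimals so outputs diff stably.

## Flexibility filter

Residue *i* is non-globular when it has fewer than `flex_min_partners` (5)
residues at sequence separation > `flex_seq_sep` (10) with symmetrized PAE
below `flex_partner_pae` (10 Å). The intuition: a residue inside a folded
domain is in confident mutual position with most of that domain, while a
linker or disordered residue is confident only about its local stretch of
backbone. The three knobs trade linker sensitivity against eroding short
domains; the defaults keep a 50-residue domain fully un-flagged while
catching ≥ 80 % of 15-residue linker residues on synthetic chains.

## Pair probability model

Two residues are scored for domain co-membership from four pairwise
features: Cα distance, symmetrized PAE, and counts of sequence-profile and
structure-alignment hits covering both. Transforms are fixed — distance
capped at 40 Å and scaled to [0,1], PAE capped at 31.75 and scaled, counts
through log1p — and a logistic regression (L2, C = 1, lbfgs) supplies the
weights. The upstream pipeline this emulates fits its pair probabilities by
regression on a curated benchmark of reference domains; here the benchmark
is synthetic: two-domain chains with a 15-residue linker, all three domain
geometries, and hits generated per ground truth. About a third of benchmark
domains deliberately carry **no** hits: real proteomes contain globular
domains with no ascertainable homology, and a benchmark without them lets
the fit treat shared hit membership as a necessary condition, which then
fragments hit-less domains at parse time. With them, the fitted weights are
negative on distance and PAE and positive on shared hits, and held-out
within/between discrimination is essentially perfect (AUROC ≈ 1.0) because
the synthetic PAE separation is wide.

The fitted weights serialize to JSON and travel with the run manifest, so a
parse is reproducible from its manifest alone.

## Segmentation and clustering

Maximal un-flagged runs are cut into `segment_len` = 5 segments; a remainder
of 1–2 residues extends the previous segment (length 6–7) and a remainder of
3–4 stands alone; runs under 3 residues stay unparsed. The 5-residue unit is
the method's granularity for domain assembly; the remainder rule is our
choice, as is the use of disjoint blocks rather than overlapping windows.

Segment affinity is the mean pair probability over cross-segment residue
pairs. Clusters merge greedily under **average linkage** (the unweighted mean
of segment-pair affinities between clusters) while the best linkage is ≥
`pair_prob_cut` = 0.5; σ(0) = 0.5 makes that a natural scale-free default,
and both linkage and cutoff are configurable. Ties break toward the pair
with the lowest minimum segment index, so the procedure is deterministic.
Because the merge order is independent of the cutoff, raising the cutoff
only truncates the same merge sequence earlier — candidate counts are
monotone in the cutoff, which the tests assert.

Candidates shorter than `min_domain_len` = 25 residues (the method's notion
of "too short to stand alone"; the upstream description says only "short")
are processed smallest-first: merged into the sequence-adjacent neighbor
with the higher inter-candidate mean pair probability when that probability
is ≥ 0.3, otherwise dropped, their residues reverting to the flexible set.
Hits attach to a candidate when ≥ 50 % of the hit's query-range residues
fall inside it.

## Region categories

Six labels partition every chain: ASSIGNED, UNASSIGNED, PARTIAL, SIMPLE,
FLEXIBLE, LOW_CONFIDENCE. Candidate precedence is: mean plDDT < `plddt_min`
(70) → LOW_CONFIDENCE; fewer than `sse_min_for_globular` = 3 secondary
structure elements → SIMPLE; otherwise the hit rule. The precedence order is
a design choice — confidence filters dominate homology calls, so a
low-confidence region can never be assigned however good its hits. The
plDDT statistic for demotion is the candidate mean (median or
fraction-below would also be defensible); per-residue labelling outside
candidates uses each residue's own plDDT.

Secondary structure is detected from Cα geometry alone (in the style of
P-SEA): residue *i* is helical when d(i,i+2) ∈ [5.0, 6.0] Å and d(i,i+3) ∈
[4.7, 6.1] Å, strand when d(i,i+2) ∈ [5.9, 7.3] Å and d(i,i+3) ∈
[9.0, 11.5] Å (helix wins on overlap); an element is a run of ≥ 6 helical or
≥ 3 strand residues. Ideal helices (rise 1.5 Å, radius 2.3 Å, 100°/residue)
and ideal strand zigzags fall comfortably inside these windows; a straight
3.8 Å-spaced trace falls outside both.

The assignment score is best-hit confidence × reference coverage — a single
transparent number per candidate standing in for the upstream method's
neural-network assignment, which is out of scope here. Thresholds
`conf_min` = 0.8, `cov_assign` = 0.7, `cov_partial` = 0.5 are package
defaults (the coverage gray zone [0.5, 0.7) is UNASSIGNED). Coverage means
aligned fraction of the reference domain; scoring against alignment length
instead would shift partial/assigned boundaries.

## Population statistics

Only ASSIGNED regions are tallied, per (H-group, stratum), with roll-ups to
architecture and structural class through the catalog metadata. Stratified
normalization reports count·T/(row total · column total), the
observed/expected ratio under independence (0 where a margin is 0).
Enrichment between an observed and a reference set tests each group's 2×2
table with the closed-form Pearson chi-squared, no continuity correction —
matching the spreadsheet function the original analysis used — with p from
the 1-df upper tail and a zero-margin convention of (χ² = 0, p = 1).
Bonferroni divides α = 0.05 by m = number of groups present in the observed
set; counting the union instead is selectable. Reference counts may be raw
or redundancy-reduced representative counts; both modes are supported since
the choice changes totals.

## Representative sets

Greedy longest-first clustering (ties by id): each sequence joins the first
cluster whose founder satisfies the identity and coverage constraints, else
founds a new cluster; best-fit joining is available by flag. The alignment
kernel is local Smith–Waterman (BLOSUM62, gap open 11 / extend 1) via
Biopython's PairwiseAligner; identity = matches over aligned columns,
coverage = aligned span over sequence length. Exact k-mer sharing
(word size) is purely a speed prefilter and never alters identity values.
Level parameters are (0.99, 0.9, 5), (0.70, 0.7, 4), (0.40, 0.7, 2) for
F99/F70/F40 with coverage applied to the shorter sequence, and
identity 0.7 / bidirectional coverage 0.7 / word 4 for the unassigned-domain
reduction — the source procedure for that reduction states the coverage but
not the identity threshold, so 0.7 is our documented default. Output
representatives follow the priority policy (previous > manual > provisional
> x-ray, then resolution, then recency, then id); the unassigned reduction
keeps the longest member. Every emitted cluster is re-audited against its
constraints.

## Annotation comparison

Obsolete protein records map to current ones by exact sequence equality
(which implies equal length); multiple matches map to the lexicographically
smallest id with an ambiguity flag. Domain/annotation overlap is the
fraction of domain residues inside the union of annotation intervals; a
domain counts as "covered by an existing sequence classification" at
fraction ≥ θ = 0.5, a configurable default since the original analysis does
not state its overlap criterion.

## Synthetic data: what it emulates and what it does not

The generator builds chains from blocks — domains (helix bundle, sheet
sandwich, or mixed geometry, built from ideal SSE coordinates), lone
30-residue helices, 15-residue linkers, 20-residue disordered tails
(self-avoiding 3.8 Å random walks with a 3.0 Å clash cutoff). plDDT is
bimodal: N(90, 5) for ordered residues, N(50, 10) for disordered tails.
PAE is block-structured: N(4, 1) within a globular block, N(20, 3) across
blocks, N(28, 2) when either residue is non-globular, clipped to
[0.2, 31.75] — the payload ceiling — with the diagonal at 0.2. Linker
residues take the non-globular PAE distribution: linkers are precisely the
regions the PAE filter must catch, and the block-pair sampling rules would
otherwise leave long linkers looking internally rigid. Hit tables are
generated from the ground truth: assigned domains get one sequence-profile
and one structure-alignment hit (confidence ~ N(0.92, 0.04), coverage ~
N(0.85, 0.05)), partial domains get low-coverage hits (N(0.3, 0.05)),
unassigned domains none, plus uniform-confidence decoys at a configurable
rate (default 0.1 per domain).

The default proteome mix reproduces the residue-category proportions
reported for real whole proteomes — 66 % assigned, 4 % unassigned, 1 %
partial, 4 % simple, 12 % flexible, 12 % low-confidence, renormalized over
the 99 % that received a category. Block categories are drawn with
probability proportional to weight/length so realized residue fractions
converge to the weights; the default proteome is 50 models of 8 blocks each
(~300 residues per chain, ~15 000 residues total — sizes chosen so the full
recovery experiment runs in seconds).

What passing recovery tests shows: the parser, classifier and statistics
correctly invert the generative process at realistic signal levels. What it
does not show: performance on real predictions, whose PAE matrices have
anisotropic inter-domain structure, partial-disorder gradations, domain
interfaces without linkers, and miscalibrated confidence that the
block-structured generator deliberately omits. The generator also makes no
attempt at side chains, multi-chain context, or sequence realism (uniform
amino-acid composition).

## Numerical and degenerate-input conventions

Deterministic tie-breaks everywhere: lowest segment index in clustering,
smallest-first processing in merging, (p, group id) ordering in comparisons,
lexicographic ids in representative selection. All stochastic steps take
explicit seeds, and generation is bitwise reproducible per seed. Degenerate
cases: empty segment lists parse to zero candidates; chi-squared with a zero
margin is (0, 1); an all-zero contingency table, an empty observed
population, and an empty summary input are errors; 0/0 cells normalize to 0.
Generator outputs are rounded (coordinates 3 dp, plDDT / PAE 2 dp) so that
write→read round trips are exact at table precision.

## Known limitations

- The pair model is fitted to the synthetic benchmark; weights are not
  transferable to real predictors without refitting on a real labelled set.
- Average linkage with a greedy merge order can differ from globally optimal
  partitions on adversarial affinity matrices; the brute-force oracle in the
  tests bounds this on small instances only.
- Long proteins split across overlapping prediction windows are not merged;
  such models should be excluded upstream, as the source analysis did.
- The SSE detector is Cα-only and window-based; it under-counts distorted
  or very short elements and is not a substitute for a full-backbone
  assignment.
- Multi-chain complexes and non-standard residues (mapped to X) are out of
  scope.
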