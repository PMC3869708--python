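# Methods

## Data model

An observation campaign on a closed social group is represented as an
`ObservationSet`: a roster of individuals (id, sex, birth date and/or
adult–cub age class, membership window), group-composition scans
(session id, timestamp, present set, absent set), directed interaction
events (timestamp, initiator, recipient, behaviour ∈ {play, greeting,
social_licking}, accepted flag), and a square kinship matrix of
coefficients of relatedness. Scans record the absent set explicitly so
mid-study roster changes are representable; when an input file omits it,
it is inferred as roster-minus-present. The accepted flag is parsed and
preserved but enters no metric by default (a config switch can drop
unaccepted bouts). Individuals missing from the kinship file — e.g. an
introduced unrelated male — default to zero relatedness with a log warning.

**Bout independence.** Two records of the same directed behaviour by the
same dyad count as one bout unless separated by at least 60 s (configurable
gap). De-duplication operates per (initiator, recipient, behaviour) stream,
keeps bout-start events, and is idempotent. The boundary is inclusive: a
61 s gap is two bouts, a 59 s gap is one.

## Matrices

**Association (modified simple ratio index).** For each unordered dyad
{A, B} over all scans: `X` = both present, `Y_A` = A present & B absent,
`Y_B` = converse; index = `X / (X + Y_A + Y_B)` ∈ [0, 1]. The classical
SRI's `Y_AB` term (A and B seen in *different* groups at the same time)
requires simultaneous multi-group observation and is excluded by
construction. A dyad with `X = Y_A = Y_B = 0` carries no information and is
stored as missing (NaN), never as 0; missing cells are pairwise-deleted
from Mantel statistics and treated as absent ties by the graph metrics.

**Interaction.** Entry (i, j) = de-duplicated bouts initiated by i toward
j, one matrix per behaviour; `all_social` is the elementwise sum of raw
bout counts of the three behaviours (summing counts, rather than averaging
per-behaviour normalized matrices, keeps the conservation property
total(all_social) = Σ totals and is the only choice that makes the combined
matrix a count matrix).

**Attributes** (all similarity-oriented, so Mantel signs are comparable):
kinship = the relatedness coefficients; gender similarity = 1 iff same sex;
age similarity = `1 − |Δage| / max|Δage|` on fractional years at the study
midpoint (all-1 when ages are equal; falls back to the adult/cub dichotomy
when birth dates are partial). Half-sibling indicator = relatedness in
[0.25, 0.5) — a band rather than a point so inbred-litter values such as
0.313 are captured; configurable. Full-sibling indicator = relatedness
≥ 0.5 **and** same generation: parent–offspring dyads also share r = 0.5,
so a sibling flag is required, defaulting to "same age class" and
overridable with explicit sibling pairs from pedigree metadata.

## Network metrics

All metrics run on labelled matrices with zero diagonal; node order is
roster order and every tie-break is deterministic.

* **Density** = realized ties / possible ties (`n(n−1)` directed,
  `n(n−1)/2` undirected); 1 ⇔ complete, 0 ⇔ empty.
* **Strong transitivity**: over ordered triples (A, B, C) with
  w(A,B) > 0 and w(B,C) > 0, the percentage whose closing tie A→C
  satisfies the closure rule — `min` (default): w(A,C) ≥ min of the two
  supporting weights; `max`: strictly greater than both; `any`: merely
  present. The rule is exposed because valued-data transitivity has several
  legitimate variants; `min` is the default as the weakest "at least as
  strong" reading, and results record the rule used.
* **Degree**: weighted row sums (initiated) and column sums (received) for
  directed networks. Normalization is `100·raw/((n−1)·max off-diagonal
  weight)` — the percentage of the ceiling attained if the individual
  carried the strongest observed tie to every other member — and is stated
  in each report's metadata, since valued-degree normalizations differ
  across software and are otherwise unreconstructible.
* **Betweenness** `B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st`, Brandes' accumulation
  over BFS shortest-path DAGs on the binarized graph (edge ⇔ weight > 0) by
  default; the path-count definition concerns numbers of shortest paths, so
  binarization is the faithful default for valued matrices, with a
  weighted variant (edge length = 1/weight, Dijkstra) behind a flag.
  Disconnected pairs contribute 0. Normalized: `100·B/((n−1)(n−2))`
  directed, `100·2B/((n−1)(n−2))` undirected.
* **Maximal cliques**: Bron–Kerbosch with pivoting on the binarized,
  symmetrized graph (union of directions by default, intersection
  selectable), size ≥ 3, lexicographic output. A complete graph is reported
  as its single maximal clique — a complete composition network therefore
  yields one n-clique rather than "no cliques"; suppressing it would hide
  information.
* **Random null**: a density-matched binary network placing exactly
  `round(density × possible)` edges uniformly (a G(n, m) draw), so each
  draw realizes the target density exactly up to edge granularity.

## Inference

**Mantel test.** r = Pearson correlation over upper-triangle dyadic cells
(missing cells pairwise-deleted); the null distribution jointly permutes
rows and columns of the second matrix; p carries the add-one correction
`(1 + #{|r*| ≥ |r|}) / (P + 1)`, so min p = 1/(P+1). Two-sided by default
(signs are read off the coefficient). Directed matrices are symmetrized by
i↔j sum before testing (max and min available): the Mantel statistic needs
a dyadic similarity structure, and the sum preserves total interaction
volume per dyad. Default 10,000 permutations. A constant matrix (e.g. a
complete association network with all indices 1, or a density-matched
random null of a complete network, which is necessarily complete and
constant) has no defined correlation; panel cells for such pairs are
reported as NaN rather than suppressed. The permutation loop has a
vectorized batch path when no cells are missing and a per-permutation path
with pairwise deletion otherwise.

**Panel.** All network×network pairs (upper triangle) plus every
attribute×network pair plus one fresh density-matched random draw per
network, with per-test seeds derived from the panel seed and recorded.
Output is a tidy table plus p-value and coefficient pivot blocks.

**Rank correlations.** Spearman (midranks) among in/out-degree vectors
within and across networks; Kendall tau-b between betweenness and degree
vectors; both delegate to scipy with asymptotic p-values. `leave_one_out`
recomputes a correlation without one individual and reports both results,
for single-individual sensitivity checks.

**Keystone ranking.** For each network report, individuals are ranked
(1 = most central, ties share average ranks) on raw betweenness and on
clique-membership count; the composite is the mean over all rank columns,
the minimum is flagged keystone, and exact ties are flagged jointly —
on a fully symmetric network nobody is flagged.

## Synthetic data generator

Each of `n_days × sessions_per_day` sessions draws a group partition: with
probability ρ (`grouping_preference`) the whole group is together;
otherwise two random anchors seed a two-block split and each remaining
member joins the anchor it is more related to, with cohesion weight
`(1 + r)^β`. A two-block split (rather than an arbitrary partition) matches
the qualitative field picture — a mostly-cohesive group with occasional
subgrouping — using one interpretable parameter; an optional per-individual
solitary rate models a male who is periodically apart. One scan is emitted
per settled group. Directed bout counts per co-grouped dyad are Poisson
(overdispersion deliberately omitted from the default noise model) with
rate `base_rate(behaviour) · (1+r_ij)^β · keystone_boost^[keystone∈dyad] ·
cub_play_boost^[play ∧ cub∈dyad]`; bout timestamps within a stream are
spaced ≥ 61 s so de-duplication is the identity on clean output, and
`messy=True` plants sub-minute duplicates to exercise it.

Relatedness comes from an explicit matrix or from a pedigree via the
standard kinship recursion (parental averaging; unknown parents are unique
unrelated founders), reported as r = 2φ without inbreeding normalization —
the field convention for nominal coefficients (0.5 full sib, 0.25 half
sib). The packaged 11×11 relatedness fixture of the reference pride is used
*directly* by `ngamo_like_config` rather than regenerated from a pedigree:
its printed values are nominal field conventions (e.g. 0.313 for cubs
related through a shared sire and half-sib dams, 0.5 for full sisters from
an inbred full-sib mating) that no exact pedigree recursion reproduces
simultaneously, and the published matrix is authoritative for the
individuals it covers. The male MI, absent from that matrix, defaults to
zero relatedness with a log note.

`ngamo_like_config` fixes the reference study conditions: 7 adults + 5
cubs, 450 days × 3 sessions, ρ = 0.8, kin bias β = 1.5, keystone PH with
boost 1.5, cub play boost 6, MI solitary rate 0.15, and per-session base
rates calibrated analytically (expected total = sessions × Σ_dyads
P(co-grouped)·λ, with P(co-grouped) ≈ ρ + (1−ρ)/2) so a full-length
campaign yields ≈ 2.7k play, 4.3k greeting and 2.6k licking bouts and
~1.4–1.9k scans — the scale of a real thrice-daily multi-month campaign.
Rates are anchored to the 450-day reference, so shorter runs yield
proportionally fewer records.

**What the generator does not emulate:** demography (no births, deaths or
roster changes mid-campaign), space (no territories or travel costs),
observation error (every present individual is detected; no misidentified
initiators), diurnal or seasonal rate variation, and behavioural
contingency (bouts are independent given the rates; no reciprocity
dynamics). Passing recovery tests therefore demonstrates that the pipeline
detects the planted structure under idealized sampling, not that real field
data meet these assumptions.

## Recovery experiment design

Two dedicated configurations validate end-to-end recovery at 12
individuals over 200 days:

* **Kin bias** (`kin_bias_experiment_config`): β = 2, no keystone, equal
  base rates 0.008 per behaviour — roughly a dozen bouts per ordered dyad
  over the campaign, enough that the Poisson noise does not drown the
  (1+r)² gradient. The kinship × all-social Mantel test should reject at
  α = 0.05 in ≥ 90% of replicates while an independent random attribute
  matrix stays at the nominal rate.
* **Keystone** (`keystone_experiment_config`): boost 3 on one adult,
  β = 1, base rates 0.0005 — a deliberately sparse regime (roughly half of
  the per-behaviour ties realized). Betweenness and clique counts are
  constant on saturated graphs (a complete network has betweenness 0 for
  everyone), so keystone identifiability requires operating below
  saturation; there the boosted individual's extra ties become bridging
  positions and extra clique memberships.

## Numerical and engineering choices

* Permutation p-values use the add-one correction and a 1e-12 comparison
  tolerance so ties at |r*| = |r| count as exceedances (conservative).
* All randomness flows through `numpy.random.Generator` seeded explicitly;
  panel and pipeline sub-seeds are drawn from the run seed, recorded in
  outputs, and two runs with the same seed produce byte-identical files.
* Undefined quantities raise (density at n < 2, transitivity at n < 3,
  betweenness at n < 3, Mantel on constant matrices, rank correlation on
  constant vectors) rather than returning sentinel numbers; the panel
  converts the constant-matrix case to NaN cells because mixed panels
  legitimately contain complete networks.
* Matrices are small (tens of individuals); all-triple transitivity is
  O(n³) vectorized and exact, and no sparse structures are used.

## Known limitations

* The weighted betweenness variant assumes weight = closeness; other
  length transforms (e.g. 1/log w) are not provided.
* The Mantel test permutes whole individuals; data-stream permutations
  (swapping individuals within scans) and MRQAP/partial Mantel are out of
  scope.
* Attribute matrices are binary or scalar similarities; no interaction
  (e.g. sex × age) attributes.
* The age-similarity encoding (rescaled years) is one of several defensible
  choices; it is flagged in output metadata and configurable upstream by
  supplying a custom attribute matrix.
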