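# Methods

## Data model

A run binds three inputs into one dataset:

* **Alignment** — aligned FASTA over {A,C,G,U,-,N}; `T` is read as `U`,
  lowercase is folded, and under the `lenient` policy IUPAC ambiguity codes
  become `N`.  Gap (`-`) and `N` are missing data throughout: a missing
  leaf cell never produces a change on that terminal branch, and a pair
  with a missing side on a branch is skipped (and logged), not classified.
* **Structure** — a Vienna dot-bracket line or a whitespace pair table
  (`i j conserved`, 1-based).  Pairs carry a conserved flag (the helix 2+3
  regions used by the CBC species criterion; settable per pair or through a
  range file) and a helix id inferred from stacking (bulges of up to 2 nt
  are absorbed).  Nesting is not required of pair-table input; multiple
  bracket tiers admit pseudoknots in dot-bracket input, although ITS2
  itself is knot-free.
* **Tree** — rooted Newick over exactly the alignment's taxa.  A basal
  trifurcation is treated as unrooted and requires an outgroup to place the
  root.  Branch lengths are kept for bookkeeping but all inference is by
  step counting.

All column indices are 0-based in memory and 1-based in every file.

## Ancestral reconstruction

Each column is an unordered 4-state character.  The bottom-up pass uses
Hartigan's majority-vote sets: a state enters a node's set iff it appears
in a maximal number of child sets, and the node contributes
`(#children − max count)` steps.  On binary trees this is exactly Fitch's
intersection/union rule; on multifurcations the plain iterated intersection
is *not* parsimony-exact (three children in states A, B, C would be scored
as one step instead of two), while the majority rule attains the exact
minimum on arbitrary trees — which the test suite verifies against an
exhaustive-enumeration oracle on hundreds of random topologies.

The top-down pass is delayed transformation (DELTRAN): a child keeps its
parent's final state whenever that state is in its first-pass set, pushing
changes tipward; residual ties — the root pick and a forced change — break
alphabetically (A < C < G < U).  The emitted events per column therefore
always number exactly the column's parsimony minimum, and two runs on the
same input are identical.  Published implementations of DELTRAN do not
document their internal tie-breaking, so reconstructions can differ from
other software precisely at ambiguous roots; the alphabetical rule is the
reproducible choice made here.

Missing leaves carry the full alphabet in the bottom-up pass (so they
inherit their parent's state and receive no event); an all-missing column
is flagged and contributes no steps.

## Pair events and homoplasy

A pair state is the ordered residue couple at a base pair in 5'-3' helix
orientation; the six paired states are G-C, C-G, A-U, U-A, G-U, U-G
(orientation matters: G-U ≠ U-G).  On each branch, each pair's parent and
child states are compared once, so two single-column changes at partner
columns yield one CBC event rather than two.  For terminal branches the
child state is the *observed* sequence, so alignment gaps surface as
skipped cells instead of fabricated events.  The classes partition all
changed cells: CBC (both sides change, pairing kept), hCBC (one side,
pairing kept), pair_loss, pair_gain, mismatch_change.

Homoplasy typing works within (pair, event class) strata:

* **REV** — the derived state equals the reconstructed state of some strict
  ancestor above the branch's parent (the full root path, matching the
  "return to a plesiomorphic state" notion, not just the grandparent).
* **PAR** — ≥2 events with the identical (ancestral, derived) couple on
  branches none of which is ancestral to another; groups are formed
  greedily in branch preorder, so one group may span many lineages.
* **CONV** — among events not absorbed into a PAR group, ≥2 independent
  events reaching the same derived state from ≥2 distinct ancestral
  states.

PAR and CONV are exclusive by construction (a change-identical bucket is
PAR; CONV only forms across distinct ancestral states).  REV takes
precedence for the primary label, and a reversal that also sits in a group
keeps its group id.  hCBC-class groups are labeled hPAR/hREV following the
field's notation.

The two-step pathway audit reports, per pair, every ordered
ancestor–descendant couple of hCBC events whose intermediate matches
(first event's derived state = second event's ancestral state) and whose
composition is a legal CBC.  Only four of the 22 directed CBC categories
admit such a decomposition (G-C ↔ A-U via G-U, C-G ↔ U-A via U-G); an
empty audit on a dataset means its CBCs did not arise by consecutive
hemi-changes.

## CBC clades and grades

Cutting the rooted tree at every branch carrying ≥1 conserved-region CBC
(several CBCs on one branch are one cut, with multiplicity recorded)
partitions the leaves into components.  A non-root component is a **clade**
iff its member set equals the complete leaf set of some node's subtree —
set-monophyly, checked directly — and a **grade** otherwise; a clade-kind
component that lost members to nested cuts is flagged *depleted* (this
covers single-leaf remainders).  The component containing the root has, by
construction, no synapomorphic conserved CBC of its own: it is the
**plesiomorphic grade** unless no cut exists at all, in which case the
whole tree is trivially one clade.  Components are never split without a
cut.  A phenetic audit re-checks every component pairwise at the conserved
pairs; nonzero CBC differences inside a component are possible under
homoplasy (e.g. a reversal) and are reported rather than suppressed.

## Summary statistics

Per branch, with steps counted at paired columns only:
`CBC_R = 2·n_CBC / steps` (a full CBC consumes two single-position steps)
and `hCBC_R = n_hCBC / steps`.  Branches without paired steps have
undefined ratios and are excluded from saturation summaries; an event
tally exceeding the step count is an internal-consistency error.
Percentages are reported to one decimal.

The category table enumerates all 36 ordered couples of the six paired
states: 22 CBC, 8 hCBC, 6 identity.  The transition tally counts
reconstructed transitions per directed couple (non-paired states pooled as
"mismatch"); extant pair-state frequencies are computed over taxa ×
universal pairs (both columns gap-free in every taxon), the set published
percentages refer to.

## Numbering, consensus, variability

A column is *universal* iff no taxon has a gap there; universal columns are
numbered 1…U in order.  Insertions are labeled `k_1, k_2, …` against the
nearest preceding universal position; columns 5' of the first universal
position are `1_-k … 1_-1`, with `1_-1` adjacent to position 1 so that
sorting by (anchor, offset) reproduces alignment order.  Position 1 is the
first universal column; datasets numbered against a different anchor differ
by a constant offset.  The majority-rule consensus (default threshold 0.70,
valid range (0.5, 1]) excludes gaps and `N` from the denominator, so a
column present in a subset of taxa still reports that subset's majority.

Variability categories: (1) invariant, (2) one change, (3) 2–5 changes,
(4) ≥6 changes — counted from the parsimony reconstruction; legends
elsewhere sometimes read "> 6", but ≥6 is used so the counts partition.
Category 5 (expansion segment) marks runs of ≥3 non-universal columns or
explicitly supplied regions; category 6 (taxon-specific insertion,
non-universal columns present in <50 % of taxa) overrides it.

## Simulator

The simulator is first-class, tested code: it defines the study conditions
under which the detector's guarantees are demonstrated.

* **Template** — 129 columns, 45 pairs in four helices (9/10/20/6 pairs
  with short loops and spacers), mirroring the canonical ITS2 layout; the
  conserved set is all of helix 2 plus the apical 18 pairs of helix 3.
  Other geometries fall back to a single hairpin.
* **Tree** — user Newick or a unit-rate Yule tree whose pendant edges are
  extended by one further exponential waiting time (so no zero-length
  branches) and rescaled to a configurable root-to-tip depth (default 1).
* **Root sequence** — pair states drawn from a configurable frequency
  vector, default G-C/C-G-dominant (0.35/0.30/0.12/0.10/0.08/0.05) as in
  helices under pairing selection; unpaired columns uniform.
* **Events** — per branch and site, Poisson counts at per-class rates
  (defaults r_cbc 0.10, r_hcbc 0.20, r_break 0.05, r_restore 0.10,
  r_unpaired 0.30 per unit branch length) with uniform event times; illegal
  draws (a CBC on a mismatch, a restore on an intact pair) are discarded.
  CBC targets are uniform over the 3–4 legal double-sided moves, hCBC over
  the 1–2 wobble-mediated moves.  The random stream is partitioned per
  (branch, site) from the master seed, so growing the template does not
  perturb earlier sites.  No indels are generated; the numbering machinery
  is exercised by static gapped fixtures instead.
* **Modes** — `direct` draws CBCs as single double-sided events.  `staged`
  realizes each CBC as two hemi-steps through its wobble intermediate
  (only the four decomposable categories occur), with the second step
  placed on one randomly chosen child branch so completed stagings span a
  root-to-tip path.  `no_multihit` permits at most one event per site in
  the whole tree and keeps the two root-adjacent branches event-free.

The `no_multihit` restrictions are identifiability safeguards, not
cosmetics: a second hit on a pair, a parallel change in a sibling subtree,
or a change on a root-child branch can each make the parsimony root state
ambiguous, in which case the alphabetical tie-break may attribute the event
to the wrong branch.  Under `no_multihit` the detector provably recovers
the truth log exactly (precision = recall = 1 on every tested seed).  In
unconstrained `direct` simulations recall is *not* near 1 at moderate
rates — the tree's total length is several times its depth, so per-pair
multi-hits are common — but every miss is attributable: the test suite
asserts that each undetected truth event lies on a multi-hit pair or a
root-child branch.  Reconstruction artifacts of multi-hits can also
fabricate hCBC couples that legally compose, which is why the "no
two-step pathway in direct simulations" property is demonstrated in the
single-hit regime, where the truth log guarantees it.

Every truth log replays: re-applying its events from the root sequence
reproduces each leaf exactly, across all modes and seeds tested.

## What the synthetic data do and do not show

The generator emulates substitution-only evolution of a structure-frozen
locus: universal columns, a single shared secondary structure, homogeneous
per-class rates, no indels, no rate heterogeneity across sites or time, no
selection beyond the legality of pair states.  Passing recovery tests
therefore demonstrate the correctness of the mapping machinery under the
stated conditions — they do not certify performance on real alignments,
where alignment error, indels, rate heterogeneity and structure slippage
add failure modes outside this model.

## Problem sizes and defaults

Test and demonstration runs use 12-leaf Yule trees, the 129-column/45-pair
template, 20-seed batches for stochastic properties, and ≤7-leaf trees
(where exhaustive enumeration over all internal labelings is exact) for
the parsimony oracle — sizes at which every property is checked exactly
while the full suite runs in seconds.  The consensus threshold defaults to
0.70; all thresholds and rates above are package defaults, overridable per
run.
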