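# cbcmap

Phylogenetic mapping of compensatory base changes (CBCs) in paired RNA
regions — the "close-up" analysis of ITS2-style loci used for molecular
species delimitation.

## The problem

The internal transcribed spacer 2 (ITS2) of the rRNA cistron folds into a
conserved four-helix secondary structure.  In its base-paired regions,
substitutions come in characteristic classes:

* **CBC** — both nucleotides of a pair change while pairing is retained
  (e.g. G-C → A-U);
* **hCBC** (hemi-CBC) — one side changes with pairing retained, enabled by
  the G-U wobble (e.g. G-C → G-U);
* non-compensatory changes — a pair breaks (G-C → G-A), is restored, or a
  mismatch mutates.

A group of organisms with no CBC difference in the conserved parts of
helices 2 and 3 ("H2+3") is a *CBC clade*, a widely used proxy for
conspecificity.  The usual practice scores CBCs *phenetically*, by pairwise
comparison of two extant structures.  That is misleading: two taxa whose
pair states are A-U and G-U look like a single hCBC apart, but if their
common ancestor carried G-C, one lineage actually underwent a full CBC and
the other an hCBC — evidence for two species, not one.  Getting this right
requires mapping every pair change onto a phylogeny, with explicit handling
of homoplasy (parallelism, convergence, reversal).

`cbcmap` implements that mapping as a reusable, tested pipeline:

1. **Ancestral reconstruction** — per-column parsimony (Fitch sets, with
   Hartigan's majority rule on multifurcations) and delayed-transformation
   (DELTRAN) resolution, yielding the per-branch inventory of substitutions
   and branch lengths restricted to paired columns.
2. **Pair-event classification** — every branch × pair cell with a state
   difference becomes exactly one event: CBC, hCBC, pair_loss, pair_gain or
   mismatch_change.
3. **Homoplasy typing** — events are labeled NHS (unique synapomorphy) or
   PAR / CONV / REV with group registries, using strict-ancestry
   independence on the rooted tree.
4. **CBC clade/grade partition** — cutting the tree at every branch
   carrying a conserved-region CBC partitions the taxa into CBC clades
   (monophyletic), CBC grades (paraphyletic remainders) and the
   plesiomorphic grade at the root.
5. **Summary statistics** — per-branch saturation ratios
   `CBC_R = 2·CBC/steps` and `hCBC_R = hCBC/steps` (steps at paired columns
   only), the 6×6 pair-state transition tally with its 22 CBC / 8 hCBC
   directed categories, per-pair positional summaries, and extant pair-state
   frequencies.
6. **Two-step pathway audit** — searches every pair for ancestor–descendant
   couples of hCBCs whose composition is a legal CBC (the hypothetical
   "2× hCBC → CBC" route).
7. **Simulator** — paired-sequence evolution along a Yule or user tree
   under per-class Poisson rates, with a replayable ground-truth event log
   for recovery testing, plus universal-position numbering, 70 %
   majority-rule consensus and a six-category variability map for the
   alignment itself.

## Worked example

The built-in two-species fixture reproduces the textbook discrepancy.  Six
taxa share one conserved helix-2 pair that is ancestrally G-C; one focal
taxon carries A-U, its congener G-U.

```sh
cbcmap simulate --help            # simulator options
python - <<'EOF'
from cbcmap.simulate import make_two_species_fixture
from cbcmap.io import write_alignment, write_structure
ds = make_two_species_fixture()
write_alignment(ds.alignment, "aln.fasta")
write_structure(ds.structure, "struct.pairs")
open("tree.nwk", "w").write(ds.tree.to_newick() + "\n")
EOF
cbcmap run -a aln.fasta -s struct.pairs -t tree.nwk -o out
cbcmap phenetic -a aln.fasta -s struct.pairs -t tree.nwk \
    Acrochaete_viridis Acrochaete_heteroclada
```

`out/pair_events.tsv` (label columns omitted here for width):

```
branch_id               pair   helix conserved parent_state child_state class homoplasy_label
Acrochaete_viridis      15/26  2     1         G-C          A-U         CBC   NHS
Acrochaete_heteroclada  15/26  2     1         G-C          G-U         hCBC  NHS
```

The phylogenetic mapping finds one full CBC plus one hCBC — two species by
the CBC criterion — while the phenetic command prints

```
CBC     0
hCBC    1
other   0
```

i.e. a single hCBC, which would wrongly lump the two taxa.  The partition
table consistently places the CBC-bearing taxon in its own (single-member)
CBC clade and everyone else in the plesiomorphic grade.

For a branch with 4 CBCs among 21 evolutionary steps at paired positions the
saturation ratio is `CBC_R = 2·4/21 = 38 %`; two CBCs making up all four
steps of a short branch give 100 %; one hCBC among 21 steps gives
`hCBC_R = 4.8 %`:

```python
>>> from cbcmap.stats import single_branch_ratio
>>> single_branch_ratio(4, 0, 21)[0]
38.095238095238095
```

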