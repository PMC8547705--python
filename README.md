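# gh19net

Sequence-network analysis for glycoside hydrolase family 19 (GH19), the
bifunctional family of plant/bacterial **chitinases** (CHIT) and phage
**endolysins** (ELYS). The package reimplements, as a tested and reusable
library, the family-analysis workflow used to organize GH19 sequence space:

* **Protein sequence networks.** All-vs-all Needleman–Wunsch global
  alignments (BLOSUM62, gap open 10 / extend 0.5) give percent identities;
  centroid sequences become nodes, and an edge connects nodes whose identity
  meets a threshold. Connected components at 40% identity that contain a
  characterized *seed* sequence define subfamilies; components at 60% inside
  a subfamily define groups (a component is a group when it holds a seed or
  at least ten centroids).
* **Scale-free network statistics.** The degree distribution is fitted by a
  power law *N(n) ~ n^-γ* and the cluster-size distribution, log-binned over
  [2,10], [11,100], [101,1000], [1001,10000], by *N(s) ~ s^-τ_h*; the Fisher
  exponent τ is extrapolated linearly from the per-threshold slopes τ_h to
  the 100%-identity limit.
* **Standard numbering.** A per-subfamily column profile built from a seed
  alignment anchored to a reference structure's sequence transfers the
  reference position numbers to every member (position-specific-score global
  alignment), so homologous sites share one standard position number.
* **Conservation patterns.** Per-position rates are discretized into five
  conservation categories (5 = most conserved; majority-gap positions are
  category 1). Score-5 positions that correspond structurally between the
  two subfamilies, are nearly gap-free, and share a residue in >5% of the
  sequences of both form the **shared core**; score-5 positions without a
  correspondent, or with <5% residue-frequency overlap, form the
  **subfamily-specific patterns** that distinguish chitin from murein
  hydrolysis.
* **Binary loop codes.** Chitinases carry up to six loop insertions (loops
  1–5 and C-terminal). Per sequence, a loop is present when its observed
  length is at most four residues shorter than the reference loop; per
  group, presence frequencies condense into a six-character code over
  {1, 0, -} (≥65% → 1, ≤30% → 0). Of the 2⁶ = 64 combinatorially possible
  codes, only a handful occur.

Because the original dataset is a moving snapshot of public databases, the
package ships a **synthetic-data generator** that emulates the family
structure with known ground truth — two subfamilies whose cross-subfamily
identities peak near 30%, >60%-identity groups inside each, implanted
invariant core columns, subfamily-specific pattern columns, and per-group
loop insertions — so every stage is testable end to end without downloads.

## Worked example

Run the whole synthetic workflow — simulate, align, cluster, build networks,
classify, number, score conservation, annotate loops — and score the
recovery against the generator's truth:

```bash
gh19net pipeline --seed 1
```

prints

```json
{
  "subfamily_accuracy": 1.0,
  "group_accuracy": 1.0,
  "loop_code_exact_match": 1.0,
  "n_group_codes_compared": 6,
  "core_precision": 1.0,
  "core_recall": 1.0,
  "pattern_precision_CHIT": 1.0,
  "pattern_recall_CHIT": 1.0,
  "pattern_precision_ELYS": 1.0,
  "pattern_recall_ELYS": 1.0,
  "group_codes": {
    "CHIT 1": "111111",
    "CHIT 2": "101000",
    "CHIT 3": "110110",
    "ELYS 1": "111111",
    "ELYS 3": "011011",
    "ELYS 2": "101101"
  }
}
```

All 120 synthetic sequences recover their true subfamily (40% networks
anchored on the seeds' activity labels) and group (60% networks); the 40
implanted invariant core columns are recovered as the shared core with
precision and recall 1.0, the 6 chitinase-specific and 4 endolysin-specific
pattern columns likewise; and each group's six-character loop code (e.g.
`111111` for the loopful group, `101000` for a loopless-style group that
keeps only loops 1 and 3) equals the implanted presence flags.

Individual stages are available as subcommands operating on plain-text
formats (FASTA/TSV/GraphML): `simulate`, `identity`, `cluster`, `network`,
`classify`, `number`, `scan`, `conserve`, `loops`. For instance:

```bash
gh19net simulate --out-prefix fam --seed 5
gh19net identity --fasta fam.fasta --out matrix.tsv
gh19net network --matrix matrix.tsv --threshold 40 --graphml net.graphml
```

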