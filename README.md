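# blockvep

Block-wise evolutionary conservation features and random-forest prediction
of damaging amino acid substitutions in human proteins.

## The problem

Most nonsynonymous variants are classified by asking how well the affected
residue is conserved across homologous proteins. Pooling all homologs into
one alignment wastes information: a substitution tolerated in yeast says
something very different from one tolerated in chimpanzee, and paralogs
mixed in among orthologs corrupt the conservation signal outright.

`blockvep` keeps the homologs apart by evolutionary distance. Hits from a
protein homology search are stacked into a query-anchored multiple sequence
alignment, sorted by **normalized alignment score**

NAS(h) = S(q, h) / S(q, q),

the raw BLOSUM62 alignment score of hit *h* against the query *q* divided by
the query's self-alignment score, so NAS = 1 is an identical sequence and
NAS decays with evolutionary distance. The NAS-sorted stack is partitioned
into five **ortholog blocks** — primate; non-primate mammal; non-mammal
vertebrate; invertebrate; other species — by marking the first sequence of
each species category down the stack, plus a sixth **paralog block** that
collects sequences whose species category disagrees with the block they are
ranked in (a human paralog ranked among fish orthologs, or a contaminant
ranked among primates).

For a substitution (position *i*, reference residue *r*, mutant *m*), each
block *b* contributes seven features at column *i*:

- f_ref = n_r / n, f_mut = n_m / n — frequencies of *r* and *m* among the
  block's position-covering sequences;
- H = −Σ_a p(a) log₂ p(a) — Shannon entropy of the column (0 to
  log₂ 20 ≈ 4.322 bits);
- NAS_first — NAS of the block's first sequence (a per-protein evolving-rate
  gauge);
- No_all, No_qp, RatioNN — block size, number of sequences covering the
  position, and their ratio.

Together with one-hot encodings of *r* and *m* and the **lowest conserved
block** (the deepest block through which *r* is perfectly conserved,
paralogs excluded), this yields 83 features per variant. A random forest
(500 trees, √p features per split) votes on them; the score is the fraction
of trees voting *neutral*, and a variant is called **damaging when its score
falls below the trained cutoff**.

## Worked example

The bundled seven-hit toy (4 primates, mouse, zebrafish, one diverged human
paralog; every expected value hand-derivable from the BLOSUM62 matrix):

```python
import blockvep as bv

we = bv.worked_example()
msa, part = we.build()
for h in msa.hits:
    print(f"  {h.hit_id:6s} cat={int(h.category)} NAS={h.nas:.4f}")
for v in we.variants:
    vec = bv.build_feature_vector(msa, part, v)
    print(f"{v.aa_ref}{v.position}{v.aa_mut} ({v.label}): "
          f"B1_f_ref={vec['B1_f_ref']:.2f} B1_f_mut={vec['B1_f_mut']:.2f} "
          f"B1_entropy={vec['B1_entropy']:.3f} "
          f"lowest_conserved_block={vec['lowest_conserved_block']:.0f}")
```

prints

```
  PRIM1  cat=1 NAS=1.0000
  PRIM2  cat=1 NAS=0.9783
  PRIM3  cat=1 NAS=0.9348
  PRIM4  cat=1 NAS=0.9348
  MAM1   cat=2 NAS=0.8696
  VERT1  cat=3 NAS=0.7826
  PARA1  cat=1 NAS=0.5000
V3I (neutral): B1_f_ref=0.75 B1_f_mut=0.25 B1_entropy=0.811 lowest_conserved_block=0
W6C (damaging): B1_f_ref=1.00 B1_f_mut=0.00 B1_entropy=0.000 lowest_conserved_block=5
```

`PARA1` is a human (primate) sequence ranked below the fish ortholog, so it
lands in the paralog block. The neutral variant sits at a position already
polymorphic among primates (one of four primate sequences carries the mutant
residue: f_mut = 0.25, entropy 0.811 bits, nothing conserved even through
the primate block). The damaging variant hits a tryptophan conserved through
every block (lowest conserved block = 5).

## Command line

```sh
blockvep make-fixture --out-dir data/            # synthetic labeled dataset
blockvep train    --variants data/variants.tsv --msa-dir data --out model.bin
blockvep predict  --model model.bin --variants data/variants.tsv --msa-dir data --out pred.tsv
blockvep evaluate --model model.bin --variants data/variants.tsv --msa-dir data --out report.json
blockvep crossval --variants data/variants.tsv --msa-dir data --folds 10 --seed 17 --ablation --out cv.json
```

The MSA directory holds, per protein, `<id>.fasta` (query) and
`<id>.hits.tsv` (an 11-column tab-separated hit table that includes the
gapped aligned strings of each HSP), plus a shared `lineage.tsv` mapping
taxids to semicolon-joined lineages. Running the homology search itself is
out of scope — any BLAST-compatible pipeline that can emit aligned HSP
strings can produce the hit table.

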