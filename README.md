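# codoncomp

Compositional dynamics of protein-coding sequences: predict the expected
nucleotide, codon and amino-acid compositions of a coding-sequence
collection from just two parameters — its GC content *S* and its purine
content *R* — and compare them with the observed compositions.

## Who this is for

Molecular-evolution and comparative-genomics work frequently asks how much
of a genome's codon and amino-acid usage is explained by its overall base
composition (mutation pressure) and how much is left over for selection to
explain. `codoncomp` provides the null expectation: a mechanistic model of
composition driven only by *S* and *R*, so that deviations of observed from
expected usage can be read as compositional signatures of selection.

## The model

Treating GC content and purine content as statistically independent, each
nucleotide frequency on the coding strand factorises:

    A = (1 − S)·R        T = (1 − S)·(1 − R)
    G = S·R              C = S·(1 − R)

The same identities applied per codon position *i* ∈ {1, 2, 3} with
position-specific contents (S_i, R_i) give positional nucleotide
frequencies x_i. A sense codon *xyz* then has expected frequency

    E[xyz] = x₁·y₂·z₃ / (1 − Σ_{abc ∈ stops} a₁·b₂·c₃)

over the 61 sense codons of the standard genetic code, and an amino acid's
expected frequency is the sum over its synonymous codons. Stop codons are
excluded from every observed and expected quantity.

Two strategies supply (S_i, R_i):

* **Model 1** predicts them from the global contents through straight-line
  relations (S → S_i, R → R_i) fitted by ordinary least squares across a
  species collection — empirical prior knowledge, smoother predictions.
* **Model 2** counts them directly from the input sequences — purely
  mechanistic, no prior knowledge. With identity relations Model 1 reduces
  to Model 2's behaviour on a positionally homogeneous sequence.

A separate module builds symmetric 20×20 amino-acid **exchange matrices**
from aligned orthologous proteins (alignments under 85% identity removed)
and ranks the most exchangeable residue pairs.

## Worked example

The dinucleotide repeat `CGCGCG` (codons CGC, GCG) has observed S = 1.0 and
R = 0.5; the model then expects no A or T and equal G and C:

```python
>>> from codoncomp import read_cds_fasta, observed_global_content, expected_nucleotides
>>> _, table = read_cds_fasta("cgcgcg.fasta")   # >repeat / CGCGCG
>>> content = observed_global_content(table)
>>> (content.S, content.R)
(np.float64(1.0), np.float64(0.5))
>>> expected_nucleotides(content)
{'A': 0.0, 'T': 0.0, 'G': 0.5, 'C': 0.5}
```

G = S·R = 0.5 and C = S·(1−R) = 0.5: the expectation reproduces the
observed composition of the repeat exactly, including its extreme
dinucleotide bias at the nucleotide level.

The same pipeline from the shell, via the CLI:

```sh
codoncomp simulate --n-species 10 --n-codons 2000 --seed 7 --out collection.spsum
codoncomp fit collection.spsum --input-format spsum --min-cds 64 --out relations.tsv
codoncomp expect collection.spsum --input-format spsum --model 1 \
    --relations relations.tsv --out deviations.tsv
```

`fit` prints one slope/intercept/r² triple per (predictor, position) pair;
`deviations.tsv` lists observed, expected, signed difference and ratio for
every nucleotide scope, sense codon and amino acid.

## File formats

* **CDS FASTA** — in-frame coding sequences; codons with non-ACGT symbols
  are skipped and tallied, stop codons are counted at read time and
  excluded by the composition layer.
* **SPSUM-style codon usage** — two lines per record: `label<TAB>n_cds`
  then 64 whitespace-separated integer counts. The column order is explicit
  configuration (`--codon-order`); the default matches the Codon Usage
  Database's documented order.
* **Relations file** — plain-text key-value serialisation of the six fitted
  lines, with provenance and per-relation r²; round-trips bit-exactly.
* **Reports** — TSV with ≥10 significant digits on floats.

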