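# neofunnel

Candidate-neoantigen prioritization and tumor-microenvironment signature
scoring for personalized cancer-vaccine target discovery, modeled on a
murine (Panc02 / C57BL/6, H-2Kb) pancreatic cancer workflow.

Tumor-specific missense mutations create mutant peptides that can be
presented on MHC class I and recognized by CD8+ T cells. Selecting which of
the hundreds of exome mutations to synthesize as vaccine peptides requires
combining MHC-binding prediction with DNA/RNA read support and expression
evidence. `neofunnel` implements that selection funnel as a tested,
reusable library plus CLI, together with the downstream bulk-transcriptome
analyses (ssGSEA immune/fibroblast signature scores, Spearman correlation,
median-split Kaplan–Meier survival) and the closed-form immunoassay
calculations used to validate the selected peptides.

## The method

For each somatic missense variant, the mutated protein is reconstructed and
every 8–11-mer window containing the altered residue is enumerated (38
windows for an interior site). Each window is scored by a roster of k = 8
MHC-I binding predictors as a **percentile rank** (lower = stronger
binding); the window's rank is the **median across predictors**, and the
variant's binding value is the minimum over its windows. A variant is a
**candidate neoantigen** iff all five criteria hold (all thresholds
inclusive):

1. best median percentile rank ≤ 2 %
2. depth ≥ 20× and VAF ≥ 0.1 in the tumor at both the DNA and RNA level
   (VAF = alt reads / depth)
3. depth ≥ 20× and VAF ≤ 0.01 in the matched normal
4. TPM ≥ 1 for both the gene and the transcript
5. tumor DNA VAF ≤ 0.6 (germline exclusion)

Passing candidates are carried into vaccine design as 17-AA long peptides
(8 residues flanking the mutated residue, clipped at protein termini).
Because the study's sequencing data are unreleased, a synthetic-data module
generates cohorts whose funnel shape (e.g. 1164 exome mutations → 123
expressed → 19 candidates) is planted exactly, with machine-readable truth.

The signature analyses score a gene set per sample with single-sample GSEA
(rank-weighted running sum, weight = rank^0.25, average ranks on ties):
CD8+ T infiltration from the {CD8A, CD8B} signature, fibroblast/Treg scores
from the top-20 fold-change cluster markers, with Spearman correlation
between genes and scores and a median-split log-rank survival comparison.
Immunoassays: ELISPOT positivity (spots strictly > 500), LDH cytotoxicity
`(sample − low) / (high − low) × 100 %`, and qPCR fold change `2^−ΔΔCt`.

## Worked example

Simulate a 200-variant cohort with 60 expressed and 10 planted candidates,
then run the funnel:

```bash
neofunnel simulate --n-total 200 --n-expressed 60 --n-candidates 10 \
    --seed 42 --out demo
neofunnel prioritize --variants demo/variants.tsv \
    --expression demo/expression.tsv --predictions demo/predictions.tsv \
    --proteins demo/proteins.fasta --out demo/prio --json
```

which logs

```
funnel: 200 input -> 60 expressed -> 10 candidates; failures per criterion:
{'binding': 10, 'tumor_support': 104, 'normal_absent': 10, 'expressed': 56,
 'not_germline': 10}
```

i.e. all 200 variants were evaluated, 60 were confirmed expressed
(RNA depth ≥ 20, RNA VAF ≥ 0.1, gene TPM ≥ 1), and 10 cleared all five
criteria — exactly the planted truth in `demo/truth.json`. The candidate
table ranks by best median percentile rank:

```
variant_id  gene       protein_change  best_peptide  best_median_rank  ... passed
var00159    Gene00159  K235P           DMPKPLHSIWI   0.62              ... True
var00106    Gene00106  C11F            ALKFCITEMW    0.71              ... True
```

and `demo/prio/long_peptides.fasta` holds the 17-AA vaccine peptides, e.g.
`>Gene00159_K235P|len17|off8` / `PMHPFFDMPKPLHSIWI` — the mutant residue
(P) at the center, offset 8. The `score` subcommand runs the ssGSEA /
correlation / survival analyses and `assay` the batch ELISPOT, cytotoxicity
and ΔΔCt calculations; see `neofunnel --help`.

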