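# craspseq

Toolkit for reading out pooled CRISPR screens whose phenotype is an RNA
splicing decision. In these screens every lentiviral construct carries a
hybrid guide RNA (hgRNA: a 20-nt Cas9 spacer fused to a 23-nt Cas12a spacer),
a 12-nt cell barcode (CBC), and an inducible minigene splicing reporter.
Sequencing the reporter mRNA together with the guide cassette links each
genetic perturbation directly to a splicing outcome: Read 1 identifies the
hgRNA, CBC and UMI; Read 2 covers the reporter's splice junction.

`craspseq` is for computational biologists analysing such screens (or
designing the libraries for them). It implements:

- **Read parsing** — anchored, Hamming-tolerant extraction of the Cas9/Cas12a
  spacers, CBC and UMI from Read 1; junction-signature classification of the
  splice outcome from Read 2; exact/Hamming-1 dictionary matching of spacer
  pairs against the library.
- **Deduplication** — directional greedy clustering of CBCs and UMIs at
  Hamming distance 1; one molecule per (hgRNA, CBC cluster, UMI cluster),
  outcome by strict majority.
- **Quantification** — per-guide percent spliced-in,
  `PSI = 100 · IE / (IE + EE)` over inclusion (IE) and exclusion (EE)
  molecule counts, and `ΔPSI = PSI_guide − PSI_intergenic`, where
  `PSI_intergenic` pools the counts of all intergenic control guides.
- **Hit calling** — an empirical 10% FDR: significance cutoffs at the 5th and
  95th percentiles of the intergenic PSI distribution; gene hits need a
  gene-level PSI beyond the cutoff, more than half of the gene's guides (and
  at least two) significant in the same direction, and agreement between two
  pseudo-replicates formed by randomly halving each guide's CBCs.
- **Base-editor tiling** — per-guide ΔPSI averaged across adenine/cytosine
  editor screens, genome→protein mapping of protospacers through a transcript
  CDS model, and mean-ΔPSI profiles in 10-amino-acid windows.
- **Library design** — the rule engine that builds hgRNA libraries from
  precomputed candidate tables: off-target/on-target filters, six-round
  quality ranking with thresholds relaxed by fifths, top-25 selection,
  tiered Cas9×Cas12a pairing (150-bp optimal cut distance), reshuffling,
  sparse-gene fallback compositions, paralog-pair hybrids, and the
  base-editor library filters.
- **Simulation** — a synthetic screen generator (library, ground-truth
  molecules, paired FASTQ) with binomial splice outcomes, Poisson PCR
  duplication and substitution noise, so the whole pipeline is verifiable
  without external data.

## Worked example

Simulate a small screen with two true regulators (ΔPSI ±30) among two null
genes and 40 intergenic controls, then run the full knockout pipeline:

```bash
crasp simulate --out demo/sim --seed 3 --n-genes 4 --n-intergenic 40 \
    --depth 80 --cbcs-per-guide 8 --substitution-rate 0.001 \
    --effects "G0001=30,G0002=-30"
crasp run-ko --r1 demo/sim/reads_R1.fastq.gz --r2 demo/sim/reads_R2.fastq.gz \
    --library demo/sim/library.tsv --seed 5 --min-reads 10 --out demo/results
```

The run log ends with

```
INFO crasp: pairs=7919 annotated=7910 molecules=5275 hits=2
```

7,919 read pairs collapse to 5,275 unique molecules (the simulator's PCR
duplication rate is 1.5) and exactly the two engineered regulators are
called. `demo/results/gene_results.tsv`:

```
 gene  n_guides_quantified  n_guides_significant direction  gene_dPSI  hit_R1  hit_R2  final_hit
G0001                    4                     4        up  30.978458    True    True       True
G0002                    4                     4      down -25.994977    True    True       True
G0003                    4                     0      none  -0.092754   False   False      False
G0004                    4                     0      none  -0.920116   False   False      False
```

`gene_dPSI` is the pooled gene-level PSI minus the intergenic reference,
averaged over the two CBC pseudo-replicates — close to the programmed +30/−30
for the true regulators and near 0 for the nulls. The per-guide table
(`guide_results.tsv`) carries IE/EE counts, PSI, ΔPSI and the per-replicate
significance call for every hgRNA, e.g.

```
 hgrna_id  gene      class replicate  IE  EE   PSI   dPSI  low_coverage  significance
G0001_hg1 G0001  targeting        R1  39   5 88.64  39.86         False             1
G0001_hg1 G0001  targeting        R2  25  10 71.43  19.52         False             1
```

Base-editor screens run through `crasp run-be` (per-editor per-guide counts
→ editor-averaged guide/gene ΔPSI tables plus 10-aa tiling profiles) or
`crasp tile` for the protein-mapping step alone; the library-design rules are
exposed through `craspseq.guide_design` (see `docs/methods.md`).

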