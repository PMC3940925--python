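# paralomir

Many animal miRNA hairpin precursors are paralogs: two or more hairpins at
distinct genomic loci that are processed into an *identical* major mature
miRNA (mouse miR-128-1 and miR-128-2 both yield miR-128-3p; miR-194-1 and
miR-194-2 both yield miR-194-5p). Reads of the shared major form map to
every member, so major-form expression alone cannot say *which* precursor
is transcribed in a tissue. `paralomir` attributes the shared expression to
individual precursors using the evidence that does differ between members —
the minor (passenger) strand, the host gene, and the genomic cluster
context — starting from nothing more than a miRBase-style small-RNA
read-mapping table (precursor, read start position, count, tissue).

It is aimed at people analysing bulk or single-cell small-RNA read-count
compendia who need precursor-level (rather than mature-level) expression
calls: annotating arm usage and arm switching, resolving paralogous
families, and corroborating calls with qPCR statistics.

## The statistics

For the entity × tissue read-count matrix *M* with row totals
*T<sub>i</sub>* and per-tissue read fractions *Q<sub>j</sub>* (reads in
tissue *j* over all reads), the tissue specificity of entity *i* in tissue
*j* is the binomial enrichment z-statistic, truncated at zero:

```
Z_ij = max(0, (M_ij − T_i·Q_j) / sqrt(T_i·Q_j·(1 − Q_j)))
```

The tissue coexpression score of a major/minor pair is the product
`S_j = Z_major,j · Z_minor,j`, which is large only where both forms are
jointly enriched and exactly 0 whenever the minor form has no reads.
Entities with ≤ 50 total reads are excluded. Pairs are screened by keeping
the global top decile of scores and requiring the minor form to be
differentially expressed against every sibling minor in its family
(two-tailed Fisher exact test, tissue *j* vs all other tissues, p < 0.05);
the qualifying member with the highest score is called the contributing
precursor for that family and tissue.

Around this sit: reads-per-million normalization and GCT 1.2 export;
Pearson R/p screens (exact t-transform null, n−2 df) for major/minor,
clustered, and host-gene/miRNA pairs; SPM/CTM tissue-pattern calls
(SPM<sub>j</sub> = x<sub>j</sub>/‖x‖, specific when SPM > 0.9; selective
when ≥ 2 tissues have SPM > 0.5 with joint CTM > 0.9); single-linkage
genomic clustering (same chromosome/strand, gap < 5000 bp); and
comparative-CT (ΔΔCt) qPCR quantification with one-way ANOVA + Tukey HSD
preferential-tissue calls.

## Worked example

The built-in generator plants a ground truth — paralogous families whose
members share a major mature sequence but are transcribed in different
tissues — and the pipeline recovers it:

```python
from paralomir import simulate, SimulationConfig, pipeline

sim = simulate(SimulationConfig(seed=7))
fams, report, inputs = pipeline.discriminate(sim.reads, sim.annotations)
print(f"families: {len(fams)}   scored rows: {len(report.rows)}")
print(report.contributors().sort_values(["family_id", "tissue"]).head(6).to_string(index=False))
```

```
families: 8   scored rows: 240
     family_id      tissue  precursor_id
sim-miR-100-5p bone_marrow sim-mir-100-1
sim-miR-100-5p      thymus sim-mir-100-2
sim-miR-101-3p  lymph_node sim-mir-101-2
sim-miR-101-3p      spleen sim-mir-101-1
sim-miR-102-5p       brain sim-mir-102-1
sim-miR-102-5p       heart sim-mir-102-2
```

Each row says: in that tissue, this member of the family is the precursor
contributing the shared major mature form. The per-pair evidence behind
the first family shows the score contrast and Fisher filter that drive the
call — member 1's pair scores ~1739 in bone marrow where member 2 scores
0, and vice versa in thymus (score ~4273):

```
 precursor_id      tissue     score  selected_top10  fisher_p
sim-mir-100-1 bone_marrow 1738.5734            True       0.0
sim-mir-100-1      thymus    0.0000           False       0.0
sim-mir-100-2 bone_marrow    0.0000           False       0.0
sim-mir-100-2      thymus 4272.5548            True       0.0
```

The same run is available from the shell:

```sh
paralomir simulate --seed 7 -o store/
paralomir discriminate --store store/ -o table2.tsv
paralomir pattern --store store/ -o table1.tsv
paralomir clusters --store store/ -o cluster_pairs.tsv
```

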