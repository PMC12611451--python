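# cerna

Prioritization of circRNA–miRNA–mRNA "sponge" networks.

Circular RNAs (circRNAs) carry binding sites for microRNAs and can act as
molecular sponges: by sequestering a miRNA they de-repress that miRNA's
mRNA targets (the competing-endogenous-RNA, ceRNA, hypothesis). Given a
circRNA→miRNA sponge map and a miRNA→gene validated-target map — e.g.
snapshots of circATLAS and miRTargetLink exports — this package answers,
for two study groups (such as a disorder group and a tissue group):

1. **Which miRNAs are hubs?** The in-degree of a miRNA is the number of
   distinct circRNAs sponging it. Hubs are miRNAs with in-degree ≥ a
   cutoff, either fixed ("sponged by eight or more circRNAs") or placed at
   the elbow of the sorted distinct-degree curve (maximum perpendicular
   distance to the endpoint chord).
2. **Which circRNAs matter?** A *reverse search* ranks circRNAs by how
   many hub miRNAs each one sponges.
3. **What do the hubs regulate?** The hubs' target genes are tested for
   pathway overrepresentation with the one-sided hypergeometric test

   P(X ≥ k), X ~ Hypergeom(N, K, n)

   where `N` is the background size, `K` the pathway size, `n` the query
   size and `k` the overlap, with Benjamini–Hochberg FDR across tested
   pathways (q < 0.05), a minimum-overlap filter, keyword-based pathway
   categorization (transcription / replication / immune / ASD-related) and
   per-category recurrent-gene selection.
4. **Which genes overlap a risk catalog?** Each group's relevant genes are
   intersected with a risk-gene catalog (SFARI-style) and compared across
   groups (Venn partition).
5. **Which circRNA covers everything?** On the tripartite network
   restricted to the shared risk genes, each circRNA is scored by the
   genes reachable through its sponged miRNAs; a circRNA reaching *all*
   shared genes is a *full-cover* candidate. An exact (or, for large
   inputs, greedy) minimum set cover and the candidate's cross-group
   shared miRNAs complete the picture.

A synthetic-interactome generator with planted ground truth (hub miRNAs,
a full-cover circRNA, an enriched pathway) makes every stage testable
without database access.

## Worked example

The packaged fixtures transcribe the two published study tables (ASD group
and placenta group). Running the pipeline on them:

```python
from cerna.pipeline import run_pipeline, worked_example_config

report = run_pipeline(worked_example_config("example_run"))
print(report.venn["shared"])
print(report.full_cover_circrnas)
print(sorted(report.shared_mirnas["hsa-MAN1A2_0008"]))
```

prints

```
['CREBBP', 'NOTCH1', 'PSMD11', 'SRSF11', 'TBL1X']
['hsa-MAN1A2_0008']
['hsa-miR-4722-5p', 'hsa-miR-6875-3p', 'hsa-miR-942-5p']
```

i.e. five risk genes are shared between the groups; exactly one placental
circRNA, hsa-MAN1A2_0008, sponges miRNAs that collectively regulate all
five (via miR-4722-5p→PSMD11, miR-942-5p→CREBBP, miR-6875-3p→TBL1X,
miR-6832-3p→SRSF11 and miR-623→NOTCH1); and three of those miRNAs are also
sponged by circRNAs of the other group.

The same stages are available as a CLI:

```bash
cerna hubs --sponge placenta.tsv --cutoff-mode fixed --fixed-cutoff 5 --out hubs.json
cerna ora --genes genes.txt --gmt reactome.gmt --universe universe.txt --out ora.tsv
cerna network --sponge-a asd.tsv --sponge-b placenta.tsv \
      --targets targets.tsv --risk sfari.tsv --out netdir/
cerna simulate --seed 7 --out bundle/
cerna run --config pipeline.yaml
```

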