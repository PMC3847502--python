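# lignotx

Comparative transcriptomics of *Trichoderma reesei* grown on a
lignocellulosic substrate (wheat straw), lactose and glucose — the workflow a
fungal enzyme-production lab uses to ask *which genes does the insoluble
inducer switch on that the soluble one does not?* — packaged as a tested,
reusable pipeline exercised end to end on synthetic data with planted ground
truth.

The pipeline covers five stages:

1. **Transcript groups.** From a genes x samples log2 expression matrix,
   genes "up" on condition X are those with fold(X/glucose) >= 2 at p < 0.05
   (pooled-variance t on log2 replicates, fold changes from differences of
   log2 condition means). The universe partitions into group **A** (up on
   wheat straw only), **B** (lactose only), **C**/**D** (up on both,
   >=2-fold stronger on wheat straw / lactose in the direct contrast),
   **E** (up on both, comparably), a **constitutive** set (all condition
   means within a +/-1.4-fold band, above an expression floor), and the
   remainder.
2. **Enrichment.** Independent chi-square tests (1 df) of each functional
   category (FunCat / KOG / CAZy family) in each group against the
   genome-wide annotation distribution, with Fisher fallback at low expected
   counts.
3. **Clustering.** Agglomerative clustering of condition-mean vectors
   (Euclidean, average linkage) with Newick export and 0-16 log2 heat maps.
4. **Promoter motifs.** Non-overlapping scans for the XYR1 consensus GGCW₄
   (`GGCWWWW`) in -1000..-1 promoter windows, average sites per gene, and a
   Monte-Carlo two-sample Anderson-Darling test of observed counts against
   the Poisson null implied by the genome-wide density (20,692 sites /
   33 Mbp ≈ one per 1,500 bp).
5. **Assays.** Dilution-series efficiencies (E = 10^(-1/slope)),
   efficiency-corrected relative expression
   R = E_t^ΔCt(t) / E_r^ΔCt(r) against a calibrator sample normalized on
   *tef1*, fixed-reallocation randomization and Welch t significance, and
   dry biomass from intracellular protein (0.35 g protein per g dry mass,
   substrate-control corrected).

A synthetic-data module generates every input with known truth (planted
group labels at the study's own proportions, controlled category
enrichments, promoters carrying exact non-overlapping site counts, Ct tables
from inverted ratio models), so each stage's recovery of its planted truth
is a test, not a hope. See `docs/methods.md` for models, assumptions and
parameter defaults.

## Worked example

```bash
python analysis/01_simulate_inputs.py   # writes results/synthetic/
python analysis/02_transcript_groups.py
python analysis/05_promoter_motifs.py
```

which prints (seed 7, 2,000 genes, three replicates):

```
group sizes: {'A': 355, 'B': 63, 'C': 75, 'D': 14, 'E': 176, 'CONSTITUTIVE': 225, 'NONE': 1092}
planted-label recovery: 99.2%
panel: 7/7 genes significantly up on wheat straw, 0/7 on lactose
...
average sites per gene: 0.650
genome-wide expected spacing: 1595 bp (~1500 bp)
Anderson-Darling vs Poisson(lambda=0.627) null: A2=1.225, p=0.261 (no rejection at alpha=0.05; ...)
```

Reading: the classifier recalls 99% of the planted transcript-group labels
(the planted sizes were 355/63/75/14/176/241), the seven-gene planted panel
behaves like the wheat-straw-specific autophagy panel it emulates, and
promoters whose site counts were drawn *from* the genome-density null are —
correctly — not flagged as enriched in XYR1 sites. The remaining scripts
(`03` enrichment, `04` clustering/heat map, `06` qPCR + biomass) write their
tables under `results/`.

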