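# gchap

Gene-CDS-haplotype (gcHap) diversity analysis for inbred crop panels.

In a selfing crop such as Asian rice, each accession is effectively
homozygous, so the ordered string of alleles it carries at the SNP sites
inside a gene's coding sequence — its *gene-CDS haplotype* — is a natural
unit of allelic identity. Given a variant file, gene CDS models, accession
metadata and phenotypes, `gchap`:

- calls one gcHap per accession per gene from a VCF (biallelic SNPs only),
  with switchable heterozygote/missing policies;
- summarises per-population diversity: number of haplotypes (gcHapN),
  major haplotypes (frequency ≥ 1%, or an absolute-count variant),
  Shannon's equitability, diversity classes, and the predominant haplotype
  with its frequency F(P);
- measures between-population differentiation with Nei's genetic identity;
- accounts for haplotype **lost / new / retained** between a landrace (LAN)
  and a modern-variety (MV) population, including promotions of rare
  haplotypes to major ones, with a chi-square test on the
  predominant-haplotype frequency shift;
- builds minimum-spanning haplotype networks over major haplotypes;
- associates major haplotypes with trait values (one-way ANOVA, Tukey or
  Duncan compact letter display) and mines favorable/unfavorable alleles;
- generates fully seeded synthetic panels so every stage is testable
  without any external download.

## The statistics

For a gene with $S$ haplotypes at frequencies $p_1,\dots,p_S$ within a
scope (the whole panel or one population):

- **Shannon's equitability** (Pielou evenness)
  $E_H = \dfrac{-\sum_i p_i \ln p_i}{\ln S}$, with $E_H = 0$ when $S = 1$.
  Genes are binned into diversity classes: HK (no CDS SNPs, one
  haplotype), low ($0 < E_H < 0.05$), medium-low ($0.05 \le E_H < 0.3$),
  medium-high ($0.3 \le E_H < 0.7$) and high ($0.7 \le E_H \le 1$).
- **Nei's genetic identity** between populations with frequency vectors
  $p, q$ on the union of their haplotype sets:
  $I_{Nei} = \dfrac{\sum_i p_i q_i}{\sqrt{\sum_i p_i^2 \sum_i q_i^2}}$,
  with $I_{Nei} < 0.35$ flagged as strong differentiation.
- **Breeding impact**: haplotypes present in LAN but absent in MV are
  *lost*, absent in LAN but present in MV are *new*, present in both
  *retained* (so |lost| + |retained| = LAN gcHapN and |new| + |retained| =
  MV gcHapN). The same accounting on each scope's own major sets separates
  promotions from novel haplotypes. Mean per-locus losses/gains are
  reported as percentages of population-wide per-locus means.
- **Association**: one-way ANOVA of trait values across major-haplotype
  groups; p < 1e-7 is flagged a strong association. The *favorable*
  haplotype has the most desirable (default highest) mean trait value; the
  *unfavorable* one is the lowest-frequency major haplotype, contrasted
  against the predominant haplotype with a Welch t-test.

## Worked example

Simulate a miniature four-population panel (26 genes, 2 of them
monomorphic, 298 accessions) and inspect one gene:

```python
from gchap import (scenario_presets, simulate_panel, call_panel,
                   diversity_stats, pairwise_identity_matrix)

cfg = scenario_presets("A_diversity")
cfg.seed = 7
panel = simulate_panel(cfg)
tables = call_panel(panel.variants, panel.genes)

s = diversity_stats(tables["gene003"])
print(f"gene003: gcHapN={s.gchapn}  majorN={s.majorn}  E_H={s.e_h:.3f} "
      f"class={s.diversity_class}  predominant={s.predominant} (F_P={s.f_p:.3f})")

m = pairwise_identity_matrix(tables["gene003"], panel.partition)
print(m.identity.round(3))
```

prints

```
gene003: gcHapN=19  majorN=13  E_H=0.805  class=high  predominant=Hap1 (F_P=0.215)
       Xian   Geng    Aus    Bas
Xian  1.000  0.517  0.167  0.413
Geng  0.517  1.000  0.078  0.396
Aus   0.167  0.078  1.000  0.029
Bas   0.413  0.396  0.029  1.000
```

gene003 is a high-diversity gene (19 haplotypes, evenness 0.805) whose
most frequent haplotype covers 21.5% of the panel; the Aus population is
strongly differentiated from every other ($I_{Nei} < 0.35$), while
Xian–Geng sit just above the cutoff in this simulated panel.

The same pipeline runs from the shell:

```bash
gchap simulate --preset A_diversity --seed 7 --out run/
gchap all --run-dir run/
```

which writes `haplotypes.tsv`, `diversity.tsv`, `nei_identity.tsv`,
`network_edges.tsv`, `association.tsv` (plus `impact.tsv` when the
metadata contains both LAN and MV accessions) and a manifest per stage.

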