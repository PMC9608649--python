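# mutclust

Mutation hotspot and cluster statistics for protein variant tables, built
around the variant catalogues of two rare neurodevelopmental syndromes:
Okur-Chung (OCNDS, *CSNK2A1*/CK2α, 391 aa) and Poirier-Bienvenu (POBINDS,
*CSNK2B*/CK2β, 215 aa). Given a table of patient variants in HGVS-style
notation, the package answers four questions:

1. **Where do patients cluster?** Nonrandom mutation clustering (NMC): under
   a uniform null, the spacing between the i-th and j-th of m ordered mutation
   events follows Beta(j−i, m−(j−i)+1); every pair is tested and the family is
   FDR-controlled with Benjamini–Hochberg. Single-residue clusters are the
   mutation hotspots.
2. **Is one codon's variant spectrum skewed?** An exact multinomial test of
   the per-residue patient counts across the nine possible single-nucleotide
   variants of a codon against the equal-1/9 null, with the chi-square
   discrepancy as statistic.
3. **Which domains are enriched?** Patients-per-residue density over named
   functional/structural residue sets, plus the interdomain complement.
4. **Do effect predictors agree?** Binary benign/effect recoding, percent
   agreement, Cohen's κ, and McNemar's test for every predictor pair.

A synthetic-data module generates variant tables, codon counts and paired
predictor calls with known ground truth, and a calibration harness measures
type-I error and power of the statistical stages — so the whole pipeline is
testable without any external downloads. The curated CK2α/CK2β tables and
domain definitions ship as packaged fixtures.

## Worked example

```python
import mutclust as mc
from mutclust.data import fixture_path, load_gene_config

cfg = load_gene_config("csnk2a1")
records = mc.load_variant_table(fixture_path("csnk2a1_variants.tsv"), cfg)
print(len(records), sum(r.n_patients for r in records))
# 60 121

profile, counts = mc.residue_patient_counts(records, cfg["protein_length"])
print(counts[198], counts[50], counts[47])
# 24 11 10

domains = mc.load_domain_config(fixture_path("csnk2a1_domains.json"), 391)
hotspots = mc.single_residue_clusters(mc.nmc_scan(profile), domains=domains)
top = hotspots[0]
print(top["residue"], top["n_samples"], f'{top["adj_p"]:.2e}', top["domains"])
# 198 24 4.55e-32 Activation segment; P+1 loop
```

The 121 patient events concentrate most extremely at residue K198 (24
patients, all K198R), in the P+1 substrate-recognition loop: the chance of 24
of 121 uniform events packing into one residue of 391 is astronomically small
even after correcting across all 7260 tested pairs. The remaining hotspots
rank 50, 47, 80, {191, 312}, {51, 156, 160}, {39, 175, 195} — the Gly-rich
loop, polybasic stretch, catalytic loop and activation segment of the kinase.

The same analyses run from the shell via the `mutclust` CLI
(`parse`, `counts`, `density`, `nmc`, `hotspot-test`, `concord`, `simulate`,
`calibrate`), and the numbered drivers under `analysis/` reproduce the full
study (variant tallies, domain densities, NMC scans with residual report,
codon hotspot tests, a concordance demo and the calibration table), writing
their outputs under `results/`.

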