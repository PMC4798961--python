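# clipscan

CLIP-seq analysis for RNA-binding proteins with U-rich specificity:
scan-statistic peak calling, normalized binding quantification and target
ranking, TMM/negative-binomial differential testing, cassette-exon
splicing GLMs, degenerate-motif and gene-set overlap statistics, and
Y RNA binding/sequestration analysis — with synthetic-data generators so
every stage is testable without any sequencing download.

It is written for computational biologists analyzing HITS-CLIP (or
similar crosslinking-immunoprecipitation) data who want the statistical
machinery of the classic brain nELAVL-style analyses as a tested,
reusable library rather than a collection of one-off scripts.

## The core model

A gene with span length L contributes n unique CLIP tag starts. Under the
null the starts are iid uniform on (0, L); a binding site is a window of
width w (the tag length) whose tag count — the PeakHeight, PH — is larger
than uniform scatter explains. The peak p-value is the scan statistic

    p = P( max_t #{starts in [t, t+w)} >= PH | n starts ~ U(0, L) ),

computed exactly (polytope volume of the order-statistics spacing
constraints) for small n and by a Naus-style product approximation with an
exact two-window term for genome-scale n, then Bonferroni-corrected over
all clusters tested. Retained peaks must also appear in at least 5 of 8
samples (biological complexity, BC). Downstream, binding is normalized as
norm_PH = (PH·10⁶ / pooled library size) / rpkm of the host gene;
differential binding and expression use TMM-normalized negative-binomial
GLM likelihood-ratio tests; cassette-exon inclusion I = inc/(inc + skip)
(inc averages the two inclusion junctions) is tested with a logit-link
binomial GLM, significant when FDR < 0.05 and |ΔI| ≥ 0.1.

## Worked example

Simulate a 20-gene annotation, implant one 15-fold-enriched 50-nt binding
window in gene `g00002`, generate 8 CLIP samples, and call peaks:

```python
from clipscan import simulate as sim
from clipscan.peaks import call_peaks, peaks_to_frame
from clipscan.tags import collapse_by_start
from clipscan.stats import OverlapSpec, hypergeom_tail

ann = sim.simulate_gene_models(sim.SimGeneSpec(n_genes=20, seed=1))
target = ann.genes[2].gene_id
window = [sim.PeakSpec(gene_id=target, offset=1500, width=50, enrichment=15)]
tags = sim.simulate_clip_samples(ann, depth=800, n_samples=8,
                                 shared_peaks=window, seed=2)
tags = {s: collapse_by_start(df) for s, df in tags.items()}
peaks = call_peaks(tags, ann, alpha=0.01, min_bc=5)
print(peaks_to_frame(peaks)[["chrom", "start", "end", "gene_id",
                             "PH", "p_adj", "BC"]].to_string(index=False))

res = hypergeom_tail(OverlapSpec(N=14_737, K=8_681, n=538, k=500))
print(f"overlap p = {res.p:.2e}")
```

prints

```
chrom  start   end gene_id  PH        p_adj  BC
 chrS  31961 31963  g00002  20 1.176401e-10   7
overlap p = 6.54e-74
```

The one retained peak sits inside the implanted window of `g00002`
(gene starts at 31,390; the summit run 31,961–31,963 lies in the enriched
window at offsets 1,500–1,550 plus tag length): 20 of the gene's pooled
tags stack there, the Bonferroni-adjusted scan p-value is ~10⁻¹⁰, and
the site is supported by 7 of 8 samples. No spurious peak is called in the
other 19 genes. The second line is the exact log-space hypergeometric
tail for an overlap of 500 genes between a 538-gene list and an 8,681-gene
target set in a 14,737-gene universe.

The same stages are available from the shell:

```sh
clipscan sim genes --n-genes 50 --seed 1 --out sim/
clipscan sim clip --gtf sim/genes.gtf --depth 10000 --out sim/clip/ --seed 2
clipscan callpeaks --gtf sim/genes.gtf --tags sim/clip/tags_s1.bed ... --out peaks/
clipscan diff --counts counts.tsv --samples samples.tsv --out diff/
```

Every run writes a `manifest.json` (config, seed, version) sufficient to
reproduce its outputs exactly.

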