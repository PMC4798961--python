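import numpy as np
import pandas as pd
import pytest

from clipscan import simulate as sim
from clipscan.intervals import AnnotationBundle, GeneModel


@pytest.fixture(scope="session")
def small_annotation() -> AnnotationBundle:
    return sim.simulate_gene_models(sim.SimGeneSpec(n_genes=20, seed=1))


@pytest.fixture()
def toy_gene() -> GeneModel:
    # 10 kb gene: exon1 [0,1000) = 5'UTR+CDS, intron, exon2 [9000,10000) = CDS+3'UTR
    return GeneModel(
        gene_id="toy", chrom="chrT", strand="+", start=0, end=10_000,
        transcripts={"toy.t1": [(0, 1000), (9000, 10_000)]},
        cds=[(200, 1000), (9000, 9500)],
        utr5=[(0, 200)], utr3=[(9500, 10_000)],
    )


def make_tags(rows, sample="s1") -> pd.DataFrame:
    """rows: iterable of (chrom, start, end, strand)."""
    return pd.DataFrame(
        [(c, s, e, f"{sample}_t{i}", 0, st) for i, (c, s, e, st) in enumerate(rows)],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


def mc_scan_pvalue(n, L, w, k, reps, seed):
    """Monte-Carlo oracle: P(max tag starts in any width-w window >= k)."""
    rng = np.random.default_rng(seed)
    x = np.sort(rng.random((reps, n)) * L, axis=1)
    maxc = np.zeros(reps, dtype=int)
    for i in range(n):
        hi = (x < x[:, i:i + 1] + w).sum(axis=1)
        maxc = np.maximum(maxc, hi - i)
    return (maxc >= k).mean()
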