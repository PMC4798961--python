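"""Scan-statistic peak calling on pooled CLIP tags.

Tags from all samples are pooled per gene and clustered into maximal
coverage runs. Each cluster's PeakHeight (PH: the maximum tag coverage,
equivalently the number of tags over the summit run) is tested against the
uniform per-gene null with the scan statistic: n = unique tag starts in the
gene, L = unspliced gene span, w = sample-median tag length. Bonferroni
correction runs over all clusters tested transcriptome-wide; retained
peaks additionally require biological complexity (BC: number of samples
with at least one tag overlapping the peak) of at least ``min_bc``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import AnnotationBundle, GeneModel, ValidationError
from .scanstat import ScanNullModel, bonferroni, scan_pvalue
from .tags import _five_prime_start

__all__ = [
    "TagCluster", "Peak", "cluster_tags", "biological_complexity",
    "call_peaks", "assign_tags_to_genes", "peaks_to_frame",
    "scan_pvalue", "bonferroni", "ScanNullModel",
]


@dataclass
class TagCluster:
    """A maximal run of positions covered by >= 1 pooled tag."""

    gene_id: str
    start: int
    end: int
    peak_height: int
    summit_start: int      # leftmost maximal-coverage run
    summit_end: int
    n_tags: int


@dataclass
class Peak:
    """A retained binding site.

    ``start``/``end`` delimit the peak interval: the leftmost maximal run
    of positions attaining the PeakHeight; ``cluster_start``/``cluster_end``
    the full covered cluster around it.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    peak_height: int
    summit: int
    p_raw: float
    p_adj: float
    biological_complexity: int
    per_sample_ph: dict[str, int] = field(default_factory=dict)
    category: str | None = None
    norm_ph: float | None = None
    cluster_start: int | None = None
    cluster_end: int | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _sweep_clusters(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int, int, int, int, int]]:
    """Coverage sweep. Returns (start, end, ph, summit_start, summit_end, n_tags) per cluster."""
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    pos = np.concatenate([starts, ends])
    delta = np.concatenate([np.ones_like(starts), -np.ones_like(ends)])
    # +1 before -1 at identical positions keeps touching tags contiguous
    key = np.lexsort((-delta, pos))
    pos, delta = pos[key], delta[key]
    cov = np.cumsum(delta)
    out = []
    cl_start = None
    seg_start = None
    best_ph = 0
    best_run = None
    run_start = None
    n_tags = 0
    for i in range(len(pos)):
        p, d, c = pos[i], delta[i], cov[i]
        prev_c = cov[i - 1] if i else 0
        if prev_c == 0 and c > 0:
            cl_start, best_ph, best_run, run_start, n_tags = p, 0, None, None, 0
        if d > 0:
            n_tags += 1
        # segment [p, next_pos) has coverage c
        nxt = pos[i + 1] if i + 1 < len(pos) else p
        if c > 0 and nxt > p:
            if c > best_ph:
                best_ph, run_start = c, p
                best_run = (p, nxt)
            elif c == best_ph and best_run is not None and best_run[1] == p:
                best_run = (best_run[0], nxt)  # extend contiguous max run
        if c == 0 and prev_c > 0:
            out.append((int(cl_start), int(p), int(best_ph), int(best_run[0]),
                        int(best_run[1]), int(n_tags)))
    return out


def cluster_tags(tags: pd.DataFrame, gene: GeneModel) -> list[TagCluster]:
    """Cluster a gene's tags into maximal covered runs."""
    if tags.empty:
        return []
    if ((tags["start"].values < gene.start) | (tags["end"].values > gene.end)).any():
        raise ValidationError(f"tag outside span of gene {gene.gene_id}")
    clusters = _sweep_clusters(tags["start"].values.astype(np.int64),
                               tags["end"].values.astype(np.int64))
    return [TagCluster(gene.gene_id, s, e, ph, ss, se, nt)
            for s, e, ph, ss, se, nt in clusters]


def assign_tags_to_genes(
    tags: pd.DataFrame, annotation: AnnotationBundle, clip: bool = True
) -> pd.DataFrame:
    """Strand-aware assignment of tags to genes by 5' start position.

    Returns the tag frame with a ``gene_id`` column (unassigned tags get
    NaN). Tag intervals are clipped to the gene span when ``clip``.
    """
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for g in annotation:
        index.setdefault((g.chrom, g.strand), ([], [], []))
    for g in annotation:
        s, e, ids = index[(g.chrom, g.strand)]
        s.append(g.start), e.append(g.end), ids.append(g.gene_id)
    for key in index:
        s, e, ids = index[key]
        order = np.argsort(s)
        index[key] = (np.asarray(s)[order], np.asarray(e)[order],
                      [ids[i] for i in order])
    df = tags.copy()
    p5 = _five_prime_start(df)
    # the 5' coordinate of a minus-strand tag is its half-open end; query pos end-1
    qpos = np.where(df["strand"].values == "-", p5 - 1, p5)
    gene_ids = np.full(len(df), None, dtype=object)
    for (chrom, strand), (gs, ge, ids) in index.items():
        mask = (df["chrom"].values == chrom) & (df["strand"].values == strand)
        if not mask.any():
            continue
        pos = qpos[mask]
        j = np.searchsorted(gs, pos, side="right") - 1
        ok = (j >= 0) & (pos < ge[np.maximum(j, 0)])
        assigned = np.full(mask.sum(), None, dtype=object)
        assigned[ok] = [ids[i] for i in j[ok]]
        gene_ids[mask] = assigned
    df["gene_id"] = gene_ids
    if clip:
        bounds = {g.gene_id: (g.start, g.end) for g in annotation}
        lo = df["gene_id"].map(lambda g: bounds[g][0] if g else 0)
        hi = df["gene_id"].map(lambda g: bounds[g][1] if g else np.iinfo(np.int64).max)
        df["start"] = np.maximum(df["start"], lo)
        df["end"] = np.minimum(df["end"], hi)
    return df


def biological_complexity(
    peak_interval: tuple[int, int],
    per_sample_tags: dict[str, pd.DataFrame],
) -> int:
    """Number of samples with >= 1 tag overlapping the peak interval."""
    lo, hi = peak_interval
    bc = 0
    for df in per_sample_tags.values():
        if df.empty:
            continue
        if ((df["start"].values < hi) & (df["end"].values > lo)).any():
            bc += 1
    return bc


def call_peaks(
    tag_sets: dict[str, pd.DataFrame],
    annotation: AnnotationBundle,
    alpha: float = 0.01,
    min_bc: int = 5,
    tag_length: int | None = None,
    keep_all: bool = False,
) -> list[Peak]:
    """Pool tags, cluster, test each cluster, Bonferroni, apply BC filter.

    Retained peaks satisfy p_adj < alpha AND BC >= min_bc. With
    ``keep_all`` every tested cluster is returned (the BC / significance
    state can be recomputed from the fields).
    """
    if len(annotation) == 0:
        raise ValidationError("empty annotation")
    assigned = {
        s: assign_tags_to_genes(df, annotation) for s, df in tag_sets.items()
    }
    pooled = pd.concat(
        [df.assign(sample_id=s) for s, df in assigned.items()],
        ignore_index=True,
    ) if assigned else pd.DataFrame()
    if pooled.empty:
        return []
    pooled = pooled[pooled["gene_id"].notna()]
    if tag_length is None:
        tag_length = int(np.median(pooled["end"] - pooled["start"]))
    candidates: list[Peak] = []
    by_gene = dict(tuple(pooled.groupby("gene_id", sort=True)))
    for gene_id, gtags in by_gene.items():
        gene = annotation.get(gene_id)
        n = len(gtags)
        model = ScanNullModel(n, float(gene.span_length),
                              float(min(tag_length, gene.span_length)))
        sample_groups = dict(tuple(gtags.groupby("sample_id")))
        for cl in cluster_tags(gtags, gene):
            p_raw = scan_pvalue(model, min(cl.peak_height, n))
            per_sample = {
                s: int(((sdf["start"].values < cl.summit_end)
                        & (sdf["end"].values > cl.summit_start)).sum())
                for s, sdf in sample_groups.items()
            }
            bc = sum(1 for v in per_sample.values() if v > 0)
            candidates.append(Peak(
                gene_id=gene_id, chrom=gene.chrom, strand=gene.strand,
                start=cl.summit_start, end=cl.summit_end,
                peak_height=cl.peak_height, summit=cl.summit_start,
                p_raw=p_raw, p_adj=np.nan, biological_complexity=bc,
                per_sample_ph=per_sample,
                cluster_start=cl.start, cluster_end=cl.end,
            ))
    m = len(candidates)
    if m:
        adj = bonferroni([p.p_raw for p in candidates], m)
        for p, a in zip(candidates, adj):
            p.p_adj = float(a)
    if keep_all:
        return candidates
    return [p for p in candidates
            if p.p_adj < alpha and p.biological_complexity >= min_bc]


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    """BED6+ style table of peaks (PH, p_raw, p_adj, BC, category, norm_PH)."""
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "name": [f"{p.gene_id}_peak{i}" for i, p in enumerate(peaks)],
            "score": [p.peak_height for p in peaks],
            "strand": [p.strand for p in peaks],
            "gene_id": [p.gene_id for p in peaks],
            "summit": [p.summit for p in peaks],
            "PH": [p.peak_height for p in peaks],
            "p_raw": [p.p_raw for p in peaks],
            "p_adj": [p.p_adj for p in peaks],
            "BC": [p.biological_complexity for p in peaks],
            "category": [p.category for p in peaks],
            "norm_PH": [p.norm_ph for p in peaks],
        }
    )
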