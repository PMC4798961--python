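"""Binding quantification: peak annotation, normalization, target ranking.

PeakHeight is made comparable across experiments by converting to cpm
against the pooled CLIP library size, then divided by the gene's mean rpkm
so that highly expressed transcripts do not dominate: norm_PH =
(PH * 1e6 / total tags) / mean_rpkm. Per-gene binding is the sum of PH
over the gene's peaks; normalized binding the sum of norm_PH; 3'UTR and
intronic binding restrict the sum to peaks of that category. Top targets
are the N genes with the highest normalized binding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import AnnotationBundle, GeneModel, ValidationError
from .peaks import Peak

CATEGORY_PRECEDENCE = ["3'UTR", "5'UTR", "CDS", "noncoding_exon", "intron"]


def compute_expression(
    counts: pd.DataFrame,
    annotation: AnnotationBundle,
    cpm_threshold: float = 1.0,
    min_samples: int = 5,
    lib_sizes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene cpm/rpkm and the expressed flag.

    cpm = count * 1e6 / library size; rpkm = count * 1e9 / (library size *
    constitutive exon length); expressed = cpm > threshold in >=
    ``min_samples`` samples.
    """
    y = counts.values.astype(float)
    lib = y.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, float)
    if (lib <= 0).any():
        raise ValidationError("zero library size")
    cpm = y * 1e6 / lib
    lengths = np.array([
        annotation.get(g).constitutive_exon_length if g in annotation else np.nan
        for g in counts.index
    ])
    with np.errstate(invalid="ignore"):
        rpkm = cpm * 1e3 / lengths[:, None]
    out = pd.DataFrame(index=counts.index)
    for j, s in enumerate(counts.columns):
        out[f"cpm_{s}"] = cpm[:, j]
        out[f"rpkm_{s}"] = rpkm[:, j]
    out["mean_cpm"] = cpm.mean(axis=1)
    out["mean_rpkm"] = rpkm.mean(axis=1)
    out["expressed"] = (cpm > cpm_threshold).sum(axis=1) >= min_samples
    return out


def annotate_peak(peak: Peak, annotation: AnnotationBundle) -> str:
    """Category of a peak by its summit position, precedence
    3'UTR > 5'UTR > CDS > noncoding exon > intron."""
    if peak.gene_id not in annotation:
        return "other"
    gene = annotation.get(peak.gene_id)
    return _categorize_position(peak.summit, gene)


def _categorize_position(pos: int, gene: GeneModel) -> str:
    regions = {
        "3'UTR": gene.utr3,
        "5'UTR": gene.utr5,
        "CDS": gene.cds,
        "noncoding_exon": gene.noncoding_exons(),
        "intron": gene.introns,
    }
    for cat in CATEGORY_PRECEDENCE:
        if any(s <= pos < e for s, e in regions[cat]):
            return cat
    return "other"


def annotate_peaks(peaks: list[Peak], annotation: AnnotationBundle) -> list[Peak]:
    for p in peaks:
        p.category = annotate_peak(p, annotation)
    return peaks


def genomic_distribution(
    peaks: list[Peak],
    annotation: AnnotationBundle,
    normalize_by_length: bool = False,
) -> pd.Series:
    """Fraction of peaks per category; the normalized mode divides by total
    category length (per-nucleotide density) before rescaling to sum 1."""
    cats = pd.Series([p.category or "other" for p in peaks])
    frac = cats.value_counts(normalize=True)
    if not normalize_by_length:
        return frac
    lengths = {c: 0.0 for c in CATEGORY_PRECEDENCE}
    for g in annotation:
        lengths["3'UTR"] += sum(e - s for s, e in g.utr3)
        lengths["5'UTR"] += sum(e - s for s, e in g.utr5)
        lengths["CDS"] += sum(e - s for s, e in g.cds)
        lengths["noncoding_exon"] += sum(e - s for s, e in g.noncoding_exons())
        lengths["intron"] += sum(e - s for s, e in g.introns)
    dens = {}
    for cat, f in frac.items():
        L = lengths.get(cat, 0.0)
        if L <= 0:
            raise ValidationError(f"category {cat} has zero annotated length")
        dens[cat] = f / L
    out = pd.Series(dens)
    return out / out.sum()


def normalize_peak_heights(
    peaks: list[Peak],
    lib_sizes: pd.Series,
    expression: pd.DataFrame,
) -> list[Peak]:
    """norm_PH = (PH * 1e6 / pooled library size) / mean rpkm of the gene.

    Peaks on genes with rpkm 0 (or missing expression) keep norm_ph None
    and are excluded from rankings downstream.
    """
    total = float(lib_sizes.sum())
    if total <= 0:
        raise ValidationError("empty libraries")
    for p in peaks:
        ph_cpm = p.peak_height * 1e6 / total
        rpkm = (
            float(expression.loc[p.gene_id, "mean_rpkm"])
            if p.gene_id in expression.index else np.nan
        )
        p.norm_ph = ph_cpm / rpkm if np.isfinite(rpkm) and rpkm > 0 else None
    return peaks


def summarize_binding(peaks: list[Peak]) -> pd.DataFrame:
    """Per-gene binding summaries: sum of PH, sum of norm_PH, and the
    region-restricted (3'UTR / intron) normalized sums."""
    rows: dict[str, dict[str, float]] = {}
    for p in peaks:
        r = rows.setdefault(p.gene_id, {
            "binding": 0.0, "norm_binding": 0.0,
            "utr3_binding": 0.0, "intron_binding": 0.0, "n_peaks": 0,
        })
        r["binding"] += p.peak_height
        r["n_peaks"] += 1
        if p.norm_ph is not None:
            r["norm_binding"] += p.norm_ph
            if p.category == "3'UTR":
                r["utr3_binding"] += p.norm_ph
            elif p.category == "intron":
                r["intron_binding"] += p.norm_ph
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "gene_id"
    return df


def rank_top_targets(
    binding: pd.DataFrame, n_top: int = 1000, region: str = "all"
) -> pd.DataFrame:
    """Rank genes by normalized binding (optionally 3'UTR-restricted).

    Ties break by gene_id so the ranking is a deterministic total order.
    """
    col = {"all": "norm_binding", "3'UTR": "utr3_binding",
           "intron": "intron_binding"}[region]
    df = binding.sort_index().sort_values(col, ascending=False, kind="mergesort")
    df = df.copy()
    df["rank"] = np.arange(1, len(df) + 1)
    df["top_target"] = df["rank"] <= n_top
    return df


def interval_overlap(
    peaks: list[Peak], features: pd.DataFrame
) -> pd.DataFrame:
    """(peak, feature) pairs where the point feature lies inside the peak
    interval (half-open: start inclusive, end exclusive).

    ``features`` needs columns chrom, pos (and optionally name).
    """
    rows = []
    for i, p in enumerate(peaks):
        hit = features[(features["chrom"] == p.chrom)
                       & (features["pos"] >= p.start)
                       & (features["pos"] < p.end)]
        for fid, f in hit.iterrows():
            rows.append({
                "peak_index": i, "gene_id": p.gene_id,
                "feature_id": f.get("name", fid), "pos": int(f["pos"]),
            })
    return pd.DataFrame(rows, columns=["peak_index", "gene_id", "feature_id", "pos"])


def meta_exon_map(
    peaks: list[Peak],
    exons: pd.DataFrame,
    flank: int = 2500,
    bin_width: int = 50,
) -> pd.DataFrame:
    """Meta-exon binding map: aggregated norm_PH by summit distance from
    regulated-exon boundaries, split by the exon's direction of change.

    ``exons`` needs columns chrom, start, end, strand, direction (one of
    ``increased_inclusion``/``decreased_inclusion``). Distances are signed
    in transcript orientation (negative = upstream of the exon's 5'
    boundary, positive = downstream of its 3' boundary, 0 = inside) and
    binned at ``bin_width`` nt over +-``flank``.
    """
    edges = np.arange(-flank, flank + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    profiles = {d: np.zeros(len(centers))
                for d in ("increased_inclusion", "decreased_inclusion")}
    for _, ex in exons.iterrows():
        d = ex["direction"]
        if d not in profiles:
            continue
        for p in peaks:
            if p.chrom != ex["chrom"] or p.strand != ex["strand"] or p.norm_ph is None:
                continue
            if ex["strand"] == "+":
                five, three = ex["start"], ex["end"]
                if p.summit < five:
                    dist = p.summit - five
                elif p.summit >= three:
                    dist = p.summit - three + 1
                else:
                    dist = 0
            else:
                five, three = ex["end"], ex["start"]
                if p.summit >= five:
                    dist = five - p.summit - 1
                elif p.summit < three:
                    dist = three - p.summit
                else:
                    dist = 0
            if dist == 0 or abs(dist) > flank:
                continue
            b = int(np.searchsorted(edges, dist, side="right") - 1)
            if 0 <= b < len(centers):
                profiles[d][b] += p.norm_ph
    out = pd.DataFrame(profiles, index=pd.Index(centers, name="distance"))
    return out
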