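"""Y RNA binding analysis.

Y RNAs are ~100 nt structured non-coding RNAs with many dispersed genomic
copies; under stress an RNA-binding protein can be redistributed onto the
motif-bearing subset of them (sequestration). This module quantifies tags
per Y RNA (discarding tags that overlap more than one Y RNA under the
default unique-only policy), defines bound Y RNAs (tags in >= 2 samples),
tests motif enrichment among bound versus unbound Y RNAs, compares binding
between conditions with a paired one-sided Wilcoxon signed-rank test on
cpm-normalized counts, reports the per-sample fraction of the CLIP library
on Y RNAs, and splits subjects into high/low Y-binding groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import ValidationError
from .stats import MotifSpec, TestResult, fisher_exact, motif_scan, wilcoxon_paired


def count_tags_per_yrna(
    tag_sets: dict[str, pd.DataFrame],
    yrna_loci: pd.DataFrame,
    policy: str = "unique",
) -> pd.DataFrame:
    """Y RNA x sample tag-count table.

    A tag counts for a Y RNA iff its interval overlaps the locus. Under the
    ``unique`` policy, tags overlapping more than one Y RNA are discarded;
    under ``best-match`` they go to the overlapped Y RNA with the highest
    unique-tag count (ties to the lexicographically first id).

    ``yrna_loci`` needs columns yrna_id, chrom, start, end, strand.
    """
    if policy not in ("unique", "best-match"):
        raise ValidationError("policy must be 'unique' or 'best-match'")
    ids = list(yrna_loci["yrna_id"])
    table = pd.DataFrame(0, index=pd.Index(ids, name="yrna_id"),
                         columns=list(tag_sets))
    ambiguous: dict[str, list[tuple[list[str]]]] = {s: [] for s in tag_sets}
    for sample, tags in tag_sets.items():
        for _, t in tags.iterrows():
            hits = yrna_loci[
                (yrna_loci["chrom"] == t["chrom"])
                & (yrna_loci["strand"] == t["strand"])
                & (yrna_loci["start"] < t["end"])
                & (t["start"] < yrna_loci["end"])
            ]["yrna_id"].tolist()
            if len(hits) == 1:
                table.loc[hits[0], sample] += 1
            elif len(hits) > 1:
                ambiguous[sample].append(hits)
    if policy == "best-match":
        for sample, items in ambiguous.items():
            for hits in items:
                counts = table.loc[hits, sample]
                best = counts[counts == counts.max()].index.min()
                table.loc[best, sample] += 1
    return table


def define_bound(table: pd.DataFrame, min_samples: int = 2) -> pd.Series:
    """Bound Y RNAs: nonzero tag count in at least ``min_samples`` samples."""
    return ((table > 0).sum(axis=1) >= min_samples).rename("bound")


def motif_enrichment(
    sequences: pd.Series,
    bound: pd.Series,
    spec: MotifSpec | None = None,
) -> tuple[np.ndarray, TestResult, pd.Series]:
    """2x2 (bound/unbound x motif+/motif-) and one-sided Fisher p for motif
    enrichment among bound Y RNAs. Returns (table, result, motif flags)."""
    spec = spec or MotifSpec()
    motif = sequences.map(lambda s: len(motif_scan(s, spec)) > 0)
    bound = bound.reindex(sequences.index)
    a = int((bound & motif).sum())
    b = int((bound & ~motif).sum())
    c = int((~bound & motif).sum())
    d = int((~bound & ~motif).sum())
    table = np.array([[a, b], [c, d]])
    if bound.all() or (~bound).all() or motif.all() or (~motif).all():
        return table, TestResult("fisher", np.nan, 1.0, "greater",
                                 flags=["empty-stratum"]), motif.rename("motif")
    res = fisher_exact(table, sidedness="greater")
    return table, res, motif.rename("motif")


def compare_conditions(
    table: pd.DataFrame,
    condition,
    bound: pd.Series | None = None,
    lib_sizes: pd.Series | None = None,
    alternative: str = "greater",
) -> tuple[pd.DataFrame, TestResult]:
    """Condition-2 vs condition-1 binding change of (bound) Y RNAs.

    Counts are cpm-normalized against the *whole-library* sizes in
    ``lib_sizes`` (tags per sample across the genome, not the Y panel
    totals, which would absorb a genuine binding shift); without library
    sizes raw counts are compared. Per Y RNA the within-condition means are
    compared with a paired one-sided Wilcoxon signed-rank test
    (``greater``: binding increases in condition 2). Returns a per-Y frame
    (means and log2 fold change with pseudocount 0.5) and the test result.
    """
    cond = pd.Categorical(condition)
    if len(cond.categories) != 2:
        raise ValidationError("need exactly two conditions")
    if bound is not None:
        table = table.loc[bound.reindex(table.index).fillna(False).astype(bool)]
    y = table.values.astype(float)
    if lib_sizes is None:
        cpmv = y
    else:
        lib = lib_sizes.reindex(table.columns).values.astype(float)
        cpmv = y * 1e6 / lib
    g2 = np.asarray(cond == cond.categories[1])
    m1 = cpmv[:, ~g2].mean(axis=1)
    m2 = cpmv[:, g2].mean(axis=1)
    out = pd.DataFrame({
        f"mean_cpm_{cond.categories[0]}": m1,
        f"mean_cpm_{cond.categories[1]}": m2,
        "log2FC": np.log2((m2 + 0.5) / (m1 + 0.5)),
    }, index=table.index)
    res = wilcoxon_paired(m1, m2, alternative=alternative)
    if len(table) < 5:
        res.flags.append("fewer-than-5-bound-yrnas")
    return out, res


def library_fraction(
    tag_sets: dict[str, pd.DataFrame], yrna_loci: pd.DataFrame
) -> pd.Series:
    """Percentage of each sample's tags overlapping any Y RNA locus."""
    out = {}
    for sample, tags in tag_sets.items():
        total = len(tags)
        if total == 0:
            out[sample] = np.nan
            continue
        n_y = 0
        for _, t in tags.iterrows():
            hit = (
                (yrna_loci["chrom"] == t["chrom"])
                & (yrna_loci["strand"] == t["strand"])
                & (yrna_loci["start"] < t["end"])
                & (t["start"] < yrna_loci["end"])
            ).any()
            n_y += int(hit)
        out[sample] = 100.0 * n_y / total
    return pd.Series(out, name="yrna_library_pct")


def group_subjects(table: pd.DataFrame, n_groups: int = 2) -> pd.Series:
    """Split subjects into high/low Y RNA binding groups by 1-d 2-means on
    log10 total Y cpm. Deterministic: initialized at the extremes, subjects
    tie-broken by id; returns labels 'high'/'low' (or a single 'all' group
    when totals are identical)."""
    if table.shape[1] < 2:
        raise ValidationError("need >= 2 subjects")
    if n_groups != 2:
        raise ValidationError("only 2 groups supported")
    totals = pd.Series(table.values.sum(axis=0), index=table.columns, dtype=float)
    x = np.log10(totals + 1.0)
    if np.allclose(x, x.iloc[0]):
        return pd.Series("all", index=table.columns, name="group")
    lo, hi = float(x.min()), float(x.max())
    for _ in range(100):
        mid = (lo + hi) / 2
        assign = x.values > mid
        new_lo = x.values[~assign].mean() if (~assign).any() else lo
        new_hi = x.values[assign].mean() if assign.any() else hi
        if np.isclose(new_lo, lo) and np.isclose(new_hi, hi):
            break
        lo, hi = new_lo, new_hi
    labels = np.where(x.values > (lo + hi) / 2, "high", "low")
    return pd.Series(labels, index=table.columns, name="group")
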