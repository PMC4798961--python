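"""Cassette-exon inclusion quantification and differential splicing tests.

Each cassette exon is summarized by two inclusion junctions (upstream and
downstream of the exon) and one exclusion (skipping) junction per sample.
The per-sample inclusion evidence is the average of the two inclusion
junctions, inc = (J_up + J_dn)/2, so the binomial denominator stays on the
read scale; the inclusion fraction of a condition pools counts across its
samples, I = sum(inc) / sum(inc + J_skip).

The condition effect is tested per exon with a binomial GLM with logit
link (intercept + condition + optional batch) and a likelihood-ratio test
against the model without condition; delta-inclusion dI = I(cond1) -
I(cond2) is computed from pooled counts, not from fitted coefficients.
High-confidence events require FDR < 0.05 and |dI| >= 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glm import fit_binomial_glm
from .intervals import ValidationError
from .stats import qvalues


@dataclass
class SplicingCounts:
    """Aligned exon x sample junction-count matrices."""

    up: pd.DataFrame      # J_up inclusion junction
    down: pd.DataFrame    # J_dn inclusion junction
    skip: pd.DataFrame    # J_skip exclusion junction

    def __post_init__(self) -> None:
        for df in (self.down, self.skip):
            if not df.index.equals(self.up.index) or not df.columns.equals(self.up.columns):
                raise ValidationError("junction matrices must be aligned")
        for df in (self.up, self.down, self.skip):
            if (df.values < 0).any():
                raise ValidationError("negative junction counts")

    @property
    def samples(self) -> list[str]:
        return list(self.up.columns)

    @property
    def exon_ids(self) -> pd.Index:
        return self.up.index

    def inclusion_reads(self) -> pd.DataFrame:
        """Per-sample inclusion evidence inc = (J_up + J_dn)/2."""
        return (self.up + self.down) / 2.0

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "SplicingCounts":
        """Build from a long table with columns exon_id, sample, J_up, J_dn, J_skip."""
        need = {"exon_id", "sample", "J_up", "J_dn", "J_skip"}
        if not need <= set(table.columns):
            raise ValidationError(f"long table must have columns {sorted(need)}")
        up = table.pivot(index="exon_id", columns="sample", values="J_up")
        dn = table.pivot(index="exon_id", columns="sample", values="J_dn")
        sk = table.pivot(index="exon_id", columns="sample", values="J_skip")
        if up.isna().any().any():
            raise ValidationError("missing exon/sample combinations")
        return cls(up, dn, sk)


def _condition_mask(samples, condition) -> tuple[np.ndarray, list]:
    cond = pd.Categorical(condition)
    if len(cond.categories) != 2:
        raise ValidationError("splicing comparison needs exactly two conditions")
    if len(cond) != len(samples):
        raise ValidationError("condition labels must match samples")
    return np.asarray(cond == cond.categories[1]), list(cond.categories)


def inclusion_fraction(counts: SplicingCounts, condition) -> pd.DataFrame:
    """Pooled inclusion fraction I per condition; NaN where a condition has
    no junction reads at all (flagged undefined)."""
    inc = counts.inclusion_reads().values
    skip = counts.skip.values
    g2, levels = _condition_mask(counts.samples, condition)
    out = {}
    for lev, mask in zip(levels, (~g2, g2)):
        i_sum = inc[:, mask].sum(axis=1)
        s_sum = skip[:, mask].sum(axis=1)
        tot = i_sum + s_sum
        with np.errstate(invalid="ignore", divide="ignore"):
            out[lev] = np.where(tot > 0, i_sum / np.maximum(tot, 1e-300), np.nan)
    return pd.DataFrame(out, index=counts.exon_ids)


def junction_filter(
    counts: SplicingCounts,
    condition,
    lib_sizes: np.ndarray | None = None,
    min_norm_cov: float = 5.0,
) -> pd.Index:
    """Exons with library-size-normalized pooled coverage >= ``min_norm_cov``
    for *each* isoform (inclusion and skipping) in *each* condition.

    Counts are rescaled per sample to the mean library size before pooling.
    """
    inc = counts.inclusion_reads().values.astype(float)
    skip = counts.skip.values.astype(float)
    g2, _ = _condition_mask(counts.samples, condition)
    if lib_sizes is None:
        scale = np.ones(inc.shape[1])
    else:
        lib = np.asarray(lib_sizes, dtype=float)
        if (lib <= 0).any():
            raise ValidationError("zero library size")
        scale = lib.mean() / lib
    inc_n, skip_n = inc * scale, skip * scale
    keep = np.ones(inc.shape[0], dtype=bool)
    for mask in (~g2, g2):
        keep &= inc_n[:, mask].sum(axis=1) >= min_norm_cov
        keep &= skip_n[:, mask].sum(axis=1) >= min_norm_cov
    return counts.exon_ids[keep]


def splicing_lrt(
    counts: SplicingCounts,
    condition,
    batch=None,
    fdr_threshold: float = 0.05,
    di_threshold: float = 0.1,
) -> pd.DataFrame:
    """Binomial GLM LRT for a condition effect on exon inclusion.

    Returns per-exon I per condition, dI = I(cond1) - I(cond2), the LRT
    statistic, p (chi-square, 1 df), q-value FDR, a ``penalized`` flag for
    separated exons, and the significance call FDR < fdr AND |dI| >= di.
    """
    inc = np.rint(counts.inclusion_reads().values)  # round-half-even
    skip = counts.skip.values.astype(float)
    trials = inc + skip
    g2, levels = _condition_mask(counts.samples, condition)
    cols = [np.ones(len(g2)), g2.astype(float)]
    if batch is not None:
        b = pd.Categorical(batch)
        cols += [(b == lev).astype(float) for lev in b.categories[1:]]
    X_full = np.column_stack(cols)
    X_red = np.column_stack([cols[0]] + cols[2:])
    full = fit_binomial_glm(inc, trials, X_full)
    red = fit_binomial_glm(inc, trials, X_red)
    lrt = np.maximum(2.0 * (full.loglik - red.loglik), 0.0)
    p = sps.chi2.sf(lrt, 1)
    q, _ = qvalues(p)
    ifrac = inclusion_fraction(counts, condition)
    di = ifrac[levels[0]].values - ifrac[levels[1]].values
    res = pd.DataFrame(
        {
            f"I_{levels[0]}": ifrac[levels[0]].values,
            f"I_{levels[1]}": ifrac[levels[1]].values,
            "dI": di,
            "LRT": lrt,
            "p": p,
            "q": q,
            "penalized": full.penalized | red.penalized,
        },
        index=counts.exon_ids,
    )
    return classify_significant(res, fdr=fdr_threshold, di=di_threshold)


def classify_significant(
    results: pd.DataFrame, fdr: float = 0.05, di: float = 0.1
) -> pd.DataFrame:
    """Apply the two significance gates and attach a direction label."""
    out = results.copy()
    out["significant"] = (out["q"] < fdr) & (out["dI"].abs() >= di)
    out["direction"] = np.select(
        [out["significant"] & (out["dI"] > 0), out["significant"] & (out["dI"] < 0)],
        ["decreased_inclusion", "increased_inclusion"],
        default="ns",
    )
    return out


def associate_peaks_with_exons(
    exons: pd.DataFrame,
    peaks: pd.DataFrame,
    flank: int = 2500,
) -> pd.DataFrame:
    """Associate exons with intronic peak summits within +-flank of the exon.

    ``exons`` needs columns chrom, start, end, strand (exon body interval);
    ``peaks`` needs chrom, summit, strand. A peak is associated iff its
    summit lies in [start - flank, end + flank); the side label is in
    transcript orientation (a summit left of a minus-strand exon is
    ``downstream``).
    """
    rows = []
    for exon_id, ex in exons.iterrows():
        lo, hi = ex["start"] - flank, ex["end"] + flank
        cand = peaks[
            (peaks["chrom"] == ex["chrom"])
            & (peaks["strand"] == ex["strand"])
            & (peaks["summit"] >= lo)
            & (peaks["summit"] < hi)
        ]
        for pid, pk in cand.iterrows():
            if pk["summit"] < ex["start"]:
                side_genomic = "left"
            elif pk["summit"] >= ex["end"]:
                side_genomic = "right"
            else:
                side_genomic = "within"
            if side_genomic == "within":
                side = "within"
            elif ex["strand"] == "+":
                side = "upstream" if side_genomic == "left" else "downstream"
            else:
                side = "downstream" if side_genomic == "left" else "upstream"
            rows.append({"exon_id": exon_id, "peak_id": pid, "side": side})
    return pd.DataFrame(rows, columns=["exon_id", "peak_id", "side"])
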