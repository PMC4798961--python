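"""Synthetic data generators with the statistical structure the pipeline assumes.

Every generator is deterministic under its seed and emits a truth table
alongside the data so recovery tests need no re-derivation. The CLIP tag
generator draws tag starts uniformly over each gene span except inside
implanted enrichment windows (a window of width ``width`` and enrichment
``e`` receives start mass proportional to ``e * width`` against a
background mass of ``L - width``); junction counts are binomial with a
logit-scale linear predictor (condition effect + shared-batch Gaussian
offsets); gene counts are gamma-Poisson (negative binomial) with
controlled fold changes; the Y RNA panel controls the motif-bearing
fraction and a multiplicative condition-2 binding shift on motif-positive
Y RNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import AnnotationBundle, GeneModel, ValidationError
from .io import BED6_COLUMNS
from .splicing import SplicingCounts
from .stats import MotifSpec

_GENE_GAP = 1000
_MIN_EXON = 50
_MIN_INTRON = 60
_UTR5_FRACTION = 0.05


@dataclass(frozen=True)
class SimGeneSpec:
    n_genes: int = 50
    gene_length_range: tuple[int, int] = (2000, 20000)
    n_exons_range: tuple[int, int] = (2, 8)
    utr3_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValidationError("n_genes must be >= 0")
        if self.gene_length_range[0] < 300 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValidationError("gene lengths must be >= 300 nt and min <= max")
        if self.n_exons_range[0] < 2:
            raise ValidationError("need >= 2 exons so every gene has an intron")
        if not 0 < self.utr3_fraction < 0.9:
            raise ValidationError("utr3_fraction must be in (0, 0.9)")


@dataclass(frozen=True)
class PeakSpec:
    """An implanted rectangular enrichment window inside one gene."""

    gene_id: str
    offset: int
    width: int
    enrichment: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.offset < 0:
            raise ValidationError("peak window must have positive width and offset >= 0")
        if self.enrichment < 1:
            raise ValidationError("enrichment must be >= 1")


@dataclass(frozen=True)
class SpliceSimSpec:
    n_exons: int = 1000
    baseline_logit_mean: float = 0.0
    baseline_logit_sd: float = 1.0
    affected_fraction: float = 0.0
    effect_logit: float = 0.0
    batch_sd: float = 0.0
    depth_mean: float = 100.0
    n_per_group: int = 4
    n_batches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.affected_fraction <= 1:
            raise ValidationError("affected_fraction must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be > 0")


@dataclass(frozen=True)
class CountSimSpec:
    n_genes: int = 5000
    dispersion: float = 0.1
    de_fraction: float = 0.0
    logfc_sd: float = 1.0
    logfc_mean: float = 0.0
    lib_sizes: tuple[int, ...] = (10_000_000,) * 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if any(l <= 0 for l in self.lib_sizes):
            raise ValidationError("lib_sizes must be positive")


@dataclass(frozen=True)
class YRNASimSpec:
    n_yrna: int = 100
    length: int = 100
    motif_fraction: float = 0.5
    base_rate: float = 10.0
    shift: float = 4.0
    n_per_group: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.motif_fraction <= 1:
            raise ValidationError("motif_fraction must be in [0, 1]")
        if self.shift < 1:
            raise ValidationError("shift must be >= 1")


def _partition(total: int, parts: int, minimum: int, rng) -> list[int]:
    """Random composition of ``total`` into ``parts`` parts each >= minimum."""
    slack = total - parts * minimum
    if slack < 0:
        raise ValidationError("cannot partition length with these minima")
    if parts == 1:
        return [total]
    cuts = np.sort(rng.integers(0, slack + 1, size=parts - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [slack]]))
    return [minimum + int(s) for s in sizes]


def simulate_gene_models(spec: SimGeneSpec) -> AnnotationBundle:
    """Non-overlapping genes on one synthetic chromosome, each with exons,
    introns, a 5'UTR, a CDS and a terminal 3'UTR (strand-aware)."""
    rng = np.random.default_rng(spec.seed)
    genes = []
    cursor = _GENE_GAP
    for i in range(spec.n_genes):
        gid = f"g{i:05d}"
        length = int(rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exonic = int(length * rng.uniform(0.1, 0.4))
        exonic = max(2 * _MIN_EXON, min(exonic, length - _MIN_INTRON))
        max_exons = min(spec.n_exons_range[1], exonic // _MIN_EXON,
                        (length - exonic) // _MIN_INTRON + 1)
        max_exons = max(2, max_exons)
        lo = min(spec.n_exons_range[0], max_exons)
        n_exons = int(rng.integers(lo, max_exons + 1))
        exon_sizes = _partition(exonic, n_exons, _MIN_EXON, rng)
        intron_sizes = _partition(length - exonic, n_exons - 1, _MIN_INTRON, rng)
        start = cursor
        pos = start
        exons = []
        for j, esz in enumerate(exon_sizes):
            exons.append((pos, pos + esz))
            pos += esz
            if j < len(intron_sizes):
                pos += intron_sizes[j]
        end = pos
        # UTRs at the transcript ends, measured along the mRNA
        utr3_len = max(1, int(exonic * spec.utr3_fraction))
        utr5_len = max(1, int(exonic * _UTR5_FRACTION))
        mrna = exons if strand == "+" else exons[::-1]

        def take(n, from_end):
            order = mrna[::-1] if from_end else mrna
            out, left = [], n
            for s, e in order:
                if left <= 0:
                    break
                sz = min(e - s, left)
                out.append((e - sz, e) if from_end else (s, s + sz))
                left -= sz
            return out

        utr3 = take(utr3_len, from_end=(strand == "+"))
        utr5 = take(utr5_len, from_end=(strand == "-"))
        cds = []
        from .intervals import subtract_intervals
        for s, e in exons:
            cds.extend(subtract_intervals((s, e), utr3 + utr5))
        genes.append(GeneModel(
            gene_id=gid, chrom="chrS", strand=strand, start=start, end=end,
            transcripts={f"{gid}.t1": exons}, cds=cds, utr5=utr5, utr3=utr3,
        ))
        cursor = end + _GENE_GAP
    return AnnotationBundle(genes=genes)


def simulate_clip_sample(
    models: AnnotationBundle,
    depth: int,
    peaks: list[PeakSpec] | None = None,
    tag_length: int = 50,
    seed: int = 0,
    sample_id: str = "s1",
) -> pd.DataFrame:
    """One sample of CLIP tags (BED6 frame).

    Tag starts are uniform over each gene span except inside implanted
    windows; a window with enrichment e receives start mass e*width against
    the gene's background mass L - width. Expected depth is split across
    genes proportionally to span length.
    """
    if depth < 0:
        raise ValidationError("depth must be >= 0")
    peaks = peaks or []
    by_gene: dict[str, list[PeakSpec]] = {}
    for ps in peaks:
        if ps.gene_id not in models:
            raise ValidationError(f"peak references unknown gene {ps.gene_id}")
        g = models.get(ps.gene_id)
        if ps.offset + ps.width > g.span_length:
            raise ValidationError(f"peak outside gene {ps.gene_id}")
        by_gene.setdefault(ps.gene_id, []).append(ps)
    rng = np.random.default_rng(seed)
    spans = np.array([g.span_length for g in models], dtype=float)
    if depth == 0 or len(models) == 0 or spans.sum() == 0:
        from .io import empty_tags
        return empty_tags()
    per_gene = rng.multinomial(depth, spans / spans.sum())
    rows = []
    tag_no = 0
    for g, n in zip(models, per_gene):
        if n == 0:
            continue
        L = g.span_length
        gps = sorted(by_gene.get(g.gene_id, []), key=lambda p: p.offset)
        # piecewise-constant start density: background 1, window e
        bounds, weights = [], []
        cur = 0
        for ps in gps:
            if ps.offset > cur:
                bounds.append((cur, ps.offset)); weights.append(ps.offset - cur)
            bounds.append((ps.offset, ps.offset + ps.width))
            weights.append(ps.enrichment * ps.width)
            cur = ps.offset + ps.width
        if cur < L:
            bounds.append((cur, L)); weights.append(L - cur)
        w = np.array(weights, dtype=float)
        seg = rng.choice(len(w), size=n, p=w / w.sum())
        u = rng.random(n)
        for si, ui in zip(seg, u):
            s0, e0 = bounds[si]
            start = g.start + int(s0 + ui * (e0 - s0))
            end = min(start + tag_length, g.end)
            rows.append((g.chrom, start, end, f"{sample_id}_t{tag_no}", 0, g.strand))
            tag_no += 1
    df = pd.DataFrame(rows, columns=BED6_COLUMNS)
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def simulate_clip_samples(
    models: AnnotationBundle,
    depth: int,
    n_samples: int = 8,
    peaks_by_sample: dict[str, list[PeakSpec]] | None = None,
    shared_peaks: list[PeakSpec] | None = None,
    tag_length: int = 50,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """A multi-sample CLIP experiment; ``shared_peaks`` go into every sample,
    ``peaks_by_sample`` adds per-sample windows (presence design for BC)."""
    out = {}
    rng = np.random.default_rng(seed)
    for i in range(n_samples):
        sid = f"s{i + 1}"
        pk = list(shared_peaks or []) + list((peaks_by_sample or {}).get(sid, []))
        out[sid] = simulate_clip_sample(
            models, depth, pk, tag_length,
            seed=int(rng.integers(0, 2**31 - 1)), sample_id=sid,
        )
    return out


def simulate_splicing_counts(
    spec: SpliceSimSpec,
) -> tuple[SplicingCounts, pd.DataFrame, pd.DataFrame]:
    """Cassette-exon junction counts with a logit-scale condition effect.

    Returns (counts, sample sheet with condition/batch, truth table with
    per-exon affected flag, baseline, effect and the implied true dI).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_exons
    exon_ids = [f"ex{i:05d}" for i in range(n)]
    samples, conds, batches = [], [], []
    # batches are deliberately imbalanced across conditions (3:1 at 4v4):
    # a balanced design would cancel batch offsets out of the condition
    # contrast and make the covariate vacuous
    k = max(1, spec.n_per_group // 4)
    for c in (1, 2):
        for j in range(spec.n_per_group):
            samples.append(f"c{c}_s{j + 1}")
            conds.append(f"cond{c}")
            if c == 1:
                batches.append("b1" if j < spec.n_per_group - k else "b2")
            else:
                batches.append("b1" if j < k else "b2")
    baseline = rng.normal(spec.baseline_logit_mean, spec.baseline_logit_sd, n)
    affected = rng.random(n) < spec.affected_fraction
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    effect = np.where(affected, spec.effect_logit * sign, 0.0)
    batch_eff = rng.normal(0.0, spec.batch_sd, size=(n, spec.n_batches))
    up = np.zeros((n, len(samples)), dtype=np.int64)
    dn = np.zeros_like(up)
    sk = np.zeros_like(up)
    for j, (cond, bat) in enumerate(zip(conds, batches)):
        eta = baseline + (effect if cond == "cond2" else 0.0)
        eta = eta + batch_eff[:, int(bat[1:]) - 1]
        pi = 1.0 / (1.0 + np.exp(-eta))
        total = rng.poisson(spec.depth_mean, n)
        n_inc = rng.binomial(total, pi)
        j_up = rng.binomial(2 * n_inc, 0.5)
        up[:, j] = j_up
        dn[:, j] = 2 * n_inc - j_up
        sk[:, j] = total - n_inc
    idx = pd.Index(exon_ids, name="exon_id")
    counts = SplicingCounts(
        pd.DataFrame(up, index=idx, columns=samples),
        pd.DataFrame(dn, index=idx, columns=samples),
        pd.DataFrame(sk, index=idx, columns=samples),
    )
    sheet = pd.DataFrame({"sample": samples, "condition": conds, "batch": batches})
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731
    truth = pd.DataFrame({
        "affected": affected,
        "baseline_logit": baseline,
        "effect_logit": effect,
        "true_dI": expit(baseline) - expit(baseline + effect),
    }, index=idx)
    return counts, sheet, truth


def simulate_expression_counts(
    spec: CountSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene x sample NB counts: mean = libsize * rel-abundance * 2^(logFC * group2).

    Returns (counts, sample sheet, truth with is_de and log2fc).
    """
    rng = np.random.default_rng(spec.seed)
    n, S = spec.n_genes, len(spec.lib_sizes)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")
    rel = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    rel /= rel.sum()
    is_de = rng.random(n) < spec.de_fraction
    log2fc = np.where(is_de, rng.normal(spec.logfc_mean, spec.logfc_sd, n), 0.0)
    half = S // 2
    group2 = np.arange(S) >= half
    counts = np.zeros((n, S), dtype=np.int64)
    for j in range(S):
        mu = spec.lib_sizes[j] * rel * np.where(group2[j], 2.0 ** log2fc, 1.0)
        if spec.dispersion < 1e-12:
            counts[:, j] = rng.poisson(mu)
        else:
            shape = 1.0 / spec.dispersion
            lam = rng.gamma(shape, mu / shape)
            counts[:, j] = rng.poisson(lam)
    samples = [f"{'B' if group2[j] else 'A'}_s{j + 1}" for j in range(S)]
    df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    sheet = pd.DataFrame({
        "sample": samples,
        "condition": np.where(group2, "condB", "condA"),
        "batch": [f"b{j % 2 + 1}" for j in range(S)],
    })
    truth = pd.DataFrame({"is_de": is_de, "log2fc": log2fc}, index=gene_ids)
    return df, sheet, truth


_BASES = np.array(list("ACGT"))


def simulate_yrna_panel(
    spec: YRNASimSpec, motif: MotifSpec | None = None
) -> tuple[pd.Series, pd.DataFrame, pd.Series, pd.DataFrame]:
    """A Y RNA panel: sequences, tag-count table, condition labels, truth.

    Motif-positive Y RNAs carry >= 1 accepted motif k-mer; motif-negative
    sequences carry none (rejection-sampled). Motif-positive Y RNAs get a
    ``shift``-fold Poisson rate increase in condition 2.
    """
    motif = motif or MotifSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_yrna
    ids = pd.Index([f"Y{i:04d}" for i in range(n)], name="yrna_id")
    n_pos = int(round(spec.motif_fraction * n))
    has_motif = np.zeros(n, dtype=bool)
    has_motif[:n_pos] = True
    kmers = sorted(motif.accepted_kmers())
    from .stats import motif_scan

    seqs = []
    for i in range(n):
        while True:
            s = "".join(rng.choice(_BASES, size=spec.length))
            if not motif_scan(s, motif):
                break
        if has_motif[i]:
            kmer = kmers[int(rng.integers(0, len(kmers)))]
            pos = int(rng.integers(0, spec.length - motif.length + 1))
            s = s[:pos] + kmer + s[pos + motif.length:]
        seqs.append(s)
    sequences = pd.Series(seqs, index=ids, name="sequence")
    samples, conds = [], []
    for c in (1, 2):
        for j in range(spec.n_per_group):
            samples.append(f"c{c}_s{j + 1}")
            conds.append(f"cond{c}")
    rates = np.empty((n, len(samples)))
    for j, c in enumerate(conds):
        boost = np.where(has_motif & (c == "cond2"), spec.shift, 1.0)
        rates[:, j] = spec.base_rate * boost
    table = pd.DataFrame(rng.poisson(rates), index=ids, columns=samples)
    truth = pd.DataFrame({"motif": has_motif,
                          "shifted": has_motif & (spec.shift > 1)}, index=ids)
    return sequences, table, pd.Series(conds, index=samples, name="condition"), truth


def write_yrna_fasta(sequences: pd.Series, path) -> None:
    with open(path, "w") as fh:
        for yid, seq in sequences.items():
            fh.write(f">{yid}\n{seq}\n")
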