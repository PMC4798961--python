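"""Readers and writers for the standard formats the pipeline touches.

GTF (1-based closed) for gene models, BED6 (0-based half-open) for CLIP
tags, TSV with a header row for count matrices, JSON for run manifests.
Internal coordinates are uniformly 0-based half-open; the +/-1 conversion
happens only here.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .intervals import AnnotationBundle, GeneModel, ValidationError

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

_GTF_FEATURE_MAP = {
    "five_prime_utr": "utr5",
    "three_prime_utr": "utr3",
    "5UTR": "utr5",
    "3UTR": "utr3",
}


def read_annotation(path: str | Path) -> AnnotationBundle:
    """Parse a GTF file into an :class:`AnnotationBundle`.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Introns and constitutive exons are derived, not read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: dict[str, GeneModel] = {}
    for feat in db.all_features(order_by=("seqid", "start")):
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ValidationError(f"feature without gene_id at {feat.seqid}:{feat.start}")
        start0, end0 = feat.start - 1, feat.end  # GTF is 1-based closed
        if end0 <= start0:
            raise ValidationError(f"gene {gid}: end < start in GTF")
        if feat.featuretype == "gene":
            if gid in genes:
                g = genes[gid]
                g.start, g.end = min(g.start, start0), max(g.end, end0)
            else:
                genes[gid] = GeneModel(
                    gene_id=gid, chrom=feat.seqid, strand=feat.strand,
                    start=start0, end=end0,
                )
            continue
        if gid not in genes:
            # gene line absent: create a stub, span fixed up at the end
            genes[gid] = GeneModel(
                gene_id=gid, chrom=feat.seqid, strand=feat.strand,
                start=start0, end=end0,
            )
        g = genes[gid]
        if feat.featuretype == "exon":
            tid = feat.attributes.get("transcript_id", [gid])[0]
            g.transcripts.setdefault(tid, []).append((start0, end0))
        elif feat.featuretype == "CDS":
            g.cds.append((start0, end0))
        elif feat.featuretype in _GTF_FEATURE_MAP:
            getattr(g, _GTF_FEATURE_MAP[feat.featuretype]).append((start0, end0))
    for g in genes.values():
        if g.transcripts:
            lo = min(s for ivs in g.transcripts.values() for s, _ in ivs)
            hi = max(e for ivs in g.transcripts.values() for _, e in ivs)
            g.start, g.end = min(g.start, lo), max(g.end, hi)
    return AnnotationBundle(genes=list(genes.values()))


def _validate_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValidationError(f"{path}:{lineno}: malformed GTF line ({len(fields)} fields)")
            try:
                s, e = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if e < s:
                raise ValidationError(f"{path}:{lineno}: end < start")


def write_annotation(bundle: AnnotationBundle, path: str | Path, source: str = "clipscan") -> None:
    """Write gene models as GTF (gene/exon/CDS/UTR features)."""
    lines = []

    def fmt(g, ftype, s, e, tid=None):
        attrs = f'gene_id "{g.gene_id}";'
        if tid is not None:
            attrs += f' transcript_id "{tid}";'
        return (
            f"{g.chrom}\t{source}\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}"
        )

    for g in bundle:
        lines.append(fmt(g, "gene", g.start, g.end))
        for tid in sorted(g.transcripts):
            for s, e in sorted(g.transcripts[tid]):
                lines.append(fmt(g, "exon", s, e, tid))
        for s, e in sorted(g.cds):
            lines.append(fmt(g, "CDS", s, e))
        for s, e in sorted(g.utr5):
            lines.append(fmt(g, "five_prime_utr", s, e))
        for s, e in sorted(g.utr3):
            lines.append(fmt(g, "three_prime_utr", s, e))
    Path(path).write_text("\n".join(lines) + "\n")


def read_tags(path: str | Path) -> pd.DataFrame:
    """Read a BED6 tag file into a DataFrame with canonical column names."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=BED6_COLUMNS, comment="#",
            dtype={"chrom": str, "name": str, "strand": str},
        )
    except pd.errors.EmptyDataError:
        return empty_tags()
    if df.empty:
        return empty_tags()
    for col in ("start", "end"):
        if not np.issubdtype(df[col].dtype, np.integer):
            raise ValidationError(f"{path}: non-integer coordinates in column {col!r}")
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ValidationError(f"{path}: invalid BED intervals")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError(f"{path}: invalid strand field")
    return df.reset_index(drop=True)


def empty_tags() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "name": pd.Series(dtype=str),
            "score": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
        }
    )


def write_tags(tags: pd.DataFrame, path: str | Path) -> None:
    tags.to_csv(path, sep="\t", header=False, index=False, columns=BED6_COLUMNS)


def canonical_sort_tags(tags: pd.DataFrame) -> pd.DataFrame:
    return tags.sort_values(
        ["chrom", "start", "end", "strand", "name"], kind="mergesort"
    ).reset_index(drop=True)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a feature×sample integer count matrix from TSV (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate feature ids")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValidationError(f"{path}: non-numeric column {col!r}")
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return df


def write_counts(matrix: pd.DataFrame, path: str | Path) -> None:
    if (matrix.values < 0).any():
        raise ValidationError("negative counts")
    matrix.to_csv(path, sep="\t")


def write_manifest(path: str | Path, config: dict, seed: int | None = None) -> None:
    """Machine-readable record of a run: config, seed, package version."""
    from . import __version__

    payload = {"package": "clipscan", "version": __version__, "seed": seed, "config": config}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
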