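"""CLIP read and tag preprocessing.

Raw reads carry a degenerate barcode (random-mer linker) at the 5' end
that marks independent ligation events: reads identical over the *whole*
sequence, barcode included, are PCR duplicates and collapse to one
representative. After mapping, tags with the same 5'-most genomic start
position within a sample collapse to one unique tag (the crosslink site
determines the start; length differences reflect digestion, not
independent binding events).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import ValidationError
from .io import BED6_COLUMNS


@dataclass(frozen=True)
class RawRead:
    sequence: str
    qualities: tuple[int, ...]
    barcode_len: int = 0

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValidationError("qualities must match sequence length")
        if self.barcode_len >= len(self.sequence):
            raise ValidationError("barcode_len must be < read length")


def filter_reads_by_quality(reads: list[RawRead], min_q: int = 20) -> list[RawRead]:
    """Keep reads whose every degenerate-linker base scores >= min_q and whose
    remaining bases average >= min_q."""
    kept = []
    for r in reads:
        if not r.qualities:
            raise ValidationError("read without qualities")
        q = np.asarray(r.qualities)
        bc, rest = q[: r.barcode_len], q[r.barcode_len:]
        if bc.size and bc.min() < min_q:
            continue
        if rest.size and rest.mean() < min_q:
            continue
        kept.append(r)
    return kept


def collapse_exact_sequences(reads: list[RawRead]) -> tuple[list[RawRead], int]:
    """One representative per distinct full sequence (barcode included).

    Returns (kept reads, number of PCR duplicates removed). Reads differing
    only in the degenerate barcode are independent events and are NOT
    collapsed, because the barcode is part of the sequence.
    """
    seen: dict[str, RawRead] = {}
    for r in reads:
        seen.setdefault(r.sequence, r)
    return list(seen.values()), len(reads) - len(seen)


def _five_prime_start(tags: pd.DataFrame) -> np.ndarray:
    """5'-most genomic coordinate of each tag: start on +, end on -."""
    return np.where(tags["strand"].values == "+", tags["start"].values, tags["end"].values)


def collapse_by_start(tags: pd.DataFrame) -> pd.DataFrame:
    """Unique tags: one per (chrom, strand, 5' start) within a sample.

    Input/output are BED6 frames; the first occurrence in canonical sort
    order is kept, so the result is deterministic and idempotent.
    """
    if tags.empty:
        return tags.copy()
    df = tags.copy()
    df["_p5"] = _five_prime_start(df)
    df = df.sort_values(
        ["chrom", "strand", "_p5", "start", "end", "name"], kind="mergesort"
    )
    df = df.drop_duplicates(subset=["chrom", "strand", "_p5"], keep="first")
    return df.drop(columns="_p5").reset_index(drop=True)[BED6_COLUMNS]


def library_sizes(tag_sets: dict[str, pd.DataFrame]) -> pd.Series:
    """Unique-tag count per sample (tags assumed already collapsed)."""
    return pd.Series({s: len(df) for s, df in tag_sets.items()}, name="library_size")
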