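"""Trimming and tailing of reads at the 3' extremity of the 5' cleavage fragment.

After RISC slicing, the 5' cleavage fragment's new 3' end is a substrate for
exonucleolytic nibbling (trimming) and non-templated nucleotide addition
(tailing).  Reads deriving from the fragment terminus therefore show
heterogeneous 3' ends.  This module selects reads covering the terminus by an
exact sequence anchor - by default the 10-nt of reference sequence occupying
fragment-local positions 11-20 (leaving the terminal 10 nt, where trimming and
tailing live, free to vary) - and classifies each as (n_trimmed, n_tailed):

* ``n_trimmed``: reference nucleotides missing between the read's last
  templated base and the annotated fragment terminus;
* ``n_tailed``: read 3' nucleotides beyond the last templated base
  (soft-clipped by the aligner, hence non-templated), with the tail sequence
  reported in RNA alphabet.

Reads mapping antisense to the 5' fragment are excluded: the fragment
extremity is a property of the sense strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .coordinates import CleavageSite

__all__ = [
    "TrimTailCall",
    "select_cf_terminal_reads",
    "classify_trim_tail",
    "trim_tail_table",
]

_TO_RNA = str.maketrans("ACGTacgt", "ACGUACGU")


@dataclass
class TrimTailCall:
    read_id: str
    n_trimmed: int
    n_tailed: int
    tail_seq: str = ""
    readthrough: bool = False  # templated alignment extends past the CF end


def _anchor(transcript_seq: str, site: CleavageSite, anchor_len: int) -> str:
    """Reference anchor: ``anchor_len`` nt ending ``anchor_len`` nt before the
    fragment terminus (fragment-local positions 11-20 for the default 10)."""
    cs = site.cs
    start = cs - 2 * anchor_len
    if start < 0:
        raise ValueError(
            f"5' cleavage fragment shorter than {2 * anchor_len} nt: "
            "anchor undefined"
        )
    return transcript_seq[start : cs - anchor_len]


def select_cf_terminal_reads(
    reads: Iterable,
    site: CleavageSite,
    transcript_seq: str,
    *,
    anchor_len: int = 10,
) -> list:
    """Keep sense reads containing an exact match to the terminal anchor.

    ``transcript_seq`` is the spliced transcript sequence (DNA or RNA
    alphabet).  Matching is exact; one mismatch inside the anchor rejects the
    read.
    """
    anchor = _anchor(transcript_seq.upper().translate(_TO_RNA), site, anchor_len)
    kept = []
    for read in reads:
        if not read.sense:
            continue
        seq = _read_rna_seq(read, transcript_seq)
        if anchor in seq:
            kept.append(read)
    return kept


def _read_rna_seq(read, transcript_seq: str) -> str:
    """Read sequence in transcript orientation, RNA alphabet.

    Falls back to reconstructing the templated part from the transcript
    sequence when the record carries no explicit sequence (simulated reads).
    """
    seq = getattr(read, "seq", "")
    if not seq:
        seq = (
            transcript_seq[read.tstart : read.tend]
            + getattr(read, "soft3", "")
        )
    return seq.upper().translate(_TO_RNA)


def classify_trim_tail(
    read,
    site: CleavageSite,
    transcript_seq: str | None = None,
) -> TrimTailCall:
    """Classify one terminal read from its coordinates and clip structure.

    n_trimmed is how far the last templated base falls short of the fragment
    terminus (floored at 0); n_tailed is the number of 3' soft-clipped bases.
    A read whose templated alignment extends beyond the fragment end is
    flagged as readthrough and excluded from dot-plot tallies.
    """
    cs = site.cs
    last_templated = read.tend - 1
    cf_end = cs - 1
    n_trimmed = max(0, cf_end - last_templated)
    tail = getattr(read, "soft3", "")
    readthrough = last_templated > cf_end
    return TrimTailCall(
        read_id=read.read_id,
        n_trimmed=int(n_trimmed),
        n_tailed=len(tail),
        tail_seq=tail.upper().translate(_TO_RNA),
        readthrough=readthrough,
    )


def trim_tail_table(
    reads: Sequence,
    site: CleavageSite,
    transcript_seq: str,
    *,
    anchor_len: int = 10,
    target_id: str = "",
    genotype: str = "",
) -> pd.DataFrame:
    """Dot-plot table: read count per (n_trimmed, n_tailed) cell.

    Applies :func:`select_cf_terminal_reads` then
    :func:`classify_trim_tail`; readthrough reads are dropped from the
    table (they carry an intact templated continuation, not a remodelled
    fragment end).
    """
    kept = select_cf_terminal_reads(
        reads, site, transcript_seq, anchor_len=anchor_len
    )
    cells: Counter = Counter()
    for read in kept:
        call = classify_trim_tail(read, site, transcript_seq)
        if call.readthrough:
            continue
        cells[(call.n_trimmed, call.n_tailed)] += 1
    rows = [
        {"target": target_id or site.transcript_id, "genotype": genotype,
         "n_trimmed": k[0], "n_tailed": k[1], "read_count": v}
        for k, v in sorted(cells.items())
    ]
    return pd.DataFrame(
        rows, columns=["target", "genotype", "n_trimmed", "n_tailed", "read_count"]
    )
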