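"""Strand-aware genomic/transcript coordinate conversion and cleavage-site anchoring.

A :class:`TranscriptModel` is an ordered exon chain on a chromosome; transcript
coordinates are 0-based and increase 5'->3' along the mature (spliced) RNA, so
on the minus strand transcript position 0 is the genomically *rightmost*
exonic base.  A :class:`CleavageSite` marks the position where a miRNA-loaded
RISC slices the transcript: ``cs`` is the transcript coordinate of the first
nucleotide of the 3' cleavage fragment, i.e. the 5' fragment occupies
``[0, cs)`` and the 3' fragment ``[cs, length)``.

All internal intervals are 0-based half-open; GFF3 I/O converts from the
1-based closed convention at the boundary.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TranscriptModel",
    "CleavageSite",
    "AlignedRead",
    "genomic_to_transcript",
    "transcript_to_genomic",
    "project_span",
    "signed_distance",
    "spliced_sequence",
    "anchor_alignments",
    "read_gff3",
    "write_gff3",
    "read_cleavage_sites",
]


class NotExonicError(ValueError):
    """Raised when a genomic position does not fall inside any exon."""


@dataclass(frozen=True)
class TranscriptModel:
    """Exon chain of one transcript isoform.

    ``exons`` are genomic ``(start, end)`` intervals, 0-based half-open,
    non-overlapping and sorted by genomic start regardless of strand.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gene_id: str = ""
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if end <= start:
                raise ValueError(f"empty exon ({start}, {end}) in {self.id}")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"overlapping exons in {self.id}")
            prev_end = end

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def genomic_start(self) -> int:
        return self.exons[0][0]

    @property
    def genomic_end(self) -> int:
        return self.exons[-1][1]

    def _cumlens(self) -> list[int]:
        cum, total = [], 0
        for s, e in self.exons:
            cum.append(total)
            total += e - s
        return cum


@dataclass(frozen=True)
class CleavageSite:
    """miRNA-guided slice position on a transcript.

    ``cs`` indexes the first nucleotide of the 3' cleavage fragment (0-based
    transcript coordinate).  The last nucleotide of the 5' fragment is
    therefore ``cs - 1``.
    """

    transcript_id: str
    cs: int
    trigger_mirna: str = ""
    gene_id: str = ""

    def validate(self, model: TranscriptModel) -> None:
        if not 0 < self.cs < model.spliced_length:
            raise ValueError(
                f"cleavage site {self.cs} outside (0, {model.spliced_length}) "
                f"for transcript {model.id}"
            )


def genomic_to_transcript(g: int, model: TranscriptModel) -> int:
    """Convert an exonic genomic position to a transcript coordinate.

    Raises :class:`NotExonicError` for intronic/intergenic positions.
    """
    plus_coord = None
    cum = 0
    for start, end in model.exons:
        if start <= g < end:
            plus_coord = cum + (g - start)
            break
        cum += end - start
    if plus_coord is None:
        raise NotExonicError(f"position {g} not exonic in {model.id}")
    if model.strand == "+":
        return plus_coord
    return model.spliced_length - 1 - plus_coord


def transcript_to_genomic(t: int, model: TranscriptModel) -> int:
    """Inverse of :func:`genomic_to_transcript`."""
    n = model.spliced_length
    if not 0 <= t < n:
        raise ValueError(f"transcript position {t} outside [0, {n}) for {model.id}")
    plus_coord = t if model.strand == "+" else n - 1 - t
    cum = 0
    for start, end in model.exons:
        length = end - start
        if plus_coord < cum + length:
            return start + (plus_coord - cum)
        cum += length
    raise AssertionError("unreachable")


def project_span(
    g_start: int, g_end: int, model: TranscriptModel
) -> tuple[int, int] | None:
    """Project a genomic interval onto spliced transcript coordinates.

    Returns the 0-based half-open transcript interval if every base of
    ``[g_start, g_end)`` is exonic (the interval may cross introns: the
    projection is through the spliced transcript).  Returns ``None`` when the
    span is partially exonic or entirely outside the transcript; such reads
    are dropped by callers with a logged count.
    """
    if g_end <= g_start:
        raise ValueError("empty genomic span")
    try:
        a = genomic_to_transcript(g_start, model)
        b = genomic_to_transcript(g_end - 1, model)
    except NotExonicError:  # endpoint in an intron or outside the model
        return None
    tpos = []
    for s, e in model.exons:
        for g in range(max(s, g_start), min(e, g_end)):
            tpos.append(genomic_to_transcript(g, model))
    lo, hi = min(tpos), max(tpos)
    if hi - lo + 1 != len(tpos) or {a, b} - {lo, hi}:
        return None  # exonic bases do not form one contiguous spliced run
    return lo, hi + 1


def spliced_sequence(model: TranscriptModel, genome: dict[str, str]) -> str:
    """Mature transcript sequence (5'->3', DNA alphabet) from a genome dict."""
    plus = "".join(genome[model.chrom][s:e] for s, e in model.exons)
    if model.strand == "+":
        return plus
    return plus.translate(_DNA_COMP)[::-1]


def signed_distance(read_position: int, site: CleavageSite) -> int:
    """Signed distance of a transcript position from the cleavage site.

    The first nucleotide of the 3' cleavage fragment maps to 0, the last
    nucleotide of the 5' fragment to -1.
    """
    return read_position - site.cs


# ---------------------------------------------------------------------------
# Anchoring alignments to transcripts
# ---------------------------------------------------------------------------


@dataclass
class AlignedRead:
    """One small-RNA alignment projected into transcript space.

    ``tstart``/``tend`` delimit the templated (matched) portion, 0-based
    half-open in transcript coordinates.  ``sense`` is True when the read's
    5'->3' direction equals the transcript's.  ``soft5``/``soft3`` are
    soft-clipped bases at the read's 5'/3' ends in read orientation; ``nm``
    is the edit distance of the matched portion; ``seq`` the full read in
    read orientation (DNA alphabet).
    """

    read_id: str
    transcript_id: str
    tstart: int
    tend: int
    sense: bool
    soft5: str = ""
    soft3: str = ""
    nm: int = 0
    seq: str = ""

    @property
    def templated_length(self) -> int:
        return self.tend - self.tstart

    @property
    def length(self) -> int:
        return len(self.soft5) + self.templated_length + len(self.soft3)


def _is_perfect_21m(read) -> bool:
    """CIGAR 21M with no mismatches: the qualifying class for phasing."""
    return (
        read.templated_length == 21
        and not getattr(read, "soft5", "")
        and not getattr(read, "soft3", "")
        and getattr(read, "nm", 0) == 0
    )


_DNA_COMP = str.maketrans("ACGTN", "TGCAN")


def anchor_alignments(
    sam_path: str | Path,
    models: dict[str, TranscriptModel],
) -> tuple[dict[str, list[AlignedRead]], int]:
    """Project SAM/BAM alignments onto transcript coordinates.

    Each alignment is assigned to every transcript whose spliced sequence
    fully contains its aligned span (intron-crossing alignments are projected
    through spliced coordinates).  Secondary/supplementary/unmapped records
    are ignored; alignments only partially exonic in a transcript do not
    anchor to it.  Returns ``(reads per transcript id, n_dropped)`` where the
    dropped count is alignments anchored to no transcript.
    """
    import pysam

    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models.values():
        by_chrom.setdefault(m.chrom, []).append(m)

    anchored: dict[str, list[AlignedRead]] = {m.id: [] for m in models.values()}
    dropped = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            hit = False
            for model in by_chrom.get(aln.reference_name, []):
                rec = _project_alignment(aln, model)
                if rec is not None:
                    anchored[model.id].append(rec)
                    hit = True
            if not hit:
                dropped += 1
    return anchored, dropped


def _project_alignment(aln, model: TranscriptModel) -> AlignedRead | None:
    tpos = []
    for g in aln.get_reference_positions():
        try:
            tpos.append(genomic_to_transcript(g, model))
        except NotExonicError:
            return None
    if not tpos:
        return None
    lo, hi = min(tpos), max(tpos)
    if hi - lo + 1 != len(tpos):  # leaks through an intron of this model
        return None
    cig = aln.cigartuples or []
    left_clip = cig[0][1] if cig and cig[0][0] == 4 else 0
    right_clip = cig[-1][1] if cig and cig[-1][0] == 4 else 0
    seq = aln.query_sequence or ""
    left_seq = seq[:left_clip]
    right_seq = seq[len(seq) - right_clip :] if right_clip else ""
    if aln.is_reverse:
        # read orientation: genomic-right clip is the read's 5' end
        soft5 = right_seq.translate(_DNA_COMP)[::-1]
        soft3 = left_seq.translate(_DNA_COMP)[::-1]
        read_seq = seq.translate(_DNA_COMP)[::-1]
    else:
        soft5, soft3, read_seq = left_seq, right_seq, seq
    sense = (not aln.is_reverse) == (model.strand == "+")
    nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
    return AlignedRead(
        read_id=aln.query_name,
        transcript_id=model.id,
        tstart=lo,
        tend=hi + 1,
        sense=sense,
        soft5=soft5,
        soft3=soft3,
        nm=int(nm),
        seq=read_seq,
    )


# ---------------------------------------------------------------------------
# GFF3 and cleavage-site table I/O
# ---------------------------------------------------------------------------

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def _attr(attributes: str, key: str) -> str | None:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_gff3(path: str | Path) -> dict[str, TranscriptModel]:
    """Read transcript models (mRNA/exon/UTR features) from a GFF3 file.

    Handles the subset this package writes plus plain Araport-style
    gene/mRNA/exon/five_prime_UTR/three_prime_UTR files. Coordinates are
    converted from 1-based closed to 0-based half-open.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"seqid": str},
    )
    tx_meta: dict[str, dict] = {}
    parts: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for row in df.itertuples(index=False):
        ftype = row.type
        if ftype in {"mRNA", "transcript"}:
            tid = _attr(row.attributes, "ID")
            if tid is None:
                raise ValueError("mRNA feature without ID attribute")
            tx_meta[tid] = {
                "chrom": row.seqid,
                "strand": row.strand,
                "gene_id": _attr(row.attributes, "Parent") or "",
            }
        elif ftype in {"exon", "five_prime_UTR", "three_prime_UTR"}:
            parent = _attr(row.attributes, "Parent")
            if parent is None:
                continue
            for tid in parent.split(","):
                slot = {"exon": "exons", "five_prime_UTR": "utr5",
                        "three_prime_UTR": "utr3"}[ftype]
                parts.setdefault(tid, {}).setdefault(slot, []).append(
                    (int(row.start) - 1, int(row.end))
                )
    models: dict[str, TranscriptModel] = {}
    for tid, meta in tx_meta.items():
        p = parts.get(tid, {})
        if not p.get("exons"):
            raise ValueError(f"transcript {tid} has no exon features")
        models[tid] = TranscriptModel(
            id=tid,
            chrom=meta["chrom"],
            strand=meta["strand"],
            exons=tuple(p["exons"]),
            gene_id=meta["gene_id"],
            utr5=tuple(sorted(p.get("utr5", []))),
            utr3=tuple(sorted(p.get("utr3", []))),
        )
    return models


def write_gff3(
    models: Iterable[TranscriptModel],
    path: str | Path,
    gene_types: dict[str, str] | None = None,
) -> None:
    """Write transcript models as gene/mRNA/exon/UTR GFF3 features.

    ``gene_types`` optionally maps gene_id to a feature class recorded in a
    ``gene_type`` attribute (miRNA_target, protein_coding, ...).
    """
    gene_types = gene_types or {}
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id or m.id, []).append(m)
    for gid in sorted(by_gene):
        txs = by_gene[gid]
        g_start = min(t.genomic_start for t in txs)
        g_end = max(t.genomic_end for t in txs)
        chrom, strand = txs[0].chrom, txs[0].strand
        attrs = f"ID={gid}"
        if gid in gene_types:
            attrs += f";gene_type={gene_types[gid]}"
        lines.append(
            f"{chrom}\tphasetally\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t{attrs}"
        )
        for t in txs:
            lines.append(
                f"{t.chrom}\tphasetally\tmRNA\t{t.genomic_start + 1}\t"
                f"{t.genomic_end}\t.\t{t.strand}\t.\tID={t.id};Parent={gid}"
            )
            for s, e in t.exons:
                lines.append(
                    f"{t.chrom}\tphasetally\texon\t{s + 1}\t{e}\t.\t{t.strand}"
                    f"\t.\tParent={t.id}"
                )
            for name, ivals in (("five_prime_UTR", t.utr5), ("three_prime_UTR", t.utr3)):
                for s, e in ivals:
                    lines.append(
                        f"{t.chrom}\tphasetally\t{name}\t{s + 1}\t{e}\t.\t"
                        f"{t.strand}\t.\tParent={t.id}"
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def read_cleavage_sites(
    path: str | Path,
    models: dict[str, TranscriptModel],
    *,
    convention: str = "first_3cf",
) -> list[CleavageSite]:
    """Load a cleavage-site table and convert to transcript coordinates.

    Expected TSV columns: ``gene_id  transcript_id  cs_genomic  mirna`` with
    ``cs_genomic`` 1-based, as published cleavage-site tables give it.  The
    position is interpreted as the first nucleotide of the 3' cleavage
    fragment (``convention="first_3cf"``); pass ``convention="last_5cf"`` to
    treat it as the last nucleotide of the 5' fragment instead.
    """
    if convention not in {"first_3cf", "last_5cf"}:
        raise ValueError(f"unknown cleavage-site convention {convention!r}")
    df = pd.read_csv(path, sep="\t")
    sites = []
    for row in df.itertuples(index=False):
        model = models[row.transcript_id]
        t = genomic_to_transcript(int(row.cs_genomic) - 1, model)
        cs = t if convention == "first_3cf" else t + 1
        site = CleavageSite(
            transcript_id=row.transcript_id,
            cs=cs,
            trigger_mirna=str(getattr(row, "mirna", "")),
            gene_id=str(getattr(row, "gene_id", "")),
        )
        site.validate(model)
        sites.append(site)
    return sites
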