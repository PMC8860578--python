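"""Synthetic small-RNA data with the statistical structure of a secondary-siRNA study.

The generator emulates what the downstream stages assume about real
inflorescence small RNA-seq libraries:

* multi-exon transcripts on both genomic strands, each miRNA target carrying a
  single cleavage site strictly inside an exon;
* 21-24-nt siRNA reads on both strands concentrated around the cleavage site,
  with a tunable fraction of 21-nt reads starting exactly on the 21-nt phase
  grid anchored at the site (``phase_fidelity``);
* trim/tail heterogeneity confined to sense reads abutting the 3' extremity of
  the 5' cleavage fragment;
* negative-binomial per-gene counts across replicated genotypes;
* miRNA:target pair tables (expression, seed dG, producer label) drawn from a
  known logistic model.

Everything is reproducible from ``SimConfig.seed``; each generator derives its
own deterministic sub-stream so outputs are independent of call order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coordinates import CleavageSite, TranscriptModel, write_gff3

__all__ = [
    "SimConfig",
    "NBParams",
    "SimRead",
    "SyntheticTranscriptome",
    "simulate_transcriptome",
    "simulate_sirna_reads",
    "simulate_terminal_reads",
    "simulate_count_matrix",
    "simulate_pair_table",
    "simulate_family_dg_table",
    "write_fasta",
    "write_sam",
]

_DNA = np.array(list("ACGT"))

DEFAULT_SIZE_MIX = {21: 0.70, 22: 0.10, 23: 0.10, 24: 0.10}

# (n_trimmed, n_tailed) -> probability, for reads abutting the 5'-CF extremity.
# Mass concentrated on short trims/tails, as terminal-read dot plots of
# exosome-mutant libraries show.
DEFAULT_TRIMTAIL_MODEL = {
    (0, 0): 0.40,
    (1, 0): 0.15,
    (2, 0): 0.10,
    (3, 0): 0.05,
    (0, 1): 0.15,
    (0, 2): 0.05,
    (1, 1): 0.05,
    (2, 2): 0.05,
}


@dataclass
class NBParams:
    """Negative-binomial count model: counts_gj ~ NB(mean_g * fc_gj, dispersion).

    ``genotypes`` maps genotype name to replicate count; ``lfc`` maps genotype
    to a per-gene log2 fold change versus the first (reference) genotype -
    scalar, array, or absent (no change).  Defaults reflect replicated
    genotype designs of inflorescence siRNA libraries: triplicates, moderate
    means, dispersion 0.1.
    """

    genotypes: Mapping[str, int] = field(
        default_factory=lambda: {"wt": 3, "mutant": 3}
    )
    n_genes: int = 2000
    mean: float = 100.0
    dispersion: float = 0.1
    lfc: Mapping[str, object] = field(default_factory=dict)


@dataclass
class SimConfig:
    """Parameters of the synthetic small-RNA study.

    ``exon_structure`` is one list of exon lengths applied to every transcript
    or a list of such lists, one per transcript.  ``cs_position`` is the
    transcript coordinate of the cleavage site (first nucleotide of the 3'
    cleavage fragment), scalar or per-target.
    """

    seed: int = 0
    n_transcripts: int = 6
    exon_structure: Sequence = (800, 400, 900)
    cs_position: object = 1000
    phase_fidelity: float = 0.8
    size_mix: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_SIZE_MIX))
    strand_mix: float = 0.5
    five_prime_frac: float = 0.65
    spread_decay: float = 0.99
    antisense_duplex_offset: int = 0
    trimtail_model: Mapping[tuple[int, int], float] | None = field(
        default_factory=lambda: dict(DEFAULT_TRIMTAIL_MODEL)
    )
    tail_alphabet: str = "ACGT"
    intron_length: int = 100
    intergenic_gap: int = 500
    gene_type_cycle: Sequence[str] = (
        "miRNA_target", "protein_coding", "transposable_element",
    )
    nb_params: NBParams = field(default_factory=NBParams)
    logit_coefs: Sequence[float] = (-2.0, 1.2)

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase_fidelity <= 1.0:
            raise ValueError("phase_fidelity must be in [0, 1]")
        if not 0.0 <= self.strand_mix <= 1.0:
            raise ValueError("strand_mix must be in [0, 1]")
        if not self.size_mix:
            raise ValueError("size_mix must be a non-empty mixture")
        probs = np.array(list(self.size_mix.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("size_mix probabilities must be >= 0 and sum to 1")
        if self.trimtail_model is not None:
            tt = np.array(list(self.trimtail_model.values()), dtype=float)
            if (tt < 0).any() or not np.isclose(tt.sum(), 1.0):
                raise ValueError("trimtail_model probabilities must sum to 1")
        for lens in self._exon_lists():
            if any(l <= 0 for l in lens):
                raise ValueError("exon lengths must be positive")
        for i in range(self.n_transcripts):
            length = sum(self._exon_lists()[i])
            cs = self._cs(i)
            if not 0 < cs < length:
                raise ValueError(
                    f"cs_position {cs} outside spliced length {length} "
                    f"of transcript {i}"
                )

    def _exon_lists(self) -> list[list[int]]:
        es = list(self.exon_structure)
        if es and isinstance(es[0], (int, np.integer)):
            return [list(es)] * self.n_transcripts
        if len(es) != self.n_transcripts:
            raise ValueError("exon_structure must match n_transcripts")
        return [list(x) for x in es]

    def _cs(self, i: int) -> int:
        if isinstance(self.cs_position, (int, np.integer)):
            return int(self.cs_position)
        return int(self.cs_position[i])

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic sub-stream ``stream`` of the run's RNG."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
        )


@dataclass
class SyntheticTranscriptome:
    models: dict[str, TranscriptModel]
    genome: dict[str, str]
    sites: list[CleavageSite]
    gene_types: dict[str, str]

    def model_for_site(self, site: CleavageSite) -> TranscriptModel:
        return self.models[site.transcript_id]


def simulate_transcriptome(config: SimConfig) -> SyntheticTranscriptome:
    """Lay transcripts along one chromosome, alternating strands.

    Gene types cycle through ``config.gene_type_cycle``; every miRNA_target
    gene carries a cleavage site at ``cs_position``.
    """
    rng = config.rng(1)
    models: dict[str, TranscriptModel] = {}
    sites: list[CleavageSite] = []
    gene_types: dict[str, str] = {}
    cursor = config.intergenic_gap
    exon_lists = config._exon_lists()
    for i in range(config.n_transcripts):
        gid = f"GENE{i + 1}"
        tid = f"{gid}.1"
        strand = "+" if i % 2 == 0 else "-"
        exons = []
        pos = cursor
        for L in exon_lists[i]:
            exons.append((pos, pos + L))
            pos += L + config.intron_length
        cursor = exons[-1][1] + config.intergenic_gap
        model = TranscriptModel(
            id=tid, chrom="chr1", strand=strand, exons=tuple(exons), gene_id=gid
        )
        models[tid] = model
        gtype = config.gene_type_cycle[i % len(config.gene_type_cycle)]
        gene_types[gid] = gtype
        if gtype == "miRNA_target":
            site = CleavageSite(
                transcript_id=tid,
                cs=config._cs(i),
                trigger_mirna=f"miR{900 + i}",
                gene_id=gid,
            )
            site.validate(model)
            sites.append(site)
    genome_len = cursor + config.intergenic_gap
    genome = {"chr1": "".join(rng.choice(_DNA, size=genome_len))}
    return SyntheticTranscriptome(models, genome, sites, gene_types)


# ---------------------------------------------------------------------------
# siRNA reads
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    """One simulated alignment, in transcript space.

    ``tstart``/``tend`` delimit the templated (matched) part, 0-based
    half-open transcript coordinates.  ``sense`` is True when the read's
    5'->3' direction equals the transcript's.  ``soft3`` holds non-templated
    bases appended at the read's 3' end (read orientation, DNA alphabet).
    """

    read_id: str
    transcript_id: str
    tstart: int
    tend: int
    sense: bool
    soft3: str = ""
    soft5: str = ""
    nm: int = 0
    seq: str = ""

    @property
    def templated_length(self) -> int:
        return self.tend - self.tstart

    @property
    def length(self) -> int:
        return len(self.soft5) + self.templated_length + len(self.soft3)


def _truncated_geometric(rng, ratio: float, kmax: int, size: int) -> np.ndarray:
    """Sample slot indices 0..kmax with P(k) proportional to ratio**k."""
    w = ratio ** np.arange(kmax + 1)
    return rng.choice(kmax + 1, size=size, p=w / w.sum())


def simulate_sirna_reads(
    config: SimConfig,
    tome: SyntheticTranscriptome,
    n_reads: int = 10_000,
    *,
    library: int = 0,
) -> list[SimRead]:
    """Simulate secondary-siRNA alignments around each cleavage site.

    Reads are spread over both cleavage fragments with geometric decay away
    from the site (``spread_decay`` per nucleotide, an artifact choice - the
    field has no quantitative spreading model).  A 21-nt read starts exactly
    on the 21-nt grid anchored at the cleavage site with probability
    ``phase_fidelity``; otherwise its grid offset is uniform over the 21
    possibilities.  Sense reads whose templated 3' end abuts the 5'-CF
    extremity receive trim/tail noise from ``trimtail_model``.
    """
    if not config.size_mix:
        raise ValueError("size_mix is empty")
    if not tome.sites:
        raise ValueError("transcriptome has no cleavage sites")
    rng = config.rng(1000 + library)
    lengths = np.array(sorted(config.size_mix), dtype=int)
    length_p = np.array([config.size_mix[l] for l in lengths], dtype=float)
    slot_ratio = config.spread_decay ** 21

    reads: list[SimRead] = []
    per_site = np.full(len(tome.sites), n_reads // len(tome.sites))
    per_site[: n_reads % len(tome.sites)] += 1
    counter = 0
    for site, n_site in zip(tome.sites, per_site):
        model = tome.model_for_site(site)
        tx_len = model.spliced_length
        cs = site.cs
        read_lens = rng.choice(lengths, size=n_site, p=length_p)
        senses = rng.random(n_site) < config.strand_mix
        on_5cf = rng.random(n_site) < config.five_prime_frac
        on_grid = rng.random(n_site) < config.phase_fidelity
        offs = np.where(on_grid, 0, rng.integers(0, 21, size=n_site))
        for L, sense, five, off in zip(read_lens, senses, on_5cf, offs):
            L = int(L)
            if five:
                space = cs  # CF length
            else:
                space = tx_len - cs
            kmax = (space - int(off) - L) // 21
            if kmax < 0:
                five = not five
                space = cs if five else tx_len - cs
                kmax = (space - int(off) - L) // 21
                if kmax < 0:
                    continue  # site too close to both ends for this read
            k = int(_truncated_geometric(rng, slot_ratio, int(kmax), 1)[0])
            if five:
                # grid interval k on the 5' CF ends at cs-1-21k; offset moves
                # the read further 5'-ward so it never straddles the site
                tend = cs - 21 * k - int(off)
                tstart = tend - L
            else:
                tstart = cs + 21 * k + int(off)
                tend = tstart + L
            if not sense and config.antisense_duplex_offset:
                shift = config.antisense_duplex_offset
                if tstart + shift >= 0 and tend + shift <= tx_len:
                    tstart, tend = tstart + shift, tend + shift
            read = SimRead(
                read_id=f"sim{library}_{counter}",
                transcript_id=site.transcript_id,
                tstart=int(tstart),
                tend=int(tend),
                sense=bool(sense),
            )
            counter += 1
            if (
                config.trimtail_model is not None
                and read.sense
                and read.tend == cs
            ):
                _apply_trimtail(read, config, rng)
            reads.append(read)
    return reads


def _apply_trimtail(read: SimRead, config: SimConfig, rng) -> None:
    keys = list(config.trimtail_model)
    p = np.array([config.trimtail_model[k] for k in keys], dtype=float)
    n_trim, n_tail = keys[rng.choice(len(keys), p=p / p.sum())]
    read.tend -= int(n_trim)
    if read.tend <= read.tstart:  # never trim a read away entirely
        read.tend = read.tstart + 1
    alphabet = list(config.tail_alphabet)
    read.soft3 = "".join(rng.choice(alphabet, size=int(n_tail)))


def simulate_terminal_reads(
    config: SimConfig,
    tome: SyntheticTranscriptome,
    n_reads: int = 10_000,
    *,
    library: int = 0,
) -> list[SimRead]:
    """Simulate reads that all abut the 5'-CF extremity before trim/tail noise.

    This isolates the population the trim/tail analysis studies (the
    CF-terminal reads), so the configured ``trimtail_model`` is the exact
    generative joint distribution of ``(n_trimmed, n_tailed)``.
    """
    if config.trimtail_model is None:
        raise ValueError("trimtail_model is not configured")
    rng = config.rng(2000 + library)
    site = tome.sites[0]
    reads = []
    for i in range(n_reads):
        read = SimRead(
            read_id=f"term{library}_{i}",
            transcript_id=site.transcript_id,
            tstart=site.cs - 21,
            tend=site.cs,
            sense=True,
        )
        _apply_trimtail(read, config, rng)
        reads.append(read)
    return reads


# ---------------------------------------------------------------------------
# NB count matrices
# ---------------------------------------------------------------------------


def simulate_count_matrix(config: SimConfig):
    """Draw a genes x libraries NB count matrix from ``config.nb_params``.

    Returns a :class:`phasetally.quantify.CountMatrix`.  Counts for gene g in
    genotype t have mean ``mean_g * 2**lfc[t]_g`` and variance
    ``mu + dispersion * mu**2``.
    """
    from .quantify import CountMatrix  # local import to avoid a cycle

    p = config.nb_params
    rng = config.rng(3000)
    mean = np.broadcast_to(np.asarray(p.mean, dtype=float), (p.n_genes,))
    alpha = float(p.dispersion)
    genes = [f"GENE{i + 1}" for i in range(p.n_genes)]
    cols, data, meta = [], [], []
    for genotype, n_rep in p.genotypes.items():
        lfc = np.broadcast_to(
            np.asarray(p.lfc.get(genotype, 0.0), dtype=float), (p.n_genes,)
        )
        mu = mean * 2.0 ** lfc
        for rep in range(1, n_rep + 1):
            if alpha > 0:
                counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
            else:
                counts = rng.poisson(mu)
            cols.append(f"{genotype}_{rep}")
            data.append(counts)
            meta.append({"library": f"{genotype}_{rep}", "genotype": genotype,
                         "replicate": rep})
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    libraries = pd.DataFrame(meta).set_index("library")
    return CountMatrix(counts=counts, libraries=libraries)


# ---------------------------------------------------------------------------
# miRNA:target pair tables
# ---------------------------------------------------------------------------

_RNA = np.array(list("ACGU"))
_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _rc_rna(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def simulate_pair_table(config: SimConfig, n_pairs: int = 153) -> pd.DataFrame:
    """Draw a miRNA:target pair table from a known logistic model.

    log-expression is Normal (log-normal RPM), seed dG is Normal with a
    negative mean (kJ/mol), and the producer label is Bernoulli with
    P = logistic(b0 + b1*log_rpm [+ b2*(-dG)]) for ``config.logit_coefs``
    = (b0, b1[, b2]).  The default table size matches a reduced
    unique-seed pair set (153 combinations).
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    coefs = list(config.logit_coefs)
    if len(coefs) not in (2, 3):
        raise ValueError("logit_coefs must be (b0, b1) or (b0, b1, b2)")
    rng = config.rng(4000)
    log_rpm = rng.normal(loc=2.0, scale=1.5, size=n_pairs)
    delta_g = rng.normal(loc=-30.0, scale=8.0, size=n_pairs)
    eta = coefs[0] + coefs[1] * log_rpm
    if len(coefs) == 3:
        eta = eta + coefs[2] * (-delta_g)
    prob = 1.0 / (1.0 + np.exp(-eta))
    producer = rng.random(n_pairs) < prob
    mirna_seqs = ["".join(rng.choice(_RNA, size=21)) for _ in range(n_pairs)]
    return pd.DataFrame(
        {
            "mirna_id": [f"miR{i + 1:03d}" for i in range(n_pairs)],
            "mirna_seq": mirna_seqs,
            "target_id": [f"AT{i + 1:05d}" for i in range(n_pairs)],
            "target_site_seq": [_rc_rna(s) for s in mirna_seqs],
            "expression_rpm": np.exp(log_rpm),
            "delta_g": delta_g,
            "producer": producer,
        }
    )


def simulate_family_dg_table(
    config: SimConfig,
    n_families: int = 9,
    targets_per_family: int = 16,
    family_sd: float = 2.0,
    producer_effect: float = -3.0,
    residual_sd: float = 4.0,
) -> pd.DataFrame:
    """Within-family dG table for the mixed-model analysis.

    dG = -30 + family intercept (Normal, sd ``family_sd``) +
    ``producer_effect`` * producer + Normal residual.  Producer labels are
    balanced within family so every family has both classes.
    """
    rng = config.rng(5000)
    rows = []
    for f in range(n_families):
        fam = f"miR{800 + f}"
        intercept = rng.normal(0.0, family_sd)
        for t in range(targets_per_family):
            producer = t % 2 == 0
            dg = (
                -30.0
                + intercept
                + (producer_effect if producer else 0.0)
                + rng.normal(0.0, residual_sd)
            )
            rows.append(
                {"family": fam, "target_id": f"{fam}_T{t}", "delta_g": dg,
                 "producer": producer}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers (FASTA genome, SAM alignments)
# ---------------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _blocks(tstart: int, tend: int, model: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic blocks (sorted by genomic start) covering a transcript interval."""
    from .coordinates import transcript_to_genomic

    positions = sorted(
        transcript_to_genomic(t, model) for t in range(tstart, tend)
    )
    blocks = []
    start = prev = positions[0]
    for g in positions[1:]:
        if g == prev + 1:
            prev = g
        else:
            blocks.append((start, prev + 1))
            start = prev = g
    blocks.append((start, prev + 1))
    return blocks


def write_sam(
    reads: Sequence[SimRead],
    tome: SyntheticTranscriptome,
    path: str | Path,
) -> None:
    """Write simulated reads as a genomic SAM file via pysam.

    Reads are emitted already aligned (there is no mapping stage): templated
    bases are copied from the genome so every alignment is a perfect match
    (NM=0) and tails appear as 3' soft clips in read orientation.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": chrom, "LN": len(seq)} for chrom, seq in tome.genome.items()
        ],
    }
    records = []
    comp = str.maketrans("ACGT", "TGCA")
    for read in reads:
        model = tome.models[read.transcript_id]
        blocks = _blocks(read.tstart, read.tend, model)
        genome_seq = tome.genome[model.chrom]
        plus_seq = "".join(genome_seq[s:e] for s, e in blocks)
        # sequence of the templated part in transcript orientation
        tx_seq = plus_seq if model.strand == "+" else plus_seq.translate(comp)[::-1]
        templated = tx_seq if read.sense else _rc_dna(tx_seq)
        read_seq = templated + read.soft3
        genomic_forward = read.sense == (model.strand == "+")
        cigar = []
        for i, (s, e) in enumerate(blocks):
            if i > 0:
                cigar.append((3, s - blocks[i - 1][1]))  # N
            cigar.append((0, e - s))  # M
        clip = (4, len(read.soft3))
        if read.soft3:
            # the read's 3' end is genomically right for forward alignments
            cigar = cigar + [clip] if genomic_forward else [clip] + cigar
        a = pysam.AlignedSegment()
        a.query_name = read.read_id
        a.query_sequence = read_seq if genomic_forward else read_seq.translate(comp)[::-1]
        a.flag = 0 if genomic_forward else 16
        a.reference_id = list(tome.genome).index(model.chrom)
        a.reference_start = blocks[0][0]
        a.mapping_quality = 255
        a.cigartuples = cigar
        a.set_tag("NM", 0)
        records.append(a)
    records.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in records:
            out.write(a)


def _rc_dna(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
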