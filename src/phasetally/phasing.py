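"""21-register phasing analysis anchored at miRNA cleavage sites.

Single-round RDR6/DCL4 amplification dices double-stranded RNA from a fixed
terminus - the RISC cleavage site - so the resulting 21-nt siRNAs stack in
consecutive 21-nt registers.  The statistic here follows that logic directly:
the nucleotide adjacent to the cleavage site is position 1 on both cleavage
fragments, each fragment is split into 21-nt intervals from position 1
(1-21, 22-42, 43-63, ...), and a perfectly matching 21-nt read whose
CS-proximal boundary falls at fragment-local position l occupies register
``((l - 1) mod 21) + 1``.  A population is called phased when a strict
majority of qualifying reads sits in register 1.

Only perfect 21-nt matches (CIGAR 21M, zero mismatches) qualify; reads
straddling the cleavage site are rejected and counted.  The 2-nt displacement
of minus-strand dicer products is deliberately not corrected for, so a tightly
phased double-stranded population may split between registers 1 and 2 by
strand - the TAS1c-like signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .coordinates import CleavageSite, _is_perfect_21m

__all__ = [
    "assign_phase_register",
    "phase_distribution",
    "call_phased",
    "PhaseRegisterTable",
]

N_REGISTERS = 21


@dataclass
class PhaseRegisterTable:
    """Per-strand register counts for one target population.

    ``plus``/``minus`` hold counts for registers 1..21 (index 0 = register 1)
    of sense/antisense reads; ``rejected`` counts reads that failed the
    qualifying rules (non-21M, mismatched, or straddling the site).
    """

    target_id: str = ""
    genotype: str = ""
    plus: list = field(default_factory=lambda: [0] * N_REGISTERS)
    minus: list = field(default_factory=lambda: [0] * N_REGISTERS)
    rejected: int = 0

    @property
    def register_counts(self) -> list:
        return [p + m for p, m in zip(self.plus, self.minus)]

    @property
    def total(self) -> int:
        return sum(self.plus) + sum(self.minus)

    def register_fraction(self, register: int) -> float:
        if self.total == 0:
            raise ZeroDivisionError("no qualifying reads")
        return self.register_counts[register - 1] / self.total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for strand, counts in (("+", self.plus), ("-", self.minus)):
            for r, c in enumerate(counts, start=1):
                rows.append(
                    {"target": self.target_id, "genotype": self.genotype,
                     "strand": strand, "register": r, "count": c}
                )
        return pd.DataFrame(rows)


def assign_phase_register(read, site: CleavageSite) -> int | None:
    """Register (1..21) of a qualifying read, or None if rejected.

    The read must be a perfect 21-nt match lying wholly within one cleavage
    fragment.  Fragment-local numbering counts away from the cleavage site on
    both fragments (position 1 is adjacent to the site), and the register is
    computed from the read boundary nearest the site.
    """
    if not _is_perfect_21m(read):
        return None
    cs = site.cs
    if read.tstart >= cs:  # 3' CF: nearest boundary is the read start
        local = read.tstart - cs + 1
    elif read.tend <= cs:  # 5' CF: nearest boundary is the read end
        local = cs - (read.tend - 1)
    else:  # straddles the cleavage site
        return None
    return (local - 1) % N_REGISTERS + 1


def phase_distribution(
    reads: Iterable,
    site: CleavageSite,
    *,
    target_id: str = "",
    genotype: str = "",
) -> PhaseRegisterTable:
    """Tally qualifying reads into the 21 registers, split by strand."""
    table = PhaseRegisterTable(target_id=target_id or site.transcript_id,
                               genotype=genotype)
    for read in reads:
        register = assign_phase_register(read, site)
        if register is None:
            table.rejected += 1
        elif read.sense:
            table.plus[register - 1] += 1
        else:
            table.minus[register - 1] += 1
    return table


def call_phased(table: PhaseRegisterTable) -> str:
    """'phased' iff register 1 holds a strict majority of qualifying reads.

    Returns 'undetermined' for empty populations; an exact 50% tie is
    'unphased' (majority read strictly).
    """
    if table.total == 0:
        return "undetermined"
    if table.register_counts[0] * 2 > table.total:
        return "phased"
    return "unphased"
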