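"""Cleavage-site-centered read-density profiles and cross-target aggregation.

Densities are per-base coverage (each read contributes to every templated
position it covers), normalized to reads per ten million mapped (RP10M),
averaged over replicate libraries, and re-indexed to signed distance from the
cleavage site (position 0 = first nucleotide of the 3' cleavage fragment).
A ``mode="5prime"`` option counts only read 5' ends instead, for spike-style
per-target panels.  Strands are kept separate so callers can plot sense
coverage upward and antisense coverage downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coordinates import CleavageSite, TranscriptModel

__all__ = ["DensityProfile", "per_position_density", "metaplot_aggregate"]

LENGTH_CLASSES = (21, 22, 23, 24)


@dataclass
class DensityProfile:
    """Mean normalized density over signed distances for one target.

    ``density[(strand, length)]`` is a vector over ``distances``; densities
    are RP10M per position, averaged over ``n_replicates`` libraries.
    ``truncated`` flags windows clipped by the transcript ends.
    """

    target_id: str
    genotype: str
    distances: np.ndarray
    density: dict = field(default_factory=dict)
    n_replicates: int = 1
    truncated: bool = False

    def total(self, strand: str | None = None) -> np.ndarray:
        """Sum of densities over length classes (and strands if None)."""
        keys = [k for k in self.density
                if strand is None or k[0] == strand]
        if not keys:
            return np.zeros_like(self.distances, dtype=float)
        return np.sum([self.density[k] for k in keys], axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (strand, length), vec in sorted(self.density.items()):
            for d, v in zip(self.distances, vec):
                rows.append(
                    {"target": self.target_id, "genotype": self.genotype,
                     "distance": int(d), "strand": strand, "length": length,
                     "density": float(v)}
                )
        return pd.DataFrame(rows)


def per_position_density(
    replicate_reads: Sequence[Iterable],
    model: TranscriptModel,
    site: CleavageSite,
    library_totals: Sequence[int],
    *,
    window: int = 1000,
    mode: str = "coverage",
    lengths: Sequence[int] = LENGTH_CLASSES,
    genotype: str = "",
) -> DensityProfile:
    """Density profile around one cleavage site for one genotype.

    ``replicate_reads`` is one iterable of transcript-anchored reads per
    replicate library, with matching ``library_totals`` (total mapped reads
    per library, used for the per-ten-million normalization).  Only reads of
    the requested ``lengths`` contribute.
    """
    if mode not in {"coverage", "5prime"}:
        raise ValueError(f"unknown mode {mode!r}")
    if len(replicate_reads) != len(library_totals):
        raise ValueError("one library total per replicate is required")
    if any(t <= 0 for t in library_totals):
        raise ValueError("library totals must be positive")
    n_rep = len(replicate_reads)
    if n_rep == 0:
        raise ValueError("at least one replicate library is required")
    tx_len = model.spliced_length
    lo = max(0, site.cs - window)
    hi = min(tx_len, site.cs + window + 1)
    distances = np.arange(lo, hi) - site.cs
    truncated = (site.cs - window < 0) or (site.cs + window + 1 > tx_len)
    acc: dict[tuple[str, int], np.ndarray] = {}
    for reads, total in zip(replicate_reads, library_totals):
        scale = 1e7 / float(total)
        for read in reads:
            L = read.length
            if L not in lengths:
                continue
            strand = "+" if read.sense else "-"
            key = (strand, L)
            vec = acc.setdefault(key, np.zeros(hi - lo))
            if mode == "coverage":
                a, b = max(read.tstart, lo), min(read.tend, hi)
                if a < b:
                    vec[a - lo : b - lo] += scale
            else:
                five = read.tstart if read.sense else read.tend - 1
                if lo <= five < hi:
                    vec[five - lo] += scale
    density = {k: v / n_rep for k, v in acc.items()}
    return DensityProfile(
        target_id=site.transcript_id,
        genotype=genotype,
        distances=distances,
        density=density,
        n_replicates=n_rep,
        truncated=truncated,
    )


def metaplot_aggregate(profiles: Sequence[DensityProfile]) -> DensityProfile:
    """Unweighted mean profile across targets on a common distance window.

    Profiles must share the same distance grid (same window, none truncated
    differently); densities missing a (strand, length) class in some targets
    are treated as zero there.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    ref = profiles[0].distances
    for p in profiles[1:]:
        if len(p.distances) != len(ref) or not np.array_equal(p.distances, ref):
            raise ValueError("profiles are not on the same distance window")
    keys = sorted({k for p in profiles for k in p.density})
    n = len(profiles)
    density = {
        k: np.sum(
            [p.density.get(k, np.zeros(len(ref))) for p in profiles], axis=0
        ) / n
        for k in keys
    }
    return DensityProfile(
        target_id=f"aggregate({n} targets)",
        genotype=profiles[0].genotype,
        distances=ref.copy(),
        density=density,
        n_replicates=profiles[0].n_replicates,
        truncated=any(p.truncated for p in profiles),
    )


def plot_profile(profile: DensityProfile, path: str) -> None:
    """Basic metaplot: sense coverage up, antisense down, colored by length."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.2))
    colors = {21: "#1b9e77", 22: "#d95f02", 23: "#7570b3", 24: "#e7298a"}
    for (strand, length), vec in sorted(profile.density.items()):
        sign = 1.0 if strand == "+" else -1.0
        ax.plot(profile.distances, sign * vec, lw=0.9,
                color=colors.get(length, "gray"),
                label=f"{length} nt ({strand})")
    ax.axvline(0, ls="--", c="k", lw=0.8)
    ax.axhline(0, c="k", lw=0.6)
    ax.set_xlabel("distance from cleavage site (nt)")
    ax.set_ylabel("RP10M")
    ax.set_title(f"{profile.target_id} {profile.genotype}".strip())
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
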