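"""Per-gene siRNA counting, normalization and simplified differential testing.

The differential test is a deliberate simplification of the DESeq2 procedure:
a per-gene negative-binomial GLM with log link and size-factor offsets,
method-of-moments dispersion with a floor (no empirical-Bayes shrinkage), a
Wald z test on the mutant-vs-wild-type contrast and Benjamini-Hochberg
adjustment.  With a two-group design and a gene-specific dispersion the GLM
decomposes into independent per-group mean fits, which are solved exactly by
vectorized Newton iterations across all genes at once.

Counting follows featureCounts defaults in spirit: a read is assigned to a
gene when its aligned span overlaps exactly one feature; reads overlapping
two or more features are ambiguous and left unassigned; only primary
alignments count by default (``multimap`` offers fractional/all modes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "feature_table",
    "assign_reads_to_features",
    "normalize_rpm",
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "fisher_enrichment",
    "size_class_profile",
    "target_zscore_matrix",
]

DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Genes x libraries integer counts with library and gene metadata.

    ``libraries`` is indexed by library name with at least a ``genotype``
    column; ``genes`` (optional) is indexed by gene id with ``type`` and
    ``is_mirna_target`` columns.
    """

    counts: pd.DataFrame
    libraries: pd.DataFrame
    genes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not set(self.counts.columns) <= set(self.libraries.index):
            missing = set(self.counts.columns) - set(self.libraries.index)
            raise ValueError(f"libraries missing metadata: {sorted(missing)}")

    def libraries_of(self, genotype: str) -> list[str]:
        sel = self.libraries[self.libraries["genotype"] == genotype].index
        return [c for c in self.counts.columns if c in set(sel)]


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------


def feature_table(
    models: Mapping[str, object],
    gene_types: Mapping[str, str] | None = None,
    *,
    chrom_sizes: Mapping[str, int] | None = None,
    include_intergenic: bool = True,
) -> pd.DataFrame:
    """Gene-level features (one row per gene: chrom, start, end, type).

    With ``include_intergenic`` and ``chrom_sizes``, gaps between gene spans
    become intergenic bin features, so every position is annotated.
    """
    gene_types = gene_types or {}
    rows: dict[str, dict] = {}
    for m in models.values():
        gid = m.gene_id or m.id
        row = rows.setdefault(
            gid,
            {"gene_id": gid, "chrom": m.chrom, "start": m.genomic_start,
             "end": m.genomic_end,
             "type": gene_types.get(gid, "protein_coding")},
        )
        row["start"] = min(row["start"], m.genomic_start)
        row["end"] = max(row["end"], m.genomic_end)
    df = pd.DataFrame(rows.values()).sort_values(["chrom", "start"])
    if include_intergenic and chrom_sizes:
        extra = []
        for chrom, size in chrom_sizes.items():
            sub = df[df["chrom"] == chrom]
            cursor, i = 0, 1
            bounds = list(zip(sub["start"], sub["end"])) + [(size, size)]
            for s, e in bounds:
                if s > cursor:
                    extra.append(
                        {"gene_id": f"intergenic_{chrom}_{i}", "chrom": chrom,
                         "start": cursor, "end": s, "type": "intergenic"}
                    )
                    i += 1
                cursor = max(cursor, e)
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def assign_reads_to_features(
    sam_paths: Mapping[str, str | Path],
    features: pd.DataFrame,
    libraries: pd.DataFrame | None = None,
    *,
    multimap: str = "primary",
    return_read_table: bool = False,
):
    """Count alignments per gene feature across libraries.

    ``sam_paths`` maps library name to SAM/BAM path.  A read counts toward a
    feature when its aligned genomic span overlaps it; reads overlapping
    several features are ambiguous and unassigned.  ``multimap``: ``primary``
    skips secondary alignments, ``all`` counts every record, ``fractional``
    weights each record by 1/NH.  Unassigned reads are tallied per library in
    the ``_unassigned`` row.
    """
    import pysam

    if multimap not in {"primary", "fractional", "all"}:
        raise ValueError(f"unknown multimap mode {multimap!r}")
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): sub.sort_values("start").reset_index(drop=True)
        for c, sub in features.groupby("chrom")
    }
    gene_ids = list(features["gene_id"])
    cols: dict[str, np.ndarray] = {}
    unassigned: dict[str, float] = {}
    read_rows: list[dict] = []
    for lib, path in sam_paths.items():
        counts = dict.fromkeys(gene_ids, 0.0)
        miss = 0.0
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            bad = [c for c in fh.references if c not in by_chrom]
            if bad:
                raise ValueError(
                    "alignment chromosomes absent from annotation: "
                    + ", ".join(sorted(bad))
                )
            for aln in fh:
                if aln.is_unmapped or aln.is_supplementary:
                    continue
                if multimap == "primary" and aln.is_secondary:
                    continue
                if multimap == "all" or multimap == "primary":
                    w = 1.0
                else:
                    nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
                    w = 1.0 / float(nh)
                sub = by_chrom[aln.reference_name]
                s, e = aln.reference_start, aln.reference_end
                hits = sub[(sub["start"] < e) & (sub["end"] > s)]
                if len(hits) == 1:
                    gid = hits.iloc[0]["gene_id"]
                    counts[gid] += w
                    if return_read_table:
                        read_rows.append(
                            {"library": lib, "gene_id": gid,
                             "length": aln.query_length}
                        )
                else:
                    miss += w
        cols[lib] = np.array([counts[g] for g in gene_ids])
        unassigned[lib] = miss
    counts_df = pd.DataFrame(cols, index=gene_ids)
    counts_df.loc["_unassigned"] = pd.Series(unassigned)
    if libraries is None:
        libraries = pd.DataFrame(
            {"genotype": [lib.rsplit("_", 1)[0] for lib in sam_paths]},
            index=list(sam_paths),
        )
    genes = features.set_index("gene_id")[["type"]].copy()
    genes["is_mirna_target"] = genes["type"] == "miRNA_target"
    cm = CountMatrix(
        counts=counts_df.drop(index="_unassigned"),
        libraries=libraries,
        genes=genes,
    )
    cm.unassigned = counts_df.loc["_unassigned"]  # type: ignore[attr-defined]
    if return_read_table:
        return cm, pd.DataFrame(read_rows, columns=["library", "gene_id", "length"])
    return cm


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_rpm(counts: pd.DataFrame, per: str = "RPM") -> pd.DataFrame:
    """Reads per million (RPM) or per ten million (RP10M) mapped."""
    scale = {"RPM": 1e6, "RP10M": 1e7}.get(per)
    if scale is None:
        raise ValueError(f"per must be 'RPM' or 'RP10M', got {per!r}")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        zero = list(totals.index[totals <= 0])
        raise ValueError(f"zero library total in {zero}")
    return counts / totals * scale


def size_factors(counts: pd.DataFrame, *, pseudocount: float = 0.0) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    Uses genes with nonzero counts in every library (after the optional
    pseudocount): factor_j = median_g count_gj / geometric-mean_g.
    """
    mat = counts.to_numpy(dtype=float) + pseudocount
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in all libraries; "
            "consider size_factors(..., pseudocount=0.5)"
        )
    log_mat = np.log(mat[allpos])
    log_geo = log_mat.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_mat - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# NB Wald differential test
# ---------------------------------------------------------------------------


def _group_nb_mle(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray,
                  n_iter: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-group NB mean fit with offsets, vectorized over genes.

    Solves sum_j (y_gj - sf_j exp(b_g)) / (1 + alpha_g sf_j exp(b_g)) = 0 by
    Newton iteration.  Returns (b, var_b) with var_b from the Fisher
    information sum_j w_j, w = mu/(1 + alpha mu).
    """
    mean0 = (y / sf).mean(axis=1)
    b = np.log(np.maximum(mean0, 1e-8))
    for _ in range(n_iter):
        mu = sf * np.exp(b)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        b = b + np.clip(step, -2.0, 2.0)
    mu = sf * np.exp(b)[:, None]
    fisher = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    var_b = 1.0 / np.maximum(fisher, 1e-12)
    return b, var_b


def _mom_dispersion(norm: np.ndarray, groups: Sequence[np.ndarray]) -> np.ndarray:
    """Per-gene method-of-moments dispersion pooled over groups, floored.

    alpha = sum_t (n_t-1)(var_t - mean_t) / sum_t (n_t-1) mean_t^2 on
    size-factor-normalized counts.
    """
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups:
        sub = norm[:, idx]
        n_t = sub.shape[1]
        if n_t < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += (n_t - 1) * (v - m)
        den += (n_t - 1) * m**2
    alpha = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    return np.maximum(alpha, DISPERSION_FLOOR)


def _pooled_mom_dispersion(norm: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """One common method-of-moments dispersion pooled over genes and groups.

    With few replicates a per-gene moment estimate has so little information
    that Wald tests built on it are badly anticonservative; pooling the
    moment sums over all genes gives a precise common estimate and calibrated
    tests when dispersions are homogeneous.
    """
    num = den = 0.0
    for idx in groups:
        sub = norm[:, idx]
        n_t = sub.shape[1]
        if n_t < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += (n_t - 1) * (v - m).sum()
        # m^2 overestimates mu^2 by var(m) ~= v/n; subtract for an unbiased
        # moment denominator
        den += (n_t - 1) * (m**2 - v / n_t).sum()
    if den <= 0:
        return DISPERSION_FLOOR
    return max(num / den, DISPERSION_FLOOR)


def nb_wald_test(
    cm: CountMatrix,
    contrast: tuple[str, str],
    *,
    dispersion: float | np.ndarray | str = "per-gene",
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Simplified NB Wald differential test for one mutant-vs-WT contrast.

    Requires at least two replicates per group; single-replicate genotypes do
    not enter testing.  ``dispersion`` may be ``"per-gene"`` (method of
    moments, floored), a scalar, or a per-gene array.  Returns a DataFrame
    with ``baseMean, log2FC, pvalue, padj`` indexed by gene; all-zero genes
    are excluded and flagged in the ``all_zero`` attribute column.
    """
    mutant, wt = contrast
    lib_m, lib_w = cm.libraries_of(mutant), cm.libraries_of(wt)
    for name, libs in ((mutant, lib_m), (wt, lib_w)):
        if len(libs) < 2:
            raise ValueError(
                f"genotype {name!r} has {len(libs)} replicate(s); at least 2 "
                "are required for testing"
            )
    libs = lib_w + lib_m
    counts = cm.counts[libs].to_numpy(dtype=float)
    if sf is None:
        sf = size_factors(cm.counts[libs])
    sfv = sf[libs].to_numpy(dtype=float)
    nonzero = counts.sum(axis=1) > 0
    y = counts[nonzero]
    norm = y / sfv
    idx_w = np.arange(len(lib_w))
    idx_m = np.arange(len(lib_w), len(libs))
    if isinstance(dispersion, str):
        if dispersion == "per-gene":
            alpha = _mom_dispersion(norm, [idx_w, idx_m])
        elif dispersion == "pooled":
            alpha = np.full(
                y.shape[0], _pooled_mom_dispersion(norm, [idx_w, idx_m])
            )
        else:
            raise ValueError(f"unknown dispersion mode {dispersion!r}")
    else:
        alpha = np.maximum(
            np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],)),
            DISPERSION_FLOOR,
        ).copy()
    b_w, v_w = _group_nb_mle(y[:, idx_w], sfv[idx_w], alpha)
    b_m, v_m = _group_nb_mle(y[:, idx_m], sfv[idx_m], alpha)
    beta = b_m - b_w
    se = np.sqrt(v_w + v_m)
    zero_group = (y[:, idx_w].sum(axis=1) == 0) | (y[:, idx_m].sum(axis=1) == 0)
    z = np.where(zero_group, np.nan, beta / se)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    res = pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2FC": beta / np.log(2.0),
            "lfcSE": se / np.log(2.0),
            "stat": z,
            "pvalue": pvalue,
            "dispersion": alpha,
        },
        index=cm.counts.index[nonzero],
    )
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    res.attrs["all_zero"] = list(cm.counts.index[~nonzero])
    res.attrs["contrast"] = f"{mutant} vs {wt}"
    return res


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaNs propagate and are excluded from ranking."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if (q < 0).any() or (q > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m:
        order = np.argsort(q, kind="mergesort")
        ranked = q[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[ok] = res
    return out


def fisher_enrichment(
    de_genes: set,
    universe: set,
    targets: set,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Exact Fisher test for miRNA-target enrichment (or set overlap).

    2x2 table of membership in ``de_genes`` x membership in ``targets`` over
    ``universe``.  Returns (odds ratio, p).
    """
    if not universe:
        raise ValueError("empty universe")
    if not de_genes <= universe or not targets <= universe:
        raise ValueError("de_genes and targets must be subsets of universe")
    a = len(de_genes & targets)
    b = len(de_genes - targets)
    c = len(targets - de_genes)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# Size-class and z-score summaries
# ---------------------------------------------------------------------------


def size_class_profile(
    read_table: pd.DataFrame,
    libraries: pd.DataFrame,
    gene_types: Mapping[str, str],
    library_totals: Mapping[str, float],
    *,
    lengths: Sequence[int] = (21, 22, 23, 24),
) -> pd.DataFrame:
    """Mean RPM (with SEM over replicates) by genotype x gene type x length.

    ``read_table`` has one row per assigned read: ``library, gene_id,
    length`` (as produced by ``assign_reads_to_features(...,
    return_read_table=True)``).  Reads outside ``lengths`` are ignored.
    """
    df = read_table[read_table["length"].isin(lengths)].copy()
    df["type"] = df["gene_id"].map(lambda g: gene_types.get(g, "intergenic"))
    per_lib = (
        df.groupby(["library", "type", "length"]).size().rename("reads").reset_index()
    )
    per_lib["rpm"] = [
        r / library_totals[l] * 1e6
        for l, r in zip(per_lib["library"], per_lib["reads"])
    ]
    per_lib["genotype"] = per_lib["library"].map(libraries["genotype"])
    # make absent combinations explicit zeros per library before averaging
    libs = list(libraries.index)
    types = sorted(set(gene_types.values()) | {"intergenic"})
    full = pd.MultiIndex.from_product(
        [libs, types, list(lengths)], names=["library", "type", "length"]
    ).to_frame(index=False)
    full = full.merge(per_lib[["library", "type", "length", "rpm"]],
                      how="left").fillna({"rpm": 0.0})
    full["genotype"] = full["library"].map(libraries["genotype"])
    out = (
        full.groupby(["genotype", "type", "length"])["rpm"]
        .agg(mean_rpm="mean", sem=lambda x: x.sem(ddof=1) if len(x) > 1 else 0.0,
             n_replicates="size")
        .reset_index()
    )
    return out


def target_zscore_matrix(mean_rpm: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row z-scores of a targets x genotypes mean-RPM matrix.

    Uses the population (n-denominator) standard deviation; constant rows get
    a zero z-row and are flagged.  Returns (z matrix, flat-row flags).
    """
    if mean_rpm.shape[1] < 2:
        raise ValueError("at least two genotypes are required")
    mat = mean_rpm.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    z = np.where(sd > 0, (mat - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z, index=mean_rpm.index, columns=mean_rpm.columns)
    return zdf, pd.Series(flat, index=mean_rpm.index, name="constant_row")
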