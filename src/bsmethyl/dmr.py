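"""Differentially methylated site (DMS) and region (DMR) detection.

Methylated regions of a single strain are found by running the two-sample
machinery against an artificial fully unmethylated sample with uniform 60x
coverage at every cytosine: any real methylation is then "differential"
against that null genome. Between-strain comparisons use the same pipeline
with the second strain in place of the artificial control.

Per shared site the two samples' counts form a 2x2 table
``[[mcA, covA - mcA], [mcB, covB - mcB]]`` tested with a two-sided Fisher
exact test; q-values are Benjamini–Hochberg across all tested sites, and a
DMS is a site with q <= alpha. DMSs are chained greedily along each contig:
consecutive DMSs at most ``max_gap`` (default 1 kb) apart join one cluster,
and clusters with at least ``min_dms`` (default 10) members are reported as
DMRs spanning their first to last DMS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import DEFAULT_ALPHA, DEFAULT_MIN_COV, bh_adjust
from .counts import CountTable
from .genome import ReferenceGenome

__all__ = [
    "MethylatedRegion",
    "make_unmethylated_control",
    "fisher_pvalues",
    "find_dms",
    "merge_dms_to_dmr",
    "dmr_pipeline",
]

DEFAULT_MAX_GAP = 1_000
DEFAULT_MIN_DMS = 10
DEFAULT_CONTROL_COVERAGE = 60

# Fisher p-values depend only on the 2x2 table; real tables repeat the same
# few thousand count combinations, so memoise across calls.
_fisher_cache: dict[tuple[int, int, int, int], float] = {}


@dataclass
class MethylatedRegion:
    """A DMR: contig interval (0-based half-open) spanning >= min_dms DMSs."""

    contig: str
    start: int
    end: int
    n_dms: int
    name: str = ""
    # per-sample weighted methylation: name -> (level, sum_mc, sum_cov)
    levels: dict[str, tuple[float, int, int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)


def make_unmethylated_control(
    genome: ReferenceGenome, coverage: int = DEFAULT_CONTROL_COVERAGE
) -> CountTable:
    """Artificial sample: every cytosine of the genome at mc=0, cov=coverage."""
    if coverage <= 0:
        raise ValueError(f"control coverage must be positive, got {coverage}")
    cyt = genome.cytosines()
    df = cyt[["contig", "pos", "strand", "context"]].copy()
    df["mc"] = 0
    df["cov"] = int(coverage)
    return CountTable(df)


def _fisher_one(mc_a: int, cov_a: int, mc_b: int, cov_b: int) -> float:
    key = (mc_a, cov_a, mc_b, cov_b)
    p = _fisher_cache.get(key)
    if p is None:
        table = [[mc_a, cov_a - mc_a], [mc_b, cov_b - mc_b]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        _fisher_cache[key] = p
    return p


def fisher_pvalues(
    mc_a: np.ndarray, cov_a: np.ndarray, mc_b: np.ndarray, cov_b: np.ndarray
) -> np.ndarray:
    """Vectorised two-sided Fisher exact p-values for paired count vectors."""
    stacked = np.column_stack([mc_a, cov_a, mc_b, cov_b]).astype(np.int64)
    uniq, inverse = np.unique(stacked, axis=0, return_inverse=True)
    pvals = np.array([_fisher_one(*row) for row in uniq])
    return pvals[inverse]


def _pool_strands(table: CountTable) -> pd.DataFrame:
    """Sum counts across strands at each (contig, pos)."""
    return (
        table.frame.groupby(["contig", "pos"], as_index=False, sort=True)
        .agg(mc=("mc", "sum"), cov=("cov", "sum"))
    )


def find_dms(
    table_a: CountTable,
    table_b: CountTable,
    alpha: float = DEFAULT_ALPHA,
    min_cov: int = DEFAULT_MIN_COV,
) -> pd.DataFrame:
    """Two-sided Fisher + BH over all sites covered >= min_cov in both samples.

    Counts are pooled across strands at each position before testing. Returns
    a frame with columns ``contig, pos, mc_a, cov_a, mc_b, cov_b, p, q,
    is_dms`` over the tested sites.
    """
    a = _pool_strands(table_a)
    b = _pool_strands(table_b)
    merged = a.merge(b, on=["contig", "pos"], suffixes=("_a", "_b"))
    merged = merged[(merged["cov_a"] >= min_cov) & (merged["cov_b"] >= min_cov)]
    merged = merged.reset_index(drop=True)
    if len(merged) == 0:
        warnings.warn("no shared sites covered in both samples; empty DMS table")
        merged["p"] = pd.Series(dtype=float)
        merged["q"] = pd.Series(dtype=float)
        merged["is_dms"] = pd.Series(dtype=bool)
        return merged
    merged["p"] = fisher_pvalues(
        merged["mc_a"].to_numpy(),
        merged["cov_a"].to_numpy(),
        merged["mc_b"].to_numpy(),
        merged["cov_b"].to_numpy(),
    )
    merged["q"] = bh_adjust(merged["p"].to_numpy())
    merged["is_dms"] = merged["q"] <= alpha
    return merged


def merge_dms_to_dmr(
    dms_positions: dict[str, np.ndarray] | pd.DataFrame,
    max_gap: int = DEFAULT_MAX_GAP,
    min_dms: int = DEFAULT_MIN_DMS,
) -> list[MethylatedRegion]:
    """Greedy single-pass chaining of DMS positions into DMRs.

    ``dms_positions`` is either a mapping of contig -> 1-based positions or a
    DMS frame from :func:`find_dms` (its ``is_dms`` rows are used). Positions
    are sorted and de-duplicated internally. Consecutive DMSs at most
    ``max_gap`` bp apart join one cluster; clusters with >= ``min_dms``
    members become regions spanning first to last DMS (reported 0-based
    half-open).
    """
    if isinstance(dms_positions, pd.DataFrame):
        df = dms_positions
        if "is_dms" in df.columns:
            df = df[df["is_dms"]]
        dms_positions = {
            ctg: grp["pos"].to_numpy() for ctg, grp in df.groupby("contig", sort=True)
        }
    regions: list[MethylatedRegion] = []
    for contig in sorted(dms_positions):
        pos = np.unique(np.asarray(dms_positions[contig], dtype=np.int64))
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [pos.size - 1]])
        for s, e in zip(starts, ends):
            n = int(e - s + 1)
            if n >= min_dms:
                regions.append(
                    MethylatedRegion(
                        contig=contig,
                        start=int(pos[s] - 1),
                        end=int(pos[e]),
                        n_dms=n,
                    )
                )
    for i, reg in enumerate(regions):
        reg.name = f"DMR_{i + 1:04d}"
    return regions


def dmr_pipeline(
    samples: list[CountTable] | dict[str, CountTable],
    reference_sample: CountTable,
    alpha: float = DEFAULT_ALPHA,
    min_cov: int = DEFAULT_MIN_COV,
    max_gap: int = DEFAULT_MAX_GAP,
    min_dms: int = DEFAULT_MIN_DMS,
) -> tuple[list[MethylatedRegion], pd.DataFrame]:
    """Pool replicates, find DMSs against the reference, chain into DMRs.

    Replicate tables are pooled by summing counts per site before testing,
    mirroring a joint DMR run over multiple samples of one strain. Per-sample
    weighted methylation levels (including the reference) are attached to
    each region. Returns ``(regions, dms_table)``.
    """
    from .regionstats import weighted_level  # local import to avoid a cycle

    if isinstance(samples, dict):
        names = list(samples)
        tables = list(samples.values())
    else:
        tables = list(samples)
        names = [f"sample_{i + 1}" for i in range(len(tables))]
    if not tables:
        raise ValueError("need at least one sample")
    pooled = CountTable.pool(tables)
    dms = find_dms(pooled, reference_sample, alpha=alpha, min_cov=min_cov)
    regions = merge_dms_to_dmr(dms, max_gap=max_gap, min_dms=min_dms)
    for reg in regions:
        for name, tab in zip(names, tables):
            reg.levels[name] = weighted_level(tab, reg.interval())
        reg.levels["reference"] = weighted_level(reference_sample, reg.interval())
    return regions, dms
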