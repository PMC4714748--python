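"""Weighted methylation levels of regions, notched box summaries, metaplots.

The weighted methylation level of an interval is the coverage-weighted
fraction ``sum(mc) / sum(cov)`` over all cytosine records (both strands)
inside it — not the mean of per-site fractions — so deeply covered sites
dominate, as in standard WGBS practice. An interval with no covered
cytosine has a *missing* level (NaN), never zero.

The metaplot scales every region to 60 ordered bins: 20 upstream flank bins
of 50 bp (1 kb total), 20 body bins of 5% of the region length each, and
20 downstream flank bins of 50 bp. By default raw counts are pooled across
regions per bin and each bin's level is the pooled weighted fraction; a
per-region mean of bin levels is available as an alternative aggregate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .counts import CountTable

__all__ = [
    "WeightedLevel",
    "NotchedBoxStats",
    "MetaplotProfile",
    "weighted_level",
    "region_level_matrix",
    "boxplot_notch_stats",
    "notches_overlap",
    "metaplot_profile",
]

logger = logging.getLogger(__name__)

NOTCH_CONSTANT = 1.58  # McGill et al. notch half-width: 1.58 * IQR / sqrt(n)


class WeightedLevel(NamedTuple):
    """Coverage-weighted methylation of one interval; level is NaN if cov=0."""

    level: float
    mc: int
    cov: int


class RegionLookupError(KeyError):
    """Region refers to a contig absent from the count table."""


def weighted_level(table: CountTable, region: tuple[str, int, int]) -> WeightedLevel:
    """Weighted methylation level of a 0-based half-open region."""
    contig, start, end = region
    if contig not in set(table.frame["contig"]):
        raise RegionLookupError(f"contig {contig!r} not present in count table")
    sub = table.subset(contig)
    pos0 = sub["pos"].to_numpy() - 1
    inside = (pos0 >= start) & (pos0 < end)
    mc = int(sub.loc[inside, "mc"].sum())
    cov = int(sub.loc[inside, "cov"].sum())
    level = mc / cov if cov > 0 else float("nan")
    return WeightedLevel(level=level, mc=mc, cov=cov)


def region_level_matrix(
    tables: dict[str, CountTable], regions: list
) -> pd.DataFrame:
    """Regions x samples matrix of weighted levels with retained counts.

    ``regions`` is a list of ``(contig, start, end)`` tuples or
    :class:`~bsmethyl.dmr.MethylatedRegion` objects. Returns a long-format
    frame with columns ``region, contig, start, end, sample, level, mc, cov``
    (one row per region-sample cell); pivot on demand.
    """
    rows = []
    for i, reg in enumerate(regions):
        if hasattr(reg, "interval"):
            contig, start, end = reg.interval()
            name = reg.name or f"region_{i + 1:04d}"
        else:
            contig, start, end = reg
            name = f"region_{i + 1:04d}"
        for sample, table in tables.items():
            wl = weighted_level(table, (contig, start, end))
            rows.append(
                {
                    "region": name,
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "sample": sample,
                    "level": wl.level,
                    "mc": wl.mc,
                    "cov": wl.cov,
                }
            )
    return pd.DataFrame(
        rows, columns=["region", "contig", "start", "end", "sample", "level", "mc", "cov"]
    )


@dataclass(frozen=True)
class NotchedBoxStats:
    """Five-number-style summary with a McGill notch around the median.

    The notch half-width ``1.58 * IQR / sqrt(n)`` approximates a 95%
    confidence interval for the median; non-overlapping notches between two
    groups indicate a difference at roughly the 5% level.
    """

    median: float
    q1: float
    q3: float
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def notch_half_width(self) -> float:
        return NOTCH_CONSTANT * self.iqr / math.sqrt(self.n)

    @property
    def notch_low(self) -> float:
        return self.median - self.notch_half_width

    @property
    def notch_high(self) -> float:
        return self.median + self.notch_half_width


def boxplot_notch_stats(levels) -> NotchedBoxStats:
    """Median, linear-interpolation quartiles and notch for a set of levels."""
    arr = np.asarray(levels, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no finite levels to summarise")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return NotchedBoxStats(median=float(med), q1=float(q1), q3=float(q3), n=int(arr.size))


def notches_overlap(a: NotchedBoxStats, b: NotchedBoxStats) -> bool:
    """True when the two notch intervals intersect ("not statistically different")."""
    return a.notch_low <= b.notch_high and b.notch_low <= a.notch_high


@dataclass
class MetaplotProfile:
    """60-bin averaged methylation profile across a set of regions.

    ``frame`` columns: ``bin`` (0..59), ``segment`` (upstream/body/downstream),
    ``label``, ``mc``, ``cov``, ``level``. ``n_regions`` counts the regions
    actually profiled (too-short regions are skipped).
    """

    frame: pd.DataFrame
    n_regions: int
    aggregate: str = "pooled"

    @property
    def levels(self) -> np.ndarray:
        return self.frame["level"].to_numpy()

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, **kwargs):
        """Line plot of the 60-bin profile with flank/body boundaries marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        ax.plot(self.frame["bin"], self.frame["level"], **kwargs)
        nb = (len(self.frame) - 2 * _N_FLANK_DEFAULT) or 20
        for x in (_N_FLANK_DEFAULT - 0.5, _N_FLANK_DEFAULT + nb - 0.5):
            ax.axvline(x, color="grey", lw=0.5, ls="--")
        ax.set_xlabel("bin (upstream | body | downstream)")
        ax.set_ylabel("weighted methylation")
        return ax


_N_FLANK_DEFAULT = 20


def metaplot_profile(
    table: CountTable,
    regions: list,
    flank: int = 1_000,
    n_flank_bins: int = 20,
    n_body_bins: int = 20,
    aggregate: str = "pooled",
) -> MetaplotProfile:
    """Average methylation profile over regions with fixed-width flanks.

    Each region contributes counts to ``n_flank_bins`` upstream bins of
    ``flank / n_flank_bins`` bp, ``n_body_bins`` equal-fraction body bins
    (half-open, last bin closed) and ``n_flank_bins`` downstream bins.
    Regions shorter than ``n_body_bins`` bases are skipped with a warning.
    Flank bins truncated by a contig end simply receive fewer sites.

    ``aggregate="pooled"`` (default) pools raw counts across regions per bin;
    ``aggregate="mean"`` averages per-region bin levels (unweighted across
    regions), with per-bin mc/cov still reporting the pooled counts.
    """
    if not regions:
        raise ValueError("no regions to profile")
    if aggregate not in ("pooled", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    bin_bp = flank // n_flank_bins
    n_bins = 2 * n_flank_bins + n_body_bins
    mc_tot = np.zeros(n_bins, dtype=np.int64)
    cov_tot = np.zeros(n_bins, dtype=np.int64)
    per_region_levels = []
    by_contig = {ctg: grp for ctg, grp in table.frame.groupby("contig", sort=False)}
    n_used = 0
    for reg in regions:
        contig, start, end = reg.interval() if hasattr(reg, "interval") else reg
        length = end - start
        if length < n_body_bins:
            logger.warning(
                "skipping region %s:%d-%d shorter than %d bp", contig, start, end, n_body_bins
            )
            continue
        grp = by_contig.get(contig)
        if grp is None:
            continue
        pos0 = grp["pos"].to_numpy() - 1
        window = (pos0 >= start - flank) & (pos0 < end + flank)
        wpos = pos0[window]
        wmc = grp["mc"].to_numpy()[window]
        wcov = grp["cov"].to_numpy()[window]
        bins = np.empty(wpos.size, dtype=np.int64)
        up = wpos < start
        down = wpos >= end
        body = ~up & ~down
        bins[up] = (wpos[up] - (start - flank)) // bin_bp
        frac = (wpos[body] - start) / length
        bins[body] = n_flank_bins + np.minimum(
            (frac * n_body_bins).astype(np.int64), n_body_bins - 1
        )
        bins[down] = n_flank_bins + n_body_bins + (wpos[down] - end) // bin_bp
        mc_r = np.bincount(bins, weights=wmc, minlength=n_bins).astype(np.int64)
        cov_r = np.bincount(bins, weights=wcov, minlength=n_bins).astype(np.int64)
        mc_tot += mc_r
        cov_tot += cov_r
        with np.errstate(invalid="ignore", divide="ignore"):
            per_region_levels.append(mc_r / cov_r)
        n_used += 1
    if n_used == 0:
        raise ValueError("all regions skipped; nothing to profile")
    with np.errstate(invalid="ignore", divide="ignore"):
        if aggregate == "pooled":
            level = np.where(cov_tot > 0, mc_tot / np.maximum(cov_tot, 1), np.nan)
        else:
            level = np.nanmean(np.vstack(per_region_levels), axis=0)
    segment = (
        ["upstream"] * n_flank_bins + ["body"] * n_body_bins + ["downstream"] * n_flank_bins
    )
    labels = (
        [f"up_{-flank + i * bin_bp}" for i in range(n_flank_bins)]
        + [f"body_{int(100 * i / n_body_bins)}%" for i in range(n_body_bins)]
        + [f"down_{i * bin_bp}" for i in range(n_flank_bins)]
    )
    frame = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "segment": segment,
            "label": labels,
            "mc": mc_tot,
            "cov": cov_tot,
            "level": level,
        }
    )
    return MetaplotProfile(frame=frame, n_regions=n_used, aggregate=aggregate)
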