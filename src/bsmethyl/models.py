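"""Model/Results front end over the functional pipeline.

Two estimators in the statsmodels idiom — construct a model from data,
call :meth:`fit`, inspect a results object with a ``summary()``:

* :class:`MethylationModel` — one sample against its unmethylated control
  contig: estimates the bisulfite non-conversion rate and calls every
  cytosine's methylation status by binomial test + BH.
* :class:`DifferentialMethylationModel` — one or more replicate samples
  against a reference sample (a second strain, or the in-silico fully
  unmethylated 60x genome): per-site Fisher exact tests, BH, DMS chaining
  into DMRs, and per-region weighted methylation levels.

Both results objects expose the underlying tables so the plain functions in
:mod:`bsmethyl.calling`, :mod:`bsmethyl.dmr` and :mod:`bsmethyl.regionstats`
remain the single source of computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calling, dmr as dmrmod, regionstats
from .counts import CountTable
from .genome import ReferenceGenome

__all__ = [
    "MethylationModel",
    "MethylationResults",
    "DifferentialMethylationModel",
    "DMRResults",
]


class MethylationModel:
    """Per-cytosine methylation caller for one sample.

    Parameters
    ----------
    counts
        The sample's per-cytosine count table.
    control_contig
        Name of the fully unmethylated contig used to estimate the
        non-conversion rate.
    min_cov
        Minimum coverage for a site to be tested (default 3).
    """

    def __init__(self, counts: CountTable, control_contig: str, min_cov: int = calling.DEFAULT_MIN_COV):
        self.counts = counts
        self.control_contig = control_contig
        self.min_cov = min_cov

    @classmethod
    def from_allc(cls, path, control_contig: str, **kwargs) -> "MethylationModel":
        return cls(CountTable.read_allc(path), control_contig, **kwargs)

    def fit(self, alpha: float = calling.DEFAULT_ALPHA) -> "MethylationResults":
        est = calling.estimate_nonconversion(self.counts, self.control_contig)
        calls = calling.call_sites(self.counts, est, alpha=alpha, min_cov=self.min_cov)
        return MethylationResults(model=self, nonconversion=est, site_calls=calls, alpha=alpha)


@dataclass
class MethylationResults:
    """Fitted methylation calls with the non-conversion estimate."""

    model: MethylationModel
    nonconversion: calling.NonConversionEstimate
    site_calls: calling.SiteCalls
    alpha: float

    @property
    def params(self) -> pd.Series:
        return pd.Series({"nonconversion_rate": self.nonconversion.rate})

    @property
    def bse(self) -> pd.Series:
        return pd.Series({"nonconversion_rate": self.nonconversion.stderr})

    @property
    def n_methylated(self) -> int:
        return self.site_calls.n_methylated

    def methylation_level(self, region: tuple[str, int, int]) -> regionstats.WeightedLevel:
        return regionstats.weighted_level(self.model.counts, region)

    def summary(self) -> str:
        est = self.nonconversion
        sc = self.site_calls
        n = len(sc.frame)
        lines = [
            "Methylation calling results",
            "=" * 46,
            f"{'sites in table':<30}{n:>16,}",
            f"{'tested (cov >= {0})'.format(self.model.min_cov):<30}{sc.n_tested:>16,}",
            f"{'called methylated':<30}{sc.n_methylated:>16,}",
            f"{'alpha (BH)':<30}{self.alpha:>16.3g}",
            "-" * 46,
            f"{'non-conversion rate r':<30}{est.rate:>16.6f}",
            f"{'  std err':<30}{est.stderr:>16.6f}",
            f"{'  control contig':<30}{est.control_contig:>16}",
            f"{'  control sites / coverage':<30}{f'{est.n_sites:,} / {est.total_cov:,}':>16}",
            "=" * 46,
        ]
        return "\n".join(lines)


class DifferentialMethylationModel:
    """DMR finder between pooled replicate samples and a reference sample."""

    def __init__(
        self,
        samples: dict[str, CountTable] | list[CountTable],
        reference: CountTable,
        alpha: float = calling.DEFAULT_ALPHA,
        min_cov: int = calling.DEFAULT_MIN_COV,
        max_gap: int = dmrmod.DEFAULT_MAX_GAP,
        min_dms: int = dmrmod.DEFAULT_MIN_DMS,
    ):
        if isinstance(samples, list):
            samples = {f"sample_{i + 1}": t for i, t in enumerate(samples)}
        self.samples = samples
        self.reference = reference
        self.alpha = alpha
        self.min_cov = min_cov
        self.max_gap = max_gap
        self.min_dms = min_dms

    @classmethod
    def against_unmethylated(
        cls,
        samples: dict[str, CountTable] | list[CountTable],
        genome: ReferenceGenome,
        control_coverage: int = dmrmod.DEFAULT_CONTROL_COVERAGE,
        **kwargs,
    ) -> "DifferentialMethylationModel":
        """Compare samples against the artificial fully unmethylated genome."""
        reference = dmrmod.make_unmethylated_control(genome, coverage=control_coverage)
        return cls(samples, reference, **kwargs)

    def fit(self) -> "DMRResults":
        regions, dms = dmrmod.dmr_pipeline(
            self.samples,
            self.reference,
            alpha=self.alpha,
            min_cov=self.min_cov,
            max_gap=self.max_gap,
            min_dms=self.min_dms,
        )
        return DMRResults(model=self, regions=regions, dms=dms)


@dataclass
class DMRResults:
    """Fitted DMRs with the per-site DMS table and region-level statistics."""

    model: DifferentialMethylationModel
    regions: list[dmrmod.MethylatedRegion]
    dms: pd.DataFrame
    _levels: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_dmrs(self) -> int:
        return len(self.regions)

    @property
    def n_dms(self) -> int:
        return int(self.dms["is_dms"].sum()) if len(self.dms) else 0

    def regions_frame(self) -> pd.DataFrame:
        rows = []
        for reg in self.regions:
            row = {
                "name": reg.name,
                "contig": reg.contig,
                "start": reg.start,
                "end": reg.end,
                "length": reg.length,
                "n_dms": reg.n_dms,
            }
            for sample, (level, _, _) in reg.levels.items():
                row[f"level_{sample}"] = level
            rows.append(row)
        return pd.DataFrame(rows)

    def region_levels(self) -> pd.DataFrame:
        """Long-format regions x samples weighted-level matrix."""
        if self._levels is None:
            self._levels = regionstats.region_level_matrix(self.model.samples, self.regions)
        return self._levels

    def notch_stats(self, sample: str) -> regionstats.NotchedBoxStats:
        lv = self.region_levels()
        vals = lv.loc[lv["sample"] == sample, "level"]
        return regionstats.boxplot_notch_stats(vals)

    def metaplot(self, sample: str | None = None, **kwargs) -> regionstats.MetaplotProfile:
        """60-bin metaplot over the fitted regions for one sample (or pooled)."""
        if sample is None:
            table = CountTable.pool(list(self.model.samples.values()))
        else:
            table = self.model.samples[sample]
        return regionstats.metaplot_profile(table, self.regions, **kwargs)

    def plot_region_levels(self, ax=None):
        """Notched box plots of per-region weighted levels, one box per sample."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * len(self.model.samples) + 1.5, 3.5))
        bxp_stats = []
        for sample in self.model.samples:
            st = self.notch_stats(sample)
            lv = self.region_levels()
            vals = lv.loc[lv["sample"] == sample, "level"].dropna().to_numpy()
            bxp_stats.append(
                {
                    "label": sample,
                    "med": st.median,
                    "q1": st.q1,
                    "q3": st.q3,
                    "cilo": st.notch_low,
                    "cihi": st.notch_high,
                    "whislo": float(np.min(vals)),
                    "whishi": float(np.max(vals)),
                    "fliers": [],
                }
            )
        ax.bxp(bxp_stats, shownotches=True)
        ax.set_ylabel("weighted methylation level")
        return ax

    def write_bed(self, path) -> None:
        from .fileio import write_regions_bed

        write_regions_bed(self.regions, path)

    def summary(self) -> str:
        m = self.model
        total_span = sum(r.length for r in self.regions)
        lines = [
            "Differential methylation results",
            "=" * 52,
            f"{'samples (pooled for testing)':<34}{len(m.samples):>18,}",
            f"{'tested sites':<34}{len(self.dms):>18,}",
            f"{'DMSs (q <= alpha)':<34}{self.n_dms:>18,}",
            f"{'DMRs (>= {0} DMSs, gap <= {1} bp)'.format(m.min_dms, m.max_gap):<34}{self.n_dmrs:>18,}",
            f"{'total DMR span (bp)':<34}{total_span:>18,}",
            f"{'alpha / min coverage':<34}{f'{m.alpha:g} / {m.min_cov}':>18}",
            "-" * 52,
        ]
        for sample in m.samples:
            lv = self.region_levels()
            vals = lv.loc[lv["sample"] == sample, "level"].dropna()
            if len(vals):
                st = regionstats.boxplot_notch_stats(vals)
                lines.append(
                    f"{sample:<22}median level {st.median:.4f}  "
                    f"notch [{st.notch_low:.4f}, {st.notch_high:.4f}]  n={st.n}"
                )
            else:
                lines.append(f"{sample:<22}no regions")
        lines.append("=" * 52)
        return "\n".join(lines)
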