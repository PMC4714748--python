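"""Per-cytosine methylation calling.

The caller follows the standard MethylC-seq recipe for organisms with a
fully unmethylated internal control sequence:

1. Estimate the bisulfite non-conversion rate ``r`` as the pooled
   methylated-read fraction over all covered cytosines of the control
   contig (the mitochondrial genome in Neurospora).
2. For each sufficiently covered cytosine, test ``H0: mc ~ Binomial(cov, r)``
   against the one-sided alternative of excess unconverted reads (methylation
   can only inflate the count above ``r``), so the p-value is the upper tail
   ``P(X >= mc)``.
3. Benjamini–Hochberg correct across all tested sites of the sample
   (contexts and strands pooled) and call a site methylated when its
   q-value is at most ``alpha`` and it has at least one methylated read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountTable

__all__ = [
    "NonConversionEstimate",
    "SiteCalls",
    "estimate_nonconversion",
    "binomial_site_pvalue",
    "bh_adjust",
    "call_sites",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_COV = 3


class EstimationError(ValueError):
    """Control contig missing or carrying no coverage."""


@dataclass(frozen=True)
class NonConversionEstimate:
    """Pooled non-conversion rate from the unmethylated control contig.

    ``rate`` is floored at ``1 / (total_cov + 1)`` when no methylated read is
    observed: zero observed failures bounds the rate, it does not prove zero.
    ``stderr`` is the binomial standard error of the pooled fraction.
    """

    rate: float
    control_contig: str
    n_sites: int
    total_cov: int
    total_mc: int

    @property
    def stderr(self) -> float:
        if self.total_cov == 0:
            return float("nan")
        return float(np.sqrt(self.rate * (1.0 - self.rate) / self.total_cov))


def estimate_nonconversion(table: CountTable, control_contig: str) -> NonConversionEstimate:
    """Estimate r = sum(mc) / sum(cov) over the control contig's covered sites."""
    sub = table.subset(control_contig)
    if len(sub) == 0:
        raise EstimationError(f"control contig {control_contig!r} absent from count table")
    covered = sub[sub["cov"] > 0]
    total_cov = int(covered["cov"].sum())
    total_mc = int(covered["mc"].sum())
    if total_cov == 0:
        raise EstimationError(f"control contig {control_contig!r} has zero coverage")
    rate = total_mc / total_cov
    if rate == 0.0:
        rate = 1.0 / (total_cov + 1)
    return NonConversionEstimate(
        rate=rate,
        control_contig=control_contig,
        n_sites=int(len(covered)),
        total_cov=total_cov,
        total_mc=total_mc,
    )


def binomial_site_pvalue(mc: int, cov: int, r: float) -> float:
    """One-sided upper-tail binomial p-value, P(X >= mc) for X ~ Bin(cov, r).

    ``r`` must lie in (0, 1]; the boundary r = 1 makes the test powerless
    (p = 1 everywhere), which is the correct degenerate behaviour when the
    control contig itself looks fully methylated.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError(f"non-conversion rate r={r} outside (0, 1]")
    if not 0 <= mc <= cov:
        raise ValueError(f"require 0 <= mc <= cov, got mc={mc}, cov={cov}")
    return float(stats.binom.sf(mc - 1, cov, r))


def _binomial_pvalues(mc: np.ndarray, cov: np.ndarray, r: float) -> np.ndarray:
    if not 0.0 < r <= 1.0:
        raise ValueError(f"non-conversion rate r={r} outside (0, 1]")
    return stats.binom.sf(mc - 1, cov, r)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SiteCalls:
    """Per-site calls: the count table with p, q and status columns appended.

    ``status`` is ``methylated``, ``unmethylated`` or ``untested``
    (``untested`` iff ``cov < min_cov``).
    """

    frame: pd.DataFrame
    nonconversion: NonConversionEstimate
    alpha: float
    min_cov: int

    @property
    def n_tested(self) -> int:
        return int((self.frame["status"] != "untested").sum())

    @property
    def n_methylated(self) -> int:
        return int((self.frame["status"] == "methylated").sum())

    def methylated_sites(self) -> pd.DataFrame:
        return self.frame[self.frame["status"] == "methylated"]

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, nonconversion=None, alpha=DEFAULT_ALPHA, min_cov=DEFAULT_MIN_COV):
        frame = pd.read_csv(path, sep="\t")
        return cls(frame=frame, nonconversion=nonconversion, alpha=alpha, min_cov=min_cov)


def call_sites(
    table: CountTable,
    estimate: NonConversionEstimate,
    alpha: float = DEFAULT_ALPHA,
    min_cov: int = DEFAULT_MIN_COV,
) -> SiteCalls:
    """Binomial-test every covered site and BH-correct genome-wide.

    Sites with ``cov < min_cov`` are left untested (p and q are NaN). A site
    is called methylated iff its q-value is at most ``alpha`` and ``mc > 0``;
    the ``mc > 0`` guard keeps pathological non-conversion estimates from
    labelling zero-signal sites.
    """
    if len(table) == 0:
        raise ValueError("empty count table")
    df = table.frame.copy()
    tested = (df["cov"] >= min_cov).to_numpy()
    p = np.full(len(df), np.nan)
    q = np.full(len(df), np.nan)
    if tested.any():
        p[tested] = _binomial_pvalues(
            df.loc[tested, "mc"].to_numpy(), df.loc[tested, "cov"].to_numpy(), estimate.rate
        )
        q[tested] = bh_adjust(p[tested])
    status = np.where(
        ~tested,
        "untested",
        np.where((q <= alpha) & (df["mc"].to_numpy() > 0), "methylated", "unmethylated"),
    )
    df["p"] = p
    df["q"] = q
    df["status"] = status
    return SiteCalls(frame=df, nonconversion=estimate, alpha=alpha, min_cov=min_cov)
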