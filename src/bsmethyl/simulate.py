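"""Synthetic bisulfite data with known ground truth.

The generator emulates what a post-alignment MethylC-seq pipeline sees for
a small multi-contig fungal-style genome: a few nuclear contigs carrying
kilobase-scale methylated domains, plus a fully unmethylated organellar
control contig ("mitochondria") from which the bisulfite non-conversion
rate is measured. It emits per-cytosine count tables directly (not reads):
every downstream stage operates on counts, so alignment is out of scope.

Noise model, per cytosine *i* with true methylation probability ``m_i`` and
non-conversion rate ``r``::

    cov_i ~ Poisson(lambda)
    mc_i  ~ Binomial(cov_i, m_i + (1 - m_i) * r)

i.e. a read reports "methylated" if the molecule is methylated *or* an
unmethylated cytosine escaped conversion. This is exactly the null/alternative
family the downstream binomial caller tests against, so simulated data are
matched to the inference.

All randomness flows through :func:`numpy.random.default_rng` seeded from
the config; identical seeds give byte-identical genomes and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .counts import CountTable
from .genome import ReferenceGenome

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationError",
    "generate_genome",
    "simulate_count_table",
]

CONTROL_CONTIG = "mitochondria"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    """Raised when a simulation config is invalid or unsatisfiable."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated study.

    Defaults describe a desk-scale version of a wild-type Neurospora-like
    sample: two ~150 kb nuclear contigs with twenty non-overlapping 2–5 kb
    methylated domains, a 40 kb unmethylated control contig, ~15x Poisson
    coverage per replicate and a 0.5% bisulfite non-conversion rate.
    """

    n_contigs: int = 2
    contig_length: int = 150_000
    gc_fraction: float = 0.5
    control_contig_length: int = 40_000
    n_regions: int = 20
    region_length_range: tuple[int, int] = (2_000, 5_000)
    region_level_range: tuple[float, float] = (0.6, 0.9)
    background_level: float = 0.0
    coverage_lambda: float = 15.0
    nonconversion_rate: float = 0.005
    n_replicates: int = 2
    seed: int = 0
    # regions are kept at least this far apart; > the 1 kb DMS merge distance
    # so neighbouring truth domains cannot be chained into one region
    min_region_separation: int = 2_000

    def validate(self) -> None:
        for name in ("gc_fraction", "background_level", "nonconversion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        lo, hi = self.region_level_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise SimulationError(f"region_level_range {self.region_level_range} invalid")
        llo, lhi = self.region_length_range
        if not (0 < llo <= lhi):
            raise SimulationError(f"region_length_range {self.region_length_range} invalid")
        if self.min_region_separation < 1_000:
            raise SimulationError("planted regions must be kept >= 1 kb apart")
        if self.n_contigs < 1 or self.contig_length < 1:
            raise SimulationError("need at least one nuclear contig of positive length")
        if self.coverage_lambda < 0:
            raise SimulationError("coverage_lambda must be non-negative")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated genome.

    ``regions`` are 0-based half-open ``(contig, start, end, level)`` tuples;
    ``cytosines`` is the enumerated cytosine table with a ``p`` column giving
    each site's true methylation probability (region level inside a planted
    domain, the background level elsewhere, and exactly 0 everywhere on the
    control contig).
    """

    regions: list[tuple[str, int, int, float]]
    cytosines: pd.DataFrame
    nonconversion_rate: float
    background_level: float
    seed: int
    config: SimulationConfig | None = field(default=None, repr=False)

    def probability_for(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """True methylation probability at 1-based ``positions`` on ``contig``."""
        positions = np.asarray(positions, dtype=np.int64)
        if contig == CONTROL_CONTIG:
            return np.zeros(positions.shape)
        p = np.full(positions.shape, self.background_level, dtype=float)
        for ctg, start, end, level in self.regions:
            if ctg == contig:
                inside = (positions - 1 >= start) & (positions - 1 < end)
                p[inside] = level
        return p

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.regions, columns=["contig", "start", "end", "level"])

    def to_bed(self, path) -> None:
        """Truth regions as BED4 (0-based half-open)."""
        with open(path, "w") as fh:
            fh.write("# planted methylated regions (truth)\n")
            for i, (ctg, start, end, level) in enumerate(self.regions):
                fh.write(f"{ctg}\t{start}\t{end}\tregion_{i:04d}_m{level:.3f}\n")

    def manifest(self) -> dict:
        out = {
            "seed": self.seed,
            "nonconversion_rate": self.nonconversion_rate,
            "background_level": self.background_level,
            "n_regions": len(self.regions),
            "planted_bases": int(sum(e - s for _, s, e, _ in self.regions)),
            "n_cytosines": int(len(self.cytosines)),
        }
        if self.config is not None:
            out["config"] = asdict(self.config)
        return out


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=probs)
    return arr.tobytes().decode("ascii")


def _place_regions(
    rng: np.random.Generator,
    contig_names: list[str],
    contig_length: int,
    n_regions: int,
    length_range: tuple[int, int],
    level_range: tuple[float, float],
    sep: int,
) -> list[tuple[str, int, int, float]]:
    """Place non-overlapping regions >= ``sep`` apart and ``sep`` off contig ends."""
    per_contig = [n_regions // len(contig_names)] * len(contig_names)
    for i in range(n_regions % len(contig_names)):
        per_contig[i] += 1
    regions: list[tuple[str, int, int, float]] = []
    for name, k in zip(contig_names, per_contig):
        if k == 0:
            continue
        lengths = rng.integers(length_range[0], length_range[1] + 1, size=k)
        slack = contig_length - int(lengths.sum()) - (k + 1) * sep
        if slack < 0:
            raise SimulationError(
                f"cannot fit {k} regions of up to {length_range[1]} bp with "
                f"{sep} bp separation into contig of {contig_length} bp"
            )
        gaps = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        cursor = sep + int(gaps[0])
        for j in range(k):
            start = cursor
            end = start + int(lengths[j])
            level = float(rng.uniform(level_range[0], level_range[1]))
            regions.append((name, start, end, level))
            cursor = end + sep + int(gaps[j + 1])
    return regions


def generate_genome(config: SimulationConfig) -> tuple[ReferenceGenome, SimulationTruth]:
    """Generate a random genome with planted methylated domains.

    Returns the genome (nuclear contigs plus the unmethylated control contig)
    and the simulation truth. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    contigs: dict[str, str] = {}
    nuclear = [f"contig_{i + 1}" for i in range(config.n_contigs)]
    for name in nuclear:
        contigs[name] = _random_sequence(rng, config.contig_length, config.gc_fraction)
    if config.control_contig_length > 0:
        contigs[CONTROL_CONTIG] = _random_sequence(
            rng, config.control_contig_length, config.gc_fraction
        )
    regions = (
        _place_regions(
            rng,
            nuclear,
            config.contig_length,
            config.n_regions,
            config.region_length_range,
            config.region_level_range,
            config.min_region_separation,
        )
        if config.n_regions > 0
        else []
    )
    genome = ReferenceGenome(
        contigs=contigs,
        control_contig=CONTROL_CONTIG if config.control_contig_length > 0 else None,
    )
    cyt = genome.cytosines().copy()
    if len(cyt):
        p = np.full(len(cyt), config.background_level, dtype=float)
        pos0 = cyt["pos"].to_numpy() - 1
        ctg = cyt["contig"].to_numpy()
        for name, start, end, level in regions:
            p[(ctg == name) & (pos0 >= start) & (pos0 < end)] = level
        p[ctg == CONTROL_CONTIG] = 0.0
        cyt["p"] = p
    else:
        cyt["p"] = pd.Series(dtype=float)
    truth = SimulationTruth(
        regions=regions,
        cytosines=cyt,
        nonconversion_rate=config.nonconversion_rate,
        background_level=config.background_level,
        seed=config.seed,
        config=config,
    )
    return genome, truth


def simulate_count_table(
    truth: SimulationTruth,
    coverage_lambda: float,
    nonconversion_rate: float,
    seed: int,
) -> CountTable:
    """Draw one sample's count table from the truth.

    ``cov ~ Poisson(coverage_lambda)`` and
    ``mc ~ Binomial(cov, m + (1 - m) * r)`` independently per cytosine.
    """
    if coverage_lambda < 0:
        raise SimulationError(f"coverage_lambda={coverage_lambda} must be non-negative")
    if not 0.0 <= nonconversion_rate <= 1.0:
        raise SimulationError(f"nonconversion_rate={nonconversion_rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    cyt = truth.cytosines
    n = len(cyt)
    cov = rng.poisson(coverage_lambda, size=n)
    m = cyt["p"].to_numpy() if n else np.array([])
    p_eff = m + (1.0 - m) * nonconversion_rate
    mc = rng.binomial(cov, p_eff) if n else np.array([], dtype=np.int64)
    df = pd.DataFrame(
        {
            "contig": cyt["contig"].to_numpy() if n else pd.Series(dtype=str),
            "pos": cyt["pos"].to_numpy() if n else pd.Series(dtype=np.int64),
            "strand": cyt["strand"].to_numpy() if n else pd.Series(dtype=str),
            "context": cyt["context"].to_numpy() if n else pd.Series(dtype=str),
            "mc": mc,
            "cov": cov,
        }
    )
    return CountTable(df)


def simulate_replicates(
    truth: SimulationTruth,
    n_replicates: int,
    coverage_lambda: float,
    nonconversion_rate: float,
    seed: int,
) -> list[CountTable]:
    """Independent replicate tables; replicate *i* uses child seed ``seed + i``."""
    return [
        simulate_count_table(truth, coverage_lambda, nonconversion_rate, seed + i)
        for i in range(n_replicates)
    ]
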