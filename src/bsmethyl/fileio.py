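"""Region/BED IO and run manifests.

Coordinate conventions: count tables and all in-memory site tables use
1-based positions; BED files are 0-based half-open, sorted by contig then
start.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, asdict

from .dmr import MethylatedRegion

__all__ = ["write_regions_bed", "read_bed", "RunManifest", "parse_region"]


def write_regions_bed(regions: list[MethylatedRegion], path) -> None:
    """Write DMRs as BED6 (name = region id, score = DMS count, strand '.')."""
    ordered = sorted(regions, key=lambda r: (r.contig, r.start, r.end))
    prev: MethylatedRegion | None = None
    for reg in ordered:
        if reg.end <= reg.start:
            raise ValueError(f"region {reg.name or reg.interval()} is empty or inverted")
        if prev is not None and prev.contig == reg.contig and reg.start < prev.end:
            raise ValueError(f"overlapping regions {prev.name} and {reg.name}")
        prev = reg
    with open(path, "w") as fh:
        fh.write("# BED6: contig start end name n_dms strand\n")
        for i, reg in enumerate(ordered):
            name = reg.name or f"DMR_{i + 1:04d}"
            fh.write(f"{reg.contig}\t{reg.start}\t{reg.end}\t{name}\t{reg.n_dms}\t.\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED3+ intervals as (contig, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}, line {lineno}: fewer than 3 BED columns")
            name = parts[3] if len(parts) > 3 else f"interval_{lineno}"
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse 'contig:start-end' (0-based half-open) region syntax."""
    try:
        contig, span = text.rsplit(":", 1)
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"cannot parse region {text!r}; expected contig:start-end") from exc
    if end <= start or start < 0:
        raise ValueError(f"invalid region {text!r}")
    return contig, start, end


@dataclass
class RunManifest:
    """Reproducibility record written alongside every pipeline output."""

    subcommand: str
    parameters: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    seed: int | None = None
    tool_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.tool_version:
            from . import __version__

            self.tool_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
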