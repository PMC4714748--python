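"""In-silico methylation-sensitive restriction digests (Southern-blot logic).

BfuCI and DpnII are GATC isoschizomers that differ in sensitivity to
cytosine methylation: BfuCI is blocked when the site carries 5mC, DpnII is
not. Digesting the same DNA with both and probing a region therefore reveals
methylation as larger fragments in the sensitive digest — the classic
Southern assay for fungal 5mC. This module reproduces that logic on a
single linear molecule with a binary per-cytosine methylation map.

Blocking rule: a methylation-sensitive enzyme skips a recognition site when
*any* cytosine within the site's footprint (either strand, so any of the
4 bp of GATC) is methylated. Cuts are placed at the site start; fragment
sizes are offset-invariant for same-site isoschizomers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Enzyme",
    "FragmentSet",
    "BFUCI",
    "DPNII",
    "find_recognition_sites",
    "digest",
    "probe_fragments",
]

_DNA = set("ACGT")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with an exact recognition sequence."""

    name: str
    recognition: str = "GATC"
    methylation_sensitive: bool = False

    def __post_init__(self) -> None:
        site = self.recognition.upper()
        if not site or not set(site) <= _DNA:
            raise ValueError(f"recognition sequence {self.recognition!r} must be ACGT+")
        object.__setattr__(self, "recognition", site)


BFUCI = Enzyme("BfuCI", "GATC", methylation_sensitive=True)
DPNII = Enzyme("DpnII", "GATC", methylation_sensitive=False)


@dataclass
class FragmentSet:
    """Ordered fragments tiling one linear contig exactly."""

    length: int
    cuts: tuple[int, ...]
    fragments: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        bounds = [0, *self.cuts, self.length]
        self.fragments = [
            (bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
            if bounds[i + 1] > bounds[i]
        ]

    @property
    def lengths(self) -> list[int]:
        return [e - s for s, e in self.fragments]

    def __len__(self) -> int:
        return len(self.fragments)


def find_recognition_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """0-based start positions of exact recognition-site matches.

    Ambiguous or lowercase-soft-masked bases are uppercased first; any
    non-ACGT character simply never matches an exact ACGT site.
    """
    seq = sequence.upper()
    site = enzyme.recognition
    out = []
    i = seq.find(site)
    while i != -1:
        out.append(i)
        i = seq.find(site, i + 1)
    return out


def digest(sequence: str, methylated_positions, enzyme: Enzyme) -> FragmentSet:
    """Digest one linear molecule given a set of methylated cytosine positions.

    ``methylated_positions`` holds 0-based coordinates of methylated
    cytosines (either strand); positions absent from the set are
    unmethylated. A methylation-sensitive enzyme does not cut a site when
    any methylated position falls within its footprint. Terminal fragments
    are included; cutting at position 0 is a no-op on a linear molecule.
    """
    sites = find_recognition_sites(sequence, enzyme)
    width = len(enzyme.recognition)
    if enzyme.methylation_sensitive and methylated_positions:
        meth = np.asarray(sorted(methylated_positions), dtype=np.int64)
        kept = []
        for s in sites:
            lo = np.searchsorted(meth, s, side="left")
            blocked = lo < meth.size and meth[lo] < s + width
            if not blocked:
                kept.append(s)
        sites = kept
    cuts = tuple(s for s in sites if 0 < s < len(sequence))
    return FragmentSet(length=len(sequence), cuts=cuts)


def probe_fragments(fragments: FragmentSet, probe_interval: tuple[int, int]) -> list[int]:
    """Lengths of fragments overlapping the probe by >= 1 bp, gel-ladder order.

    ``probe_interval`` is 0-based half-open. Returns lengths sorted
    descending (largest band first, as read off a gel).
    """
    p_start, p_end = probe_interval
    if p_end <= p_start:
        raise ValueError(f"empty probe interval {probe_interval}")
    hits = [e - s for s, e in fragments.fragments if s < p_end and e > p_start]
    return sorted(hits, reverse=True)


def methylated_positions_from_calls(site_calls, contig: str) -> set[int]:
    """0-based methylated-cytosine positions on one contig from a SiteCalls table."""
    df = site_calls.frame
    sel = (df["contig"] == contig) & (df["status"] == "methylated")
    return set((df.loc[sel, "pos"] - 1).tolist())
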