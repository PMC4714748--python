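"""Reference genome container and cytosine enumeration.

A genome is a small ordered collection of linear contigs, one of which may
be flagged as the unmethylated control (in *Neurospora crassa*-style data
that is the mitochondrial sequence, which carries no 5mC and therefore
measures the bisulfite non-conversion rate).

Cytosines are enumerated on both strands with their sequence context:

* ``CG``  — C immediately followed by G (on the cytosine's strand);
* ``CHG`` — C, any non-G base, then G;
* ``CHH`` — everything else, including cytosines too close to a contig end
  to have two downstream bases.

Positions are 1-based throughout the in-memory tables; interval inputs
(regions, BED) are 0-based half-open, matching the conventions of the
allc and BED ecosystems respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["ReferenceGenome", "enumerate_cytosines"]

_CYTOSINE_COLUMNS = ["contig", "pos", "strand", "context"]


def _contexts_forward(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positions (0-based) and contexts of forward-strand cytosines."""
    is_c = arr == ord("C")
    idx = np.flatnonzero(is_c)
    if idx.size == 0:
        return idx, np.array([], dtype=object)
    n = arr.size
    nxt1 = np.full(idx.size, -1, dtype=np.int64)
    nxt2 = np.full(idx.size, -1, dtype=np.int64)
    ok1 = idx + 1 < n
    ok2 = idx + 2 < n
    nxt1[ok1] = arr[idx[ok1] + 1]
    nxt2[ok2] = arr[idx[ok2] + 2]
    ctx = np.where(
        nxt1 == ord("G"), "CG", np.where(nxt2 == ord("G"), "CHG", "CHH")
    ).astype(object)
    return idx, ctx


def _contexts_reverse(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reverse-strand cytosines appear as G on the forward sequence."""
    is_g = arr == ord("G")
    idx = np.flatnonzero(is_g)
    if idx.size == 0:
        return idx, np.array([], dtype=object)
    prv1 = np.full(idx.size, -1, dtype=np.int64)
    prv2 = np.full(idx.size, -1, dtype=np.int64)
    ok1 = idx - 1 >= 0
    ok2 = idx - 2 >= 0
    prv1[ok1] = arr[idx[ok1] - 1]
    prv2[ok2] = arr[idx[ok2] - 2]
    ctx = np.where(
        prv1 == ord("C"), "CG", np.where(prv2 == ord("C"), "CHG", "CHH")
    ).astype(object)
    return idx, ctx


def enumerate_cytosines(sequence: str, contig: str) -> pd.DataFrame:
    """Enumerate every cytosine of one contig on both strands.

    Returns a frame with columns ``contig, pos (1-based), strand, context``
    sorted by position (forward-strand cytosine first at a shared position,
    which cannot occur for standard bases).
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8).copy()
    fw_idx, fw_ctx = _contexts_forward(arr)
    rv_idx, rv_ctx = _contexts_reverse(arr)
    pos = np.concatenate([fw_idx, rv_idx]) + 1
    strand = np.concatenate(
        [np.full(fw_idx.size, "+", dtype=object), np.full(rv_idx.size, "-", dtype=object)]
    )
    ctx = np.concatenate([fw_ctx, rv_ctx])
    df = pd.DataFrame(
        {"contig": contig, "pos": pos.astype(np.int64), "strand": strand, "context": ctx}
    )
    return df.sort_values(["pos", "strand"], kind="mergesort", ignore_index=True)


@dataclass
class ReferenceGenome:
    """Contig sequences plus an optional unmethylated control contig flag.

    Parameters
    ----------
    contigs
        Mapping of contig name to uppercase DNA sequence, in genome order.
    control_contig
        Name of the contig known to be fully unmethylated, or ``None``.
    """

    contigs: dict[str, str]
    control_contig: str | None = None
    _cytosines: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.control_contig is not None and self.control_contig not in self.contigs:
            raise KeyError(f"control contig {self.control_contig!r} not in genome")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def cytosines(self) -> pd.DataFrame:
        """All cytosines of the genome (both strands), cached after first call."""
        if self._cytosines is None:
            parts = [enumerate_cytosines(seq, name) for name, seq in self.contigs.items()]
            if parts:
                self._cytosines = pd.concat(parts, ignore_index=True)
            else:
                self._cytosines = pd.DataFrame(columns=_CYTOSINE_COLUMNS)
        return self._cytosines

    # --- FASTA round trip -------------------------------------------------
    def to_fasta(self, path) -> None:
        """Write the genome as 60-column-wrapped FASTA."""
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.contigs.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def from_fasta(cls, path, control_contig: str | None = None) -> "ReferenceGenome":
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not contigs:
            raise ValueError(f"no sequences found in {path}")
        return cls(contigs=contigs, control_contig=control_contig)
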