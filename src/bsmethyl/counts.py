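"""Per-cytosine count tables and their on-disk dialects.

The canonical in-memory container is a validated :class:`pandas.DataFrame`
wrapped by :class:`CountTable`, one row per cytosine per strand::

    contig  pos  strand  context  mc  cov

``pos`` is 1-based; ``mc`` is the methylated (unconverted) read count and
``cov`` the total aligned read count, so ``0 <= mc <= cov``.

Two tab-separated dialects are supported, mirroring the two formats the
bisulfite ecosystem splits along:

* **allc** — ``contig  pos  strand  context  mc  cov  flag`` (the trailing
  binary call flag is ignored on read and written as ``mc > 0``);
* **cx_report** — Bismark CX-report style,
  ``contig  pos  strand  count_meth  count_unmeth  context  tricontext``
  with ``cov = count_meth + count_unmeth``. The trinucleotide column is not
  retained; on write it repeats the context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CountTable", "CountTableError"]

COLUMNS = ["contig", "pos", "strand", "context", "mc", "cov"]
_VALID_STRANDS = {"+", "-"}
_VALID_CONTEXTS = {"CG", "CHG", "CHH"}


class CountTableError(ValueError):
    """Raised for malformed or invariant-violating count tables."""


def _validate(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"{source}: missing columns {missing}")
    df = df[COLUMNS].copy()
    for col in ("pos", "mc", "cov"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            line = int(df.index[bad][0]) + 1
            raise CountTableError(f"{source}, line {line}: non-numeric {col} field")
        df[col] = coerced.astype(np.int64)
    bad = df.index[(df["mc"] < 0) | (df["cov"] < 0) | (df["mc"] > df["cov"])]
    if len(bad):
        line = int(bad[0]) + 1
        row = df.loc[bad[0]]
        raise CountTableError(
            f"{source}, line {line}: mc={row['mc']} cov={row['cov']} violates 0 <= mc <= cov"
        )
    bad_strand = ~df["strand"].isin(_VALID_STRANDS)
    if bad_strand.any():
        line = int(df.index[bad_strand][0]) + 1
        raise CountTableError(f"{source}, line {line}: strand must be + or -")
    if df.duplicated(subset=["contig", "pos", "strand"]).any():
        dup = df[df.duplicated(subset=["contig", "pos", "strand"])].iloc[0]
        raise CountTableError(
            f"{source}: duplicate site ({dup['contig']}, {dup['pos']}, {dup['strand']})"
        )
    return df.reset_index(drop=True)


@dataclass
class CountTable:
    """One sample's per-cytosine bisulfite counts."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = _validate(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def contigs(self) -> list[str]:
        return list(dict.fromkeys(self.frame["contig"]))

    def subset(self, contig: str) -> pd.DataFrame:
        return self.frame[self.frame["contig"] == contig]

    # --- constructors -----------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(df)

    @classmethod
    def read(cls, path, dialect: str = "allc") -> "CountTable":
        if dialect == "allc":
            return cls.read_allc(path)
        if dialect == "cx_report":
            return cls.read_cx_report(path)
        raise ValueError(f"unknown count-table dialect {dialect!r}")

    @classmethod
    def read_allc(cls, path) -> "CountTable":
        names = COLUMNS + ["flag"]
        try:
            df = pd.read_csv(
                path, sep="\t", names=names, comment="#", header=None,
                dtype={"contig": str, "strand": str, "context": str},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise CountTableError(f"{path}: unparseable allc file ({exc})") from exc
        if df["pos"].isna().any() or df["mc"].isna().any() or df["cov"].isna().any():
            line = int(df.index[df[["pos", "mc", "cov"]].isna().any(axis=1)][0]) + 1
            raise CountTableError(f"{path}, line {line}: malformed row")
        return cls(_validate(df.drop(columns=["flag"]), source=str(path)))

    @classmethod
    def read_cx_report(cls, path) -> "CountTable":
        names = ["contig", "pos", "strand", "count_meth", "count_unmeth", "context", "tri"]
        try:
            df = pd.read_csv(
                path, sep="\t", names=names, comment="#", header=None,
                dtype={"contig": str, "strand": str, "context": str, "tri": str},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise CountTableError(f"{path}: unparseable CX report ({exc})") from exc
        if df[["pos", "count_meth", "count_unmeth"]].isna().any(axis=None):
            line = int(
                df.index[df[["pos", "count_meth", "count_unmeth"]].isna().any(axis=1)][0]
            ) + 1
            raise CountTableError(f"{path}, line {line}: malformed row")
        out = pd.DataFrame(
            {
                "contig": df["contig"],
                "pos": df["pos"],
                "strand": df["strand"],
                "context": df["context"],
                "mc": df["count_meth"],
                "cov": df["count_meth"] + df["count_unmeth"],
            }
        )
        return cls(_validate(out, source=str(path)))

    # --- writers ----------------------------------------------------------
    def write(self, path, dialect: str = "allc") -> None:
        if dialect == "allc":
            self.write_allc(path)
        elif dialect == "cx_report":
            self.write_cx_report(path)
        else:
            raise ValueError(f"unknown count-table dialect {dialect!r}")

    def write_allc(self, path) -> None:
        df = self.frame.copy()
        df["flag"] = (df["mc"] > 0).astype(int)
        df.to_csv(path, sep="\t", header=False, index=False)

    def write_cx_report(self, path) -> None:
        df = pd.DataFrame(
            {
                "contig": self.frame["contig"],
                "pos": self.frame["pos"],
                "strand": self.frame["strand"],
                "count_meth": self.frame["mc"],
                "count_unmeth": self.frame["cov"] - self.frame["mc"],
                "context": self.frame["context"],
                "tri": self.frame["context"],
            }
        )
        df.to_csv(path, sep="\t", header=False, index=False)

    # --- algebra ----------------------------------------------------------
    @staticmethod
    def pool(tables: list["CountTable"]) -> "CountTable":
        """Sum mc and cov site-wise across replicate tables (outer union)."""
        if not tables:
            raise ValueError("no tables to pool")
        if len(tables) == 1:
            return CountTable(tables[0].frame.copy())
        cat = pd.concat([t.frame for t in tables], ignore_index=True)
        pooled = (
            cat.groupby(["contig", "pos", "strand", "context"], as_index=False, sort=True)
            .agg(mc=("mc", "sum"), cov=("cov", "sum"))
        )
        return CountTable(pooled[COLUMNS])
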