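"""Reading/writing Bismark-style methylation files and single-cell QC filters.

Internal coordinate convention is 1-based inclusive (the Bismark ``.cov``
convention); all BED output is 0-based half-open. Gzipped inputs are read
transparently (pandas dispatches on the ``.gz`` suffix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Expected ceiling of unique reads per CpG in a single diplotene nucleus:
#: four chromatids, each contributing two bisulfite-converted strands.
DIPLOTENE_MAX_DEPTH = 4 * 2

_COV_COLUMNS = ["chrom", "start", "end", "percent", "meth", "unmeth"]
_CX_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class CpGRecord:
    """One CpG dinucleotide: methylated/unmethylated call counts at a position.

    ``pos`` is the 1-based coordinate of the cytosine on the plus strand of
    the dinucleotide. ``meth + unmeth`` is the read depth n_t used by the HMM.
    """

    chrom: str
    pos: int
    meth: int
    unmeth: int

    @property
    def depth(self) -> int:
        return self.meth + self.unmeth


@dataclass
class MethylomeTable:
    """Per-CpG methylation counts for one sample, sorted by (chrom, pos).

    Wraps a DataFrame with columns ``chrom`` (str), ``pos`` (1-based int),
    ``meth``, ``unmeth`` (non-negative ints) and optionally ``strand``.
    Positions are unique within each chromosome.
    """

    df: pd.DataFrame
    sample_id: str = ""

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "meth", "unmeth"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"MethylomeTable missing columns: {missing}")
        df = self.df
        if len(df):
            if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
                raise ValueError("negative counts in methylome table")
            if (df["pos"] < 1).any():
                raise ValueError("positions must be 1-based (>= 1)")
            if not df[["chrom", "pos"]].equals(
                df[["chrom", "pos"]].sort_values(["chrom", "pos"])
            ):
                logger.info("methylome table was unsorted; sorting on load")
                self.df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
                    drop=True
                )
            dup = self.df.duplicated(subset=["chrom", "pos"])
            if dup.any():
                i = int(np.flatnonzero(dup.to_numpy())[0])
                row = self.df.iloc[i]
                raise ParseError(
                    f"duplicate CpG position {row.chrom}:{row.pos} in table"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def depth(self) -> np.ndarray:
        return (self.df["meth"] + self.df["unmeth"]).to_numpy()

    def records(self) -> Iterable[CpGRecord]:
        for row in self.df.itertuples(index=False):
            yield CpGRecord(row.chrom, int(row.pos), int(row.meth), int(row.unmeth))

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str],
        pos: Sequence[int],
        meth: Sequence[int],
        unmeth: Sequence[int],
        sample_id: str = "",
    ) -> "MethylomeTable":
        df = pd.DataFrame(
            {
                "chrom": np.asarray(chrom, dtype=object),
                "pos": np.asarray(pos, dtype=np.int64),
                "meth": np.asarray(meth, dtype=np.int64),
                "unmeth": np.asarray(unmeth, dtype=np.int64),
            }
        )
        return cls(df, sample_id=sample_id)


def _coerce_int(df: pd.DataFrame, col: str, path: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ParseError(f"{path}: malformed value in column '{col}' at line {line}")
    return out.astype(np.int64)


def read_cov(
    path: str | Path,
    sample_id: str | None = None,
    dedup: str = "error",
    drop_uncovered: bool = False,
) -> MethylomeTable:
    """Read a Bismark coverage file (6 columns, 1-based inclusive).

    The percent-methylation column is ignored and recomputed from counts.
    ``dedup``: "error" (default) rejects duplicated positions, "sum" merges
    their counts. ``drop_uncovered`` removes zero-depth rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=_COV_COLUMNS,
            dtype={"chrom": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_COV_COLUMNS)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(df) and df[["start", "end", "meth", "unmeth"]].isna().any().any():
        line = int(df[["start", "end", "meth", "unmeth"]].isna().any(axis=1).idxmax()) + 1
        raise ParseError(f"{path}: malformed line {line}")
    if len(df):
        for col in ("start", "meth", "unmeth"):
            df[col] = _coerce_int(df, col, str(path))
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(object) if len(df) else [],
            "pos": df["start"] if len(df) else [],
            "meth": df["meth"] if len(df) else [],
            "unmeth": df["unmeth"] if len(df) else [],
        }
    )
    out = _apply_dedup(out, dedup, str(path))
    if drop_uncovered and len(out):
        out = out[(out["meth"] + out["unmeth"]) > 0].reset_index(drop=True)
    return MethylomeTable(
        out.reset_index(drop=True), sample_id=sample_id or path.stem
    )


def _apply_dedup(df: pd.DataFrame, dedup: str, path: str) -> pd.DataFrame:
    if not len(df):
        return df
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if not df.duplicated(subset=["chrom", "pos"]).any():
        return df
    if dedup == "sum":
        logger.info("%s: merging duplicated positions by summing counts", path)
        return (
            df.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "unmeth"]]
            .sum()
        )
    dup = df[df.duplicated(subset=["chrom", "pos"])].iloc[0]
    raise ParseError(f"{path}: duplicated CpG position {dup.chrom}:{dup.pos}")


def read_cx_report(
    path: str | Path,
    sample_id: str | None = None,
    merge: bool = True,
    drop_uncovered: bool = False,
) -> MethylomeTable:
    """Read a Bismark cytosine (CX / CpG) report, keeping CpG-context rows.

    With ``merge=True`` (default) plus- and minus-strand calls of the same
    dinucleotide are summed onto the plus-strand coordinate.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=_CX_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "tri": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_CX_COLUMNS)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(df):
        df["pos"] = _coerce_int(df, "pos", str(path))
        df["meth"] = _coerce_int(df, "meth", str(path))
        df["unmeth"] = _coerce_int(df, "unmeth", str(path))
        df = df[df["context"] == "CpG"].reset_index(drop=True)
    if not len(df):
        logger.warning("%s: no CpG-context rows found", path)
        return MethylomeTable.from_arrays([], [], [], [], sample_id=sample_id or path.stem)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(object),
            "pos": df["pos"],
            "meth": df["meth"],
            "unmeth": df["unmeth"],
            "strand": df["strand"].astype(object),
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    table = MethylomeTable(out, sample_id=sample_id or path.stem)
    if merge:
        table = merge_strands(table)
    if drop_uncovered:
        d = table.df
        table = MethylomeTable(
            d[(d["meth"] + d["unmeth"]) > 0].reset_index(drop=True),
            sample_id=table.sample_id,
        )
    return table


def merge_strands(table: MethylomeTable) -> MethylomeTable:
    """Collapse strand-resolved CpG calls onto the plus-strand coordinate.

    A minus-strand cytosine at position p belongs to the dinucleotide whose
    plus-strand cytosine sits at p - 1; counts of the pair are summed. Lone
    minus-strand records are remapped to p - 1. Total counts are conserved.
    """
    df = table.df
    if "strand" not in df.columns or not len(df):
        out = df.drop(columns=[c for c in ("strand",) if c in df.columns])
        return MethylomeTable(out.reset_index(drop=True), sample_id=table.sample_id)
    pos = df["pos"].to_numpy(np.int64).copy()
    minus = (df["strand"] == "-").to_numpy()
    pos[minus] -= 1
    merged = (
        pd.DataFrame(
            {
                "chrom": df["chrom"].to_numpy(object),
                "pos": pos,
                "meth": df["meth"].to_numpy(np.int64),
                "unmeth": df["unmeth"].to_numpy(np.int64),
            }
        )
        .groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "unmeth"]]
        .sum()
    )
    return MethylomeTable(merged, sample_id=table.sample_id)


def filter_coverage_artifacts(
    table: MethylomeTable, max_depth: int = DIPLOTENE_MAX_DEPTH
) -> tuple[MethylomeTable, float]:
    """Remove CpGs covered more than ``max_depth`` times.

    In a single diplotene nucleus at most eight unique reads can cover one
    CpG dinucleotide (four chromatids, two converted strands each), so deeper
    sites are treated as artifacts or somatic contamination. Returns the
    filtered table and the artifact fraction among sites with depth >= 1.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    depth = table.depth
    covered = depth >= 1
    removed = depth > max_depth
    n_covered = int(covered.sum())
    frac = float(removed.sum() / n_covered) if n_covered else 0.0
    kept = MethylomeTable(
        table.df[~removed].reset_index(drop=True), sample_id=table.sample_id
    )
    return kept, frac


def write_cov(table: MethylomeTable, path: str | Path) -> None:
    """Write a Bismark-style coverage file (percent recomputed from counts)."""
    df = table.df
    depth = df["meth"] + df["unmeth"] if len(df) else pd.Series([], dtype=np.int64)
    with open(path, "w") as fh:
        for chrom, pos, m, u, d in zip(
            df.get("chrom", []), df.get("pos", []), df.get("meth", []),
            df.get("unmeth", []), depth,
        ):
            pct = 100.0 * m / d if d else 0.0
            fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:g}\t{m}\t{u}\n")


def write_segments_bed(segments: Sequence, path: str | Path) -> None:
    """Write segments as BED6 (0-based half-open; score = 100 x mean methylation)."""
    segs = sorted(segments, key=lambda s: (s.chrom, s.start, s.end))
    with open(path, "w") as fh:
        for s in segs:
            score = int(round(100.0 * s.mean_meth))
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.regime}\t{score}\t.\n")


def read_segments_bed(path: str | Path):
    """Read a BED6 written by :func:`write_segments_bed` back into segments."""
    from .segmentation import Segment

    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: malformed BED line {ln}")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            out.append(
                Segment(
                    chrom=chrom,
                    start=start + 1,
                    end=end,
                    regime=name,
                    state=-1,
                    n_cpg=0,
                    mean_meth=score / 100.0,
                )
            )
    return out
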