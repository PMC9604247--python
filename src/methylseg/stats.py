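"""Descriptive methylome statistics and repeat-element methylation.

Global and per-feature methylation levels, fixed-width genomic binning,
between-sample Spearman correlation, and quantification of methylation in
tandem repeats via manually constructed bisulfite-converted reference
variants (methylated vs unmethylated state of each monomer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class FeatureSet:
    """Named genomic intervals (0-based half-open, as loaded from BED)."""

    name: str
    df: pd.DataFrame  # columns: chrom, start, end[, strand, label]

    def __post_init__(self) -> None:
        for col in ("chrom", "start", "end"):
            if col not in self.df.columns:
                raise ValueError(f"FeatureSet missing column {col!r}")
        if len(self.df) and (self.df["start"] >= self.df["end"]).any():
            raise ValueError("feature intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "FeatureSet":
        path = Path(path)
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                row = {
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                }
                if len(parts) > 3:
                    row["label"] = parts[3]
                if len(parts) > 5:
                    row["strand"] = parts[5]
                rows.append(row)
        df = (
            pd.DataFrame(rows)
            if rows
            else pd.DataFrame(columns=["chrom", "start", "end"])
        )
        return cls(name=name or path.stem, df=df)


def global_methylation(table, min_depth: int = 1, site_mean: bool = False) -> float:
    """Overall CpG methylation level of a sample.

    Default is count-weighted: sum of methylated calls over all calls at
    sites with depth >= ``min_depth`` (robust to sparse single-cell depth).
    ``site_mean=True`` instead averages per-site fractions.
    """
    df = table.df
    depth = df["meth"] + df["unmeth"]
    keep = depth >= max(min_depth, 1)
    if not keep.any():
        raise ValueError("no covered sites at this depth cutoff")
    m = df.loc[keep, "meth"].to_numpy(float)
    n = depth[keep].to_numpy(float)
    if site_mean:
        return float(np.mean(m / n))
    return float(m.sum() / n.sum())


def _chrom_cumsums(table) -> dict:
    out = {}
    for chrom, sub in table.df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(np.int64)
        m = np.cumsum(np.concatenate([[0], sub["meth"].to_numpy(np.int64)]))
        u = np.cumsum(np.concatenate([[0], sub["unmeth"].to_numpy(np.int64)]))
        out[chrom] = (pos, m, u)
    return out


def feature_methylation(
    table, features: FeatureSet, min_depth: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Per-interval count-weighted methylation plus a distribution summary.

    Intervals (half-open) with no covered CpG get NaN. The summary reports
    a 20-bin histogram over [0, 1] and the fractions of intervals below /
    above the 0.2, 0.4 and 0.6 cut lines, enough to spot the bimodal
    promoter/CpG-island pattern without a formal test.
    """
    cums = _chrom_cumsums(table)
    means = np.full(len(features), np.nan)
    n_cpg = np.zeros(len(features), dtype=np.int64)
    for i, (chrom, start, end) in enumerate(
        features.df[["chrom", "start", "end"]].itertuples(index=False)
    ):
        if chrom not in cums:
            continue
        pos, mcum, ucum = cums[chrom]
        lo = np.searchsorted(pos, start + 1, side="left")  # half-open -> 1-based
        hi = np.searchsorted(pos, end, side="right")
        m = mcum[hi] - mcum[lo]
        u = ucum[hi] - ucum[lo]
        if m + u >= max(min_depth, 1):
            means[i] = m / (m + u)
            n_cpg[i] = hi - lo
    out = features.df[["chrom", "start", "end"]].copy()
    out["mean_meth"] = means
    out["n_cpg"] = n_cpg
    valid = means[~np.isnan(means)]
    hist, edges = np.histogram(valid, bins=20, range=(0.0, 1.0))
    summary = {
        "n_intervals": len(features),
        "n_measured": int(len(valid)),
        "histogram": hist.tolist(),
        "bin_edges": edges.tolist(),
        "frac_below_20": float(np.mean(valid <= 0.2)) if len(valid) else float("nan"),
        "frac_below_40": float(np.mean(valid < 0.4)) if len(valid) else float("nan"),
        "frac_above_60": float(np.mean(valid > 0.6)) if len(valid) else float("nan"),
    }
    return out, summary


def bin_methylation(
    table, bin_size: int = 5000, min_cpg: int = 3
) -> pd.DataFrame:
    """Mean methylation of fixed-width genomic bins.

    The genome is tiled from coordinate 1 in ``bin_size`` windows
    ((1..bin_size], (bin_size+1..2*bin_size], ...). Only bins containing at
    least one CpG appear; bins with fewer than ``min_cpg`` covered CpGs have
    NaN means but keep their counts, so totals are conserved.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    df = table.df
    if not len(df):
        return pd.DataFrame(
            columns=["chrom", "bin", "start", "end", "n_cpg", "meth", "unmeth", "mean_meth"]
        )
    binned = df.assign(bin=(df["pos"] - 1) // bin_size)
    depth = binned["meth"] + binned["unmeth"]
    binned = binned.assign(covered=(depth > 0).astype(int))
    g = binned.groupby(["chrom", "bin"], as_index=False).agg(
        n_cpg=("covered", "sum"), meth=("meth", "sum"), unmeth=("unmeth", "sum")
    )
    g["start"] = g["bin"] * bin_size + 1
    g["end"] = (g["bin"] + 1) * bin_size
    total = g["meth"] + g["unmeth"]
    with np.errstate(invalid="ignore"):
        g["mean_meth"] = np.where(
            (g["n_cpg"] >= min_cpg) & (total > 0), g["meth"] / total, np.nan
        )
    return g[["chrom", "bin", "start", "end", "n_cpg", "meth", "unmeth", "mean_meth"]]


def correlate_samples(bins_a: pd.DataFrame, bins_b: pd.DataFrame) -> tuple[float, int]:
    """Spearman rank correlation of per-bin methylation between two samples.

    Bins are matched on (chrom, bin); only bins non-missing in both samples
    enter. Returns (rho, number of shared bins); requires >= 3 shared bins.
    """
    merged = bins_a.merge(bins_b, on=["chrom", "bin"], suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["mean_meth_a", "mean_meth_b"])
    n = len(merged)
    if n < 3:
        raise ValueError(f"need at least 3 shared non-missing bins, have {n}")
    rho, _ = sps.spearmanr(merged["mean_meth_a"], merged["mean_meth_b"])
    return float(rho), n


def compare_global_levels(levels_a: Sequence[float], levels_b: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney comparison of per-sample global methylation levels."""
    u, p = sps.mannwhitneyu(levels_a, levels_b, alternative="two-sided")
    return {"U": float(u), "p_value": float(p), "n_a": len(levels_a), "n_b": len(levels_b)}


# ---------------------------------------------------------------------------
# repeat-element methylation via converted reference variants
# ---------------------------------------------------------------------------

@dataclass
class RepeatReferencePair:
    """Bisulfite-converted variants of one repeat monomer strand.

    ``methylated`` converts only non-CpG cytosines C->T (CpG cytosines stay
    C, as if fully methylated); ``unmethylated`` converts every C->T. The
    monomer is treated as circular, since reads come from tandem arrays and
    a terminal C's CpG context wraps to the first base.
    """

    strand: str  # "top" or "bottom"
    monomer: str
    methylated: str
    unmethylated: str


def _convert(seq: str, keep_cpg: bool) -> str:
    n = len(seq)
    out = []
    for i, base in enumerate(seq):
        if base == "C":
            nxt = seq[(i + 1) % n]  # circular context: tandem monomer
            if keep_cpg and nxt == "G":
                out.append("C")
            else:
                out.append("T")
        else:
            out.append(base)
    return "".join(out)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_repeat_references(monomer: str) -> dict[str, RepeatReferencePair]:
    """Construct methylated/unmethylated converted variants of a repeat monomer.

    Returns one pair per original strand ("top" and "bottom", for
    non-directional libraries); bottom-strand variants apply the same
    conversion rules to the reverse complement.
    """
    monomer = monomer.upper()
    bad = set(monomer) - set("ACGT")
    if bad:
        raise ValueError(f"monomer contains non-ACGT symbols: {sorted(bad)}")
    out = {}
    for strand, seq in (("top", monomer), ("bottom", reverse_complement(monomer))):
        out[strand] = RepeatReferencePair(
            strand=strand,
            monomer=seq,
            methylated=_convert(seq, keep_cpg=True),
            unmethylated=_convert(seq, keep_cpg=False),
        )
    return out


@dataclass
class RepeatClassification:
    n_methylated: int
    n_unmethylated: int
    n_unassigned: int
    fraction_methylated: float | None


def _best_phase_score(read: str, variant: str) -> float:
    """Best ungapped identity of ``read`` against the tandem array of ``variant``.

    Every phase of the monomer period is scanned (equivalent to a k-mer
    anchored search over a tandem concatenation, but exhaustive).
    """
    L = len(variant)
    reps = -(-len(read) // L) + 1
    ref = variant * reps
    best = 0
    for off in range(L):
        matches = sum(a == b for a, b in zip(read, ref[off : off + len(read)]))
        if matches > best:
            best = matches
    return best / len(read)


def classify_repeat_reads(
    reads: Iterable[str],
    refs: dict[str, RepeatReferencePair],
    min_score: float = 0.8,
) -> RepeatClassification:
    """Assign bisulfite reads from a tandem repeat to methylated/unmethylated pools.

    Each read is scored against the methylated and unmethylated variants of
    both strands (best ungapped phase match over the tandem array); it joins
    the pool of its best-scoring variant. Ties and reads under ``min_score``
    identity stay unassigned. Returns pool counts and the methylated
    fraction (None when nothing was assigned).
    """
    n_m = n_u = n_x = 0
    for read in reads:
        read = read.upper()
        if not read:
            n_x += 1
            continue
        s_m = max(_best_phase_score(read, p.methylated) for p in refs.values())
        s_u = max(_best_phase_score(read, p.unmethylated) for p in refs.values())
        if max(s_m, s_u) < min_score or s_m == s_u:
            n_x += 1
        elif s_m > s_u:
            n_m += 1
        else:
            n_u += 1
    frac = n_m / (n_m + n_u) if (n_m + n_u) else None
    if frac is None:
        logger.warning("no reads assigned to either repeat state")
    return RepeatClassification(n_m, n_u, n_x, frac)
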