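"""From decoded CpG states to labelled genomic loci and locus-level analyses.

Covers regime assignment (hypo / intermediate / hyper by ascending state
mean), hypomethylated-locus calling at the 20% discriminative threshold,
cross-sample (cell-type-)specific locus flagging, and permutation-based
enrichment of loci over feature sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hmm import UN, HMMModel, ObservationSeries, StatePath

logger = logging.getLogger(__name__)

HYPOMETHYLATION_THRESHOLD = 0.20  # "does not exceed 20%" read as <= 0.20

REGIMES_3 = ("hypo", "intermediate", "hyper")


@dataclass
class Segment:
    """A maximal run of CpGs sharing one decoded methylation regime.

    ``start``/``end`` are 1-based inclusive and span the first to the last
    CpG of the run. ``n_cpg`` counts covered (depth >= 1) member CpGs;
    ``mean_meth`` is the count-weighted methylation over those CpGs.
    """

    chrom: str
    start: int
    end: int
    regime: str
    state: int
    n_cpg: int
    mean_meth: float
    n_sites: int = 0  # all member CpGs incl. uncovered ones

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")
        if not self.n_sites:
            self.n_sites = self.n_cpg

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def assign_regimes(model: HMMModel) -> dict[int, str]:
    """Name each HMM state by its methylation rank.

    With K = 3 the ascending-beta order maps to hypo / intermediate / hyper;
    K = 2 gives hypo / hyper; other K get generic intermediate labels.
    """
    K = model.K
    if K == 3:
        return dict(enumerate(REGIMES_3))
    if K == 2:
        return {0: "hypo", 1: "hyper"}
    if K == 1:
        return {0: "intermediate"}
    labels = {0: "hypo", K - 1: "hyper"}
    for k in range(1, K - 1):
        labels[k] = f"intermediate_{k}"
    return labels


def states_to_segments(
    path: StatePath,
    series: ObservationSeries,
    min_cpg: int = 3,
    regime_map: Mapping[int, str] | None = None,
) -> list[Segment]:
    """Collapse a decoded state path into maximal same-state segments.

    "un" sites are skipped and do not break a run when the flanking states
    match; a run spans the first to the last CpG assigned to it. Runs with
    fewer than ``min_cpg`` covered CpGs are dropped.
    """
    if len(path) != len(series):
        raise ValueError("state path and series lengths differ")
    states = path.states
    segs: list[Segment] = []

    def flush(idx: list[int]) -> None:
        if not idx:
            return
        pos = series.positions[idx]
        m = series.meth[idx]
        n = series.depth[idx]
        covered = n > 0
        n_cov = int(covered.sum())
        if n_cov < min_cpg:
            return
        mean = float(m[covered].sum() / n[covered].sum()) if n_cov else float("nan")
        k = int(states[idx[0]])
        regime = regime_map[k] if regime_map is not None else f"state{k}"
        segs.append(
            Segment(
                chrom=series.chrom,
                start=int(pos[0]),
                end=int(pos[-1]),
                regime=regime,
                state=k,
                n_cpg=n_cov,
                mean_meth=mean,
                n_sites=len(idx),
            )
        )

    run: list[int] = []
    for t, s in enumerate(states):
        if s == UN:
            continue
        if run and states[run[-1]] != s:
            flush(run)
            run = []
        run.append(t)
    flush(run)
    return segs


def call_hypomethylated(
    segments: Sequence[Segment],
    table,
    threshold: float = HYPOMETHYLATION_THRESHOLD,
) -> list[Segment]:
    """Keep segments whose mean methylation over covered CpGs is <= threshold.

    The mean is recomputed from the table (methylated calls / total calls
    over covered CpGs inside the interval), so a segmentation from one
    sample can be screened against any sample's counts. Segments with no
    covered CpG in the table are excluded and logged.
    """
    means = segment_means(segments, table)
    kept = []
    n_uncovered = 0
    for seg, mean in zip(segments, means):
        if np.isnan(mean):
            n_uncovered += 1
            continue
        if mean <= threshold:
            kept.append(seg)
    if n_uncovered:
        logger.info("%d segments had no covered CpGs and were excluded", n_uncovered)
    return kept


def segment_means(segments: Sequence[Segment], table) -> np.ndarray:
    """Count-weighted mean methylation of each segment interval in ``table``.

    NaN where the interval contains no covered CpG.
    """
    df = table.df
    out = np.full(len(segments), np.nan)
    by_chrom = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(np.int64)
        m = np.cumsum(np.concatenate([[0], sub["meth"].to_numpy(np.int64)]))
        u = np.cumsum(np.concatenate([[0], sub["unmeth"].to_numpy(np.int64)]))
        by_chrom[chrom] = (pos, m, u)
    for i, seg in enumerate(segments):
        if seg.chrom not in by_chrom:
            continue
        pos, mcum, ucum = by_chrom[seg.chrom]
        lo = np.searchsorted(pos, seg.start, side="left")
        hi = np.searchsorted(pos, seg.end, side="right")
        meth = mcum[hi] - mcum[lo]
        total = meth + ucum[hi] - ucum[lo]
        if total > 0:
            out[i] = meth / total
    return out


def call_specific_loci(
    loci: Sequence[Segment],
    sample_means: pd.DataFrame,
    focal: str,
    threshold: float = HYPOMETHYLATION_THRESHOLD,
) -> list[bool]:
    """Flag loci whose hypomethylation status separates the focal sample.

    A locus is focal-specific iff it is hypomethylated (mean <= threshold)
    in the focal sample but in none of the others, or hypomethylated in
    every other sample but not the focal one. ``sample_means`` has one row
    per locus and one column per sample; loci with any missing sample value
    are never flagged (logged).
    """
    if focal not in sample_means.columns:
        raise ValueError(f"focal sample {focal!r} not in sample_means columns")
    if sample_means.shape[1] < 2:
        raise ValueError("need at least two samples")
    if len(sample_means) != len(loci):
        raise ValueError("sample_means rows must match loci")
    others = [c for c in sample_means.columns if c != focal]
    flags = []
    n_missing = 0
    for _, row in sample_means.iterrows():
        if row.isna().any():
            flags.append(False)
            n_missing += 1
            continue
        f_hypo = row[focal] <= threshold
        o_hypo = [row[o] <= threshold for o in others]
        flags.append((f_hypo and not any(o_hypo)) or (not f_hypo and all(o_hypo)))
    if n_missing:
        logger.info("%d loci had missing sample means and were not flagged", n_missing)
    return flags


@dataclass
class EnrichmentResult:
    """Observed feature-overlap count against a length-preserving random null."""

    observed: int
    null_mean: float
    null_sd: float
    z: float | None
    n_perm: int
    seed: int

    def as_row(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": np.nan if self.z is None else self.z,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _loci_to_halfopen(loci) -> list[tuple[str, int, int]]:
    out = []
    for loc in loci:
        if isinstance(loc, Segment):
            out.append((loc.chrom, loc.start - 1, loc.end))
        else:
            chrom, start, end = loc
            out.append((chrom, int(start) - 1, int(end)))
    return out


def _count_overlapped(features: pd.DataFrame, loci: Sequence[tuple[str, int, int]]) -> int:
    """Number of feature intervals overlapped >= 1 bp by any locus (half-open)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in loci:
        by_chrom.setdefault(chrom, []).append((s, e))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.array(starts), np.array(ends))
    count = 0
    for chrom, fs, fe in features[["chrom", "start", "end"]].itertuples(index=False):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        i = np.searchsorted(ends, fs, side="right")
        if i < len(starts) and starts[i] < fe:
            count += 1
    return count


def feature_enrichment(
    loci,
    features,
    chrom_sizes: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test: do the loci overlap more features than random placement?

    Observed = features overlapped >= 1 bp by any locus. The null keeps each
    locus on its chromosome, preserves its length, and redraws its start
    uniformly, ``n_perm`` times (overlaps among placed intervals allowed).
    Reports null mean +- sd and z = (obs - mean) / sd (None when sd = 0).
    """
    feat_df = features.df if hasattr(features, "df") else pd.DataFrame(
        features, columns=["chrom", "start", "end"]
    )
    half = _loci_to_halfopen(loci)
    observed = _count_overlapped(feat_df, half)
    rng = np.random.default_rng(seed)
    lens = np.array([e - s for _, s, e in half], dtype=np.int64)
    chroms = [c for c, _, _ in half]
    maxstart = np.array(
        [max(chrom_sizes[c] - L, 0) for c, L in zip(chroms, lens)], dtype=np.int64
    )
    null = np.empty(n_perm)
    for p in range(n_perm):
        starts = rng.integers(0, maxstart + 1)
        placed = [(c, int(s), int(s + L)) for c, s, L in zip(chroms, starts, lens)]
        null[p] = _count_overlapped(feat_df, placed)
    mean = float(null.mean()) if n_perm else float("nan")
    sd = float(null.std(ddof=1)) if n_perm > 1 else float("nan")
    z = None if not np.isfinite(sd) or sd == 0 else float((observed - mean) / sd)
    return EnrichmentResult(
        observed=observed, null_mean=mean, null_sd=sd, z=z, n_perm=n_perm, seed=seed
    )
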