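"""Synthetic methylomes with the statistical structure the HMM assumes.

The generator is the exact sampling counterpart of the model: CpG positions
from cumulative geometric gaps, hidden regimes from the distance-decay
Markov chain, read depths from a truncated Poisson, and methylated counts
from Binomial(depth, beta_state). Defaults mirror sparse single-oocyte
bisulfite data: three regimes at means 0.05 / 0.50 / 0.85, decay length
d0 = 1250 bp, mean inter-CpG gap 100 bp, Poisson depth mean 3 truncated at
the 8-read single-nucleus ceiling, and a ~5 Mb chromosome giving roughly
50,000 CpG sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .hmm import ObservationSeries, StatePath, _stay_switch
from .io import MethylomeTable
from .segmentation import REGIMES_3, Segment


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic methylome."""

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000}
    )
    betas: tuple = (0.05, 0.50, 0.85)
    d0: float = 1250.0
    mean_gap: float = 100.0
    depth_mean: float = 3.0
    max_depth: int = 8
    pi: tuple | None = None  # uniform when None
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, float)
        if np.any(b <= 0) or np.any(b >= 1) or len(np.unique(b)) != len(b):
            raise ValueError("betas must be distinct values in (0, 1)")
        if min(self.d0, self.mean_gap, self.depth_mean) <= 0:
            raise ValueError("d0, mean_gap and depth_mean must be positive")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")

    @property
    def K(self) -> int:
        return len(self.betas)


@dataclass
class SimulationResult:
    """One simulated sample plus its ground truth."""

    table: MethylomeTable
    series: list[ObservationSeries]
    paths: dict[str, StatePath]  # true hidden states per chromosome
    segments: list[Segment]  # true regime segments
    config: SimulationConfig


def _sample_positions(rng: np.random.Generator, length: int, mean_gap: float) -> np.ndarray:
    """CpG positions by cumulative geometric gaps (support >= 1, mean = mean_gap)."""
    p = min(1.0, 1.0 / mean_gap)
    chunks = []
    last = 0
    est = int(length / mean_gap * 1.2) + 100
    while last <= length:
        gaps = rng.geometric(p, size=est)
        pos = last + np.cumsum(gaps)
        chunks.append(pos)
        last = int(pos[-1])
    pos = np.concatenate(chunks)
    return pos[pos <= length]


def _sample_states(
    rng: np.random.Generator, gaps: np.ndarray, K: int, d0: float, pi: np.ndarray
) -> np.ndarray:
    """Hidden regimes from the distance-decay chain (switch prob. per gap)."""
    T = len(gaps) + 1
    states = np.empty(T, dtype=np.int64)
    states[0] = rng.choice(K, p=pi)
    _, switch = _stay_switch(K, gaps, d0)
    p_switch = (K - 1) * np.asarray(switch)
    u = rng.random(T - 1)
    jump = u < p_switch
    draws = rng.integers(0, K - 1, size=T - 1) if K > 1 else np.zeros(T - 1, np.int64)
    for t in range(1, T):
        cur = states[t - 1]
        if jump[t - 1]:
            nxt = draws[t - 1]
            states[t] = nxt if nxt < cur else nxt + 1
        else:
            states[t] = cur
    return states


def _truncated_poisson_depths(
    rng: np.random.Generator, mean: float, max_depth: int, size: int
) -> np.ndarray:
    k = np.arange(max_depth + 1)
    pmf = sps.poisson.pmf(k, mean)
    pmf /= pmf.sum()
    return rng.choice(max_depth + 1, size=size, p=pmf)


def _true_segments(
    chrom: str, positions: np.ndarray, states: np.ndarray,
    meth: np.ndarray, depth: np.ndarray, betas: Sequence[float],
) -> list[Segment]:
    regime_names = (
        dict(enumerate(REGIMES_3)) if len(betas) == 3
        else {k: f"state{k}" for k in range(len(betas))}
    )
    segs = []
    bounds = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [len(states)]])
    for a, b in zip(starts, ends):
        n = depth[a:b]
        cov = n > 0
        total = int(n[cov].sum())
        segs.append(
            Segment(
                chrom=chrom,
                start=int(positions[a]),
                end=int(positions[b - 1]),
                regime=regime_names[int(states[a])],
                state=int(states[a]),
                n_cpg=int(cov.sum()),
                mean_meth=float(meth[a:b][cov].sum() / total) if total else float("nan"),
                n_sites=int(b - a),
            )
        )
    return segs


def simulate(config: SimulationConfig, sample_id: str = "sim") -> SimulationResult:
    """Draw one methylome from the generative model; deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    K = config.K
    betas = np.asarray(config.betas, float)
    pi = (
        np.asarray(config.pi, float)
        if config.pi is not None
        else np.full(K, 1.0 / K)
    )
    chroms_out, pos_out, meth_out, unmeth_out = [], [], [], []
    paths: dict[str, StatePath] = {}
    series: list[ObservationSeries] = []
    segments: list[Segment] = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        positions = _sample_positions(rng, length, config.mean_gap)
        if not len(positions):
            continue
        gaps = np.diff(positions)
        states = _sample_states(rng, gaps, K, config.d0, pi)
        depth = _truncated_poisson_depths(
            rng, config.depth_mean, config.max_depth, len(positions)
        )
        meth = rng.binomial(depth, betas[states])
        chroms_out.append(np.full(len(positions), chrom, dtype=object))
        pos_out.append(positions)
        meth_out.append(meth)
        unmeth_out.append(depth - meth)
        paths[chrom] = StatePath(states=states)
        series.append(ObservationSeries(positions, meth, depth, chrom=chrom))
        segments.extend(_true_segments(chrom, positions, states, meth, depth, betas))
    table = MethylomeTable.from_arrays(
        np.concatenate(chroms_out) if chroms_out else [],
        np.concatenate(pos_out) if pos_out else [],
        np.concatenate(meth_out) if meth_out else [],
        np.concatenate(unmeth_out) if unmeth_out else [],
        sample_id=sample_id,
    )
    return SimulationResult(
        table=table, series=series, paths=paths, segments=segments, config=config
    )


@dataclass
class SpecificLocus:
    """A planted locus whose regime deviates in (or outside) the focal sample.

    mode "focal_hypo": the focal sample is forced to the lowest regime here
    while every other sample is forced to the highest; "focal_not_hypo" is
    the reverse case (all others hypomethylated, focal not).
    """

    chrom: str
    start: int
    end: int
    mode: str = "focal_hypo"

    def __post_init__(self) -> None:
        if self.mode not in ("focal_hypo", "focal_not_hypo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.start > self.end:
            raise ValueError("locus start must not exceed end")


@dataclass
class MultiSampleResult:
    tables: dict[str, MethylomeTable]
    backbone: SimulationResult  # shared positions/states before overrides
    states: dict[str, dict[str, np.ndarray]]  # sample -> chrom -> states
    truth: list[SpecificLocus]
    focal: str


def simulate_multisample(
    config: SimulationConfig,
    n_samples: int,
    loci_spec: Sequence[SpecificLocus] = (),
    focal: str | None = None,
) -> MultiSampleResult:
    """Simulate several samples sharing one segment backbone.

    All samples share CpG positions and hidden states except at the planted
    loci, where the focal sample (default: first) and the rest are forced to
    opposite extreme regimes according to each locus's mode. Depths and
    counts are drawn independently per sample from child seeds.
    """
    for i, a in enumerate(loci_spec):
        for b in list(loci_spec)[i + 1 :]:
            if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                raise ValueError(
                    f"overlapping specific loci {a.chrom}:{a.start}-{a.end} "
                    f"and {b.chrom}:{b.start}-{b.end}"
                )
    backbone = simulate(config)
    K = config.K
    betas = np.asarray(config.betas, float)
    names = [f"s{i}" for i in range(n_samples)]
    focal = focal or names[0]
    if focal not in names:
        raise ValueError(f"focal sample {focal!r} not among generated samples")
    seeds = np.random.SeedSequence(config.seed).spawn(n_samples)
    tables: dict[str, MethylomeTable] = {}
    all_states: dict[str, dict[str, np.ndarray]] = {}
    for name, seed_seq in zip(names, seeds):
        rng = np.random.default_rng(seed_seq)
        chroms_out, pos_out, meth_out, unmeth_out = [], [], [], []
        per_chrom: dict[str, np.ndarray] = {}
        for s in backbone.series:
            states = backbone.paths[s.chrom].states.copy()
            for loc in loci_spec:
                if loc.chrom != s.chrom:
                    continue
                mask = (s.positions >= loc.start) & (s.positions <= loc.end)
                is_focal = name == focal
                hypo_here = (loc.mode == "focal_hypo") == is_focal
                states[mask] = 0 if hypo_here else K - 1
            depth = _truncated_poisson_depths(
                rng, config.depth_mean, config.max_depth, len(s)
            )
            meth = rng.binomial(depth, betas[states])
            per_chrom[s.chrom] = states
            chroms_out.append(np.full(len(s), s.chrom, dtype=object))
            pos_out.append(s.positions)
            meth_out.append(meth)
            unmeth_out.append(depth - meth)
        tables[name] = MethylomeTable.from_arrays(
            np.concatenate(chroms_out),
            np.concatenate(pos_out),
            np.concatenate(meth_out),
            np.concatenate(unmeth_out),
            sample_id=name,
        )
        all_states[name] = per_chrom
    return MultiSampleResult(
        tables=tables,
        backbone=backbone,
        states=all_states,
        truth=list(loci_spec),
        focal=focal,
    )
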