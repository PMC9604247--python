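"""K-state HMM over CpG sites with binomial emissions and distance-decay transitions.

The model: hidden state S_t of CpG site t has mean methylation level beta_k;
the observed methylated count m_t given depth n_t is Binomial(n_t, beta_{S_t}).
Transition probabilities decay with the genomic gap d between consecutive
CpGs, so that methylation correlation falls off with distance:

    P(stay)   = 1/K + (K-1)/K * exp(-d / d0)
    P(switch) = 1/K * (1 - exp(-d / d0))        (to each of the K-1 others)

At K = 4 this is exactly the 1/4 + 3/4 e^(-d/d0) / 1/4 - 1/4 e^(-d/d0) form;
for other K it is the minimal row-stochastic generalization. A "literal"
mode keeps the K = 4 coefficients for any K and renormalizes rows.

Training (Baum-Welch with transitions fixed by d0) raises each site's
emission likelihood to the power (n_t + 2), so deeply covered cytosines
dominate learning; decoding and model-selection likelihoods are unweighted.
Both the forward and the reverse-directed copy of every series enter
training and decoding; sites whose forward and reverse Viterbi states
disagree are labelled "un" (unknown).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

logger = logging.getLogger(__name__)

UN = -1  # label for sites whose forward and reverse decodings disagree

_BETA_FLOOR = 1e-6


@dataclass
class HMMModel:
    """Fitted methylation HMM: per-state means, initial probs, distance scale.

    ``betas`` are kept in canonical ascending order so state k is the k-th
    lowest methylation regime. ``d0`` is the transition decay length in bp.
    """

    betas: np.ndarray
    pi: np.ndarray
    d0: float
    transition_form: str = "generalized"  # or "literal" (K=4 coefficients, renormalized)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.betas.ndim != 1 or self.pi.shape != self.betas.shape:
            raise ValueError("betas and pi must be 1-D arrays of equal length")
        if self.K < 2 and self.K != 1:
            raise ValueError("need at least one state")
        if np.any(self.betas < 0) or np.any(self.betas > 1):
            raise ValueError("betas must lie in [0, 1]")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        order = np.argsort(self.betas, kind="stable")
        self.betas = self.betas[order]
        self.pi = self.pi[order]

    @property
    def K(self) -> int:
        return len(self.betas)

    def to_json(self, path: str | Path | None = None, **meta) -> str:
        doc = {
            "k": self.K,
            "betas": [float(b) for b in self.betas],
            "pi": [float(p) for p in self.pi],
            "d0": float(self.d0),
            "transition_form": self.transition_form,
            "meta": meta,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "HMMModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            betas=np.array(doc["betas"]),
            pi=np.array(doc["pi"]),
            d0=doc["d0"],
            transition_form=doc.get("transition_form", "generalized"),
        )


@dataclass
class ObservationSeries:
    """Observed counts along one chromosome or locus, ordered by position."""

    positions: np.ndarray
    meth: np.ndarray
    depth: np.ndarray
    chrom: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if not (len(self.positions) == len(self.meth) == len(self.depth)):
            raise ValueError("positions, meth, depth must have equal length")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.meth < 0) or np.any(self.meth > self.depth):
            raise ValueError("need 0 <= meth <= depth at every site")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def gaps(self) -> np.ndarray:
        return np.diff(self.positions)


@dataclass
class StatePath:
    """Decoded per-site states; ``UN`` (-1) marks forward/reverse disagreement."""

    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_un(self) -> int:
        return int(np.sum(self.states == UN))

    def labels(self) -> list:
        return ["un" if s == UN else int(s) for s in self.states]


def series_from_table(
    table, include_uncovered: bool = True
) -> list[ObservationSeries]:
    """Split a :class:`~methylseg.io.MethylomeTable` into per-chromosome series."""
    out = []
    df = table.df
    for chrom, sub in df.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(np.int64)
        m = sub["meth"].to_numpy(np.int64)
        n = m + sub["unmeth"].to_numpy(np.int64)
        if not include_uncovered:
            keep = n > 0
            pos, m, n = pos[keep], m[keep], n[keep]
        if len(pos):
            out.append(ObservationSeries(pos, m, n, chrom=str(chrom)))
    return out


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

def _stay_switch(K: int, d, d0: float, form: str = "generalized"):
    """Per-gap stay/switch probabilities; vectorized over d."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genomic distance must be non-negative")
    e = np.exp(-d / d0)
    if form == "literal":
        stay = 0.25 + 0.75 * e
        switch = 0.25 - 0.25 * e
        norm = stay + (K - 1) * switch
        return stay / norm, switch / norm
    if form != "generalized":
        raise ValueError(f"unknown transition form: {form!r}")
    stay = 1.0 / K + (K - 1) / K * e
    switch = (1.0 / K) * (1.0 - e)
    return stay, switch


def transition_probs(model: HMMModel, d: float) -> np.ndarray:
    """The K x K row-stochastic transition matrix at genomic gap ``d`` bp."""
    K = model.K
    stay, switch = _stay_switch(K, d, model.d0, model.transition_form)
    A = np.full((K, K), float(switch))
    np.fill_diagonal(A, float(stay))
    return A


# ---------------------------------------------------------------------------
# emissions and weights
# ---------------------------------------------------------------------------

def binom_logpmf(meth: np.ndarray, depth: np.ndarray, beta: float | np.ndarray) -> np.ndarray:
    """log Binomial(meth; depth, beta), broadcastable; beta clamped off {0,1}."""
    m = np.asarray(meth, dtype=float)
    n = np.asarray(depth, dtype=float)
    b = np.clip(np.asarray(beta, dtype=float), _BETA_FLOOR, 1.0 - _BETA_FLOOR)
    return (
        gammaln(n + 1.0)
        - gammaln(m + 1.0)
        - gammaln(n - m + 1.0)
        + m * np.log(b)
        + (n - m) * np.log1p(-b)
    )


def emission_prob(model: HMMModel, state: int, meth: int, depth: int) -> float:
    """Binomial emission probability of ``meth`` of ``depth`` calls in ``state``.

    A zero-depth site is uninformative and has probability 1 in every state.
    """
    if not 0 <= meth <= depth:
        raise ValueError("need 0 <= meth <= depth")
    if depth == 0:
        return 1.0
    return float(np.exp(binom_logpmf(meth, depth, model.betas[state])))


def training_weight(depth: int | np.ndarray):
    """Exponent applied to each site's emission likelihood during training.

    Equal to depth + 2, so cytosines with greater read depth contribute more;
    a zero-depth site's constant-1 emission stays neutral under any exponent.
    """
    return np.asarray(depth) + 2


def _log_emissions(series: ObservationSeries, betas: np.ndarray) -> np.ndarray:
    return binom_logpmf(
        series.meth[:, None], series.depth[:, None], betas[None, :]
    )


# ---------------------------------------------------------------------------
# numba kernels: scaled forward/backward (structured transitions) and Viterbi
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_backward(b, stay, switch, pi):  # pragma: no cover - numba
    """Scaled forward-backward for A(d) = switch*J + (stay-switch)*I.

    ``b``: (T, K) emission values (scaled so each row max is ~1).
    Returns (gamma, log_c_sum): posteriors and sum of log scaling factors.
    """
    T, K = b.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    s0 = 0.0
    for j in range(K):
        alpha[0, j] = pi[j] * b[0, j]
        s0 += alpha[0, j]
    c[0] = s0
    for j in range(K):
        alpha[0, j] /= s0
    for t in range(1, T):
        st = 0.0
        diff = stay[t - 1] - switch[t - 1]
        for j in range(K):
            # row sums of alpha[t-1] are 1 after scaling
            alpha[t, j] = (switch[t - 1] + diff * alpha[t - 1, j]) * b[t, j]
            st += alpha[t, j]
        c[t] = st
        for j in range(K):
            alpha[t, j] /= st
    beta = np.empty((T, K))
    for j in range(K):
        beta[T - 1, j] = 1.0
    for t in range(T - 2, -1, -1):
        diff = stay[t] - switch[t]
        s = 0.0
        tmp = np.empty(K)
        for j in range(K):
            tmp[j] = b[t + 1, j] * beta[t + 1, j]
            s += tmp[j]
        for i in range(K):
            beta[t, i] = (switch[t] * s + diff * tmp[i]) / c[t + 1]
    gamma = np.empty((T, K))
    log_c = 0.0
    for t in range(T):
        log_c += np.log(c[t])
        g = 0.0
        for j in range(K):
            gamma[t, j] = alpha[t, j] * beta[t, j]
            g += gamma[t, j]
        for j in range(K):
            gamma[t, j] /= g
    return gamma, log_c


@njit(cache=True)
def _viterbi(logb, lstay, lswitch, logpi):  # pragma: no cover - numba
    """Log-space Viterbi; ties broken toward the lowest state index."""
    T, K = logb.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for j in range(K):
        delta[0, j] = logpi[j] + logb[0, j]
    for t in range(1, T):
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                trans = lstay[t - 1] if i == j else lswitch[t - 1]
                v = delta[t - 1, i] + trans
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logb[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for j in range(K):
        if delta[T - 1, j] > best:
            best = delta[T - 1, j]
            arg = j
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


# ---------------------------------------------------------------------------
# bidirectional preparation
# ---------------------------------------------------------------------------

def prepare_bidirectional(
    series: ObservationSeries,
) -> tuple[ObservationSeries, ObservationSeries]:
    """Return the series and its reverse-directed copy.

    Positions of the reversal are negated and reversed, so the gap sequence
    of the reverse series is the mirror of the forward one and the gap
    multiset is preserved.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    rev = ObservationSeries(
        positions=-series.positions[::-1],
        meth=series.meth[::-1],
        depth=series.depth[::-1],
        chrom=series.chrom,
    )
    return series, rev


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: HMMModel
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def _init_betas(series_list: Sequence[ObservationSeries], K: int, seed: int) -> np.ndarray:
    fracs = []
    for s in series_list:
        cov = s.depth > 0
        if cov.any():
            fracs.append(s.meth[cov] / s.depth[cov])
    if not fracs:
        raise ValueError("no covered sites in training data")
    fracs = np.concatenate(fracs)
    qs = np.linspace(0.1, 0.9, K)
    # Clamp well inside (0, 1): sparse per-site fractions put the outer
    # quantiles at exactly 0/1, which are absorbing fixed points of the
    # depth-weighted EM (a beta at 1e-6 vetoes every site with one
    # methylated call and can never recover).
    betas = np.clip(np.quantile(fracs, qs), 0.05, 0.95)
    # break exact ties (sparse data quantiles can coincide) with seeded jitter
    if np.min(np.diff(np.sort(betas)), initial=1.0) < 0.02:
        rng = np.random.default_rng(seed)
        betas = np.clip(betas + rng.uniform(-0.02, 0.02, K), 0.02, 0.98)
        betas = np.maximum.accumulate(np.sort(betas))
        betas += np.arange(K) * 0.02
        betas = np.clip(betas, 0.02, 0.98)
    return np.sort(betas)


def _weighted_emissions(series, betas, weighted: bool):
    logp = _log_emissions(series, betas)
    if weighted:
        logp = training_weight(series.depth)[:, None] * logp
    off = logp.max(axis=1)
    b = np.exp(logp - off[:, None])
    return b, float(off.sum())


def fit(
    series_list: Iterable[ObservationSeries],
    K: int,
    d0: float,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
    include_reverse: bool = True,
    transition_form: str = "generalized",
    init_betas: np.ndarray | None = None,
) -> FitResult:
    """Baum-Welch fit of the K-state model at fixed ``d0``.

    Transitions are fully determined by d0 (selected by grid search, not
    re-estimated); EM updates betas and pi. Per-site emission log-likelihoods
    are scaled by the (n_t + 2) training weight, and the reverse-directed
    copy of every series joins the training set. The monitored objective is
    the weighted log-likelihood, which is non-decreasing across iterations.
    """
    fwd = [s for s in series_list if len(s)]
    if not fwd:
        raise ValueError("empty series list")
    n_covered = sum(int((s.depth > 0).sum()) for s in fwd)
    if n_covered < 10 * K:
        raise ValueError(f"need at least {10 * K} covered sites, have {n_covered}")
    train = list(fwd)
    if include_reverse:
        train += [prepare_bidirectional(s)[1] for s in fwd]

    betas = (
        np.sort(np.clip(np.asarray(init_betas, float), _BETA_FLOOR, 1 - _BETA_FLOOR))
        if init_betas is not None
        else _init_betas(fwd, K, seed)
    )
    pi = np.full(K, 1.0 / K)

    # per-series stay/switch arrays are fixed across EM iterations
    trans = []
    for s in train:
        stay, switch = _stay_switch(K, s.gaps, d0, transition_form)
        trans.append((np.atleast_1d(stay), np.atleast_1d(switch)))

    if len(np.unique(np.concatenate([s.meth / np.maximum(s.depth, 1) for s in fwd]))) == 1:
        logger.warning("degenerate training data: all covered sites identical")

    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll = 0.0
        num = np.zeros(K)
        den = np.zeros(K)
        pi_acc = np.zeros(K)
        for s, (stay, switch) in zip(train, trans):
            b, off = _weighted_emissions(s, betas, weighted=True)
            gamma, log_c = _forward_backward(b, stay, switch, pi)
            ll += log_c + off
            w = training_weight(s.depth).astype(float)
            num += gamma.T @ (w * s.meth)
            den += gamma.T @ (w * s.depth)
            pi_acc += gamma[0]
        history.append(ll)
        if len(history) > 1:
            prev = history[-2]
            if ll - prev < tol * abs(prev):
                converged = True
                break
        betas = np.where(den > 0, num / np.maximum(den, 1e-300), betas)
        betas = np.clip(betas, _BETA_FLOOR, 1.0 - _BETA_FLOOR)
        pi = pi_acc / len(train)
        pi = np.clip(pi, 1e-12, None)
        pi /= pi.sum()

    model = HMMModel(betas=betas, pi=pi, d0=float(d0), transition_form=transition_form)
    return FitResult(model=model, log_likelihoods=history, converged=converged, n_iter=it)


def log_likelihood(
    model: HMMModel, series_list: Iterable[ObservationSeries], weighted: bool = False
) -> float:
    """Total (default: unweighted, forward-direction) log-likelihood."""
    total = 0.0
    for s in series_list:
        if not len(s):
            continue
        stay, switch = _stay_switch(model.K, s.gaps, model.d0, model.transition_form)
        b, off = _weighted_emissions(s, model.betas, weighted=weighted)
        _, log_c = _forward_backward(
            b, np.atleast_1d(stay), np.atleast_1d(switch), model.pi
        )
        total += log_c + off
    return float(total)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _viterbi_path(model: HMMModel, series: ObservationSeries) -> tuple[np.ndarray, float]:
    logb = _log_emissions(series, model.betas)
    stay, switch = _stay_switch(model.K, series.gaps, model.d0, model.transition_form)
    with np.errstate(divide="ignore"):
        lstay = np.log(np.atleast_1d(stay))
        lswitch = np.log(np.atleast_1d(switch))
        logpi = np.log(model.pi)
    return _viterbi(logb, lstay, lswitch, logpi)


def _posterior_path(model: HMMModel, series: ObservationSeries) -> np.ndarray:
    stay, switch = _stay_switch(model.K, series.gaps, model.d0, model.transition_form)
    b, _ = _weighted_emissions(series, model.betas, weighted=False)
    gamma, _ = _forward_backward(b, np.atleast_1d(stay), np.atleast_1d(switch), model.pi)
    return gamma.argmax(axis=1)


def decode(model: HMMModel, series: ObservationSeries, method: str = "viterbi") -> StatePath:
    """Bidirectional decoding with "un" labels where directions disagree.

    The series is decoded forward and in reverse direction (unweighted
    emissions); per-site states that agree are kept, disagreements become
    the "un" (unknown) label, excluded from downstream segment analysis.
    ``method`` is "viterbi" (default) or "posterior".
    """
    fwd_s, rev_s = prepare_bidirectional(series)
    if method == "viterbi":
        f, _ = _viterbi_path(model, fwd_s)
        r, _ = _viterbi_path(model, rev_s)
    elif method == "posterior":
        f = _posterior_path(model, fwd_s)
        r = _posterior_path(model, rev_s)
    else:
        raise ValueError(f"unknown decode method: {method!r}")
    r = r[::-1]
    states = np.where(f == r, f, UN)
    return StatePath(states=states)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def select_model(
    series_list: Sequence[ObservationSeries],
    K_grid: Sequence[int],
    d0_grid: Sequence[float],
    seed: int = 0,
    **fit_kwargs,
) -> tuple[HMMModel, pd.DataFrame]:
    """Grid-search (K, d0) by information criteria; returns the argmin-BIC model.

    AIC = 2p - 2 lnL and BIC = p ln N - 2 lnL with p = K betas + (K - 1) free
    initial probabilities + 1 distance parameter = 2K, N the number of covered
    sites, and lnL the unweighted forward-direction log-likelihood (the
    (n_t + 2) weight is a training device only).
    """
    if not len(K_grid) or not len(d0_grid):
        raise ValueError("K_grid and d0_grid must be non-empty")
    series_list = [s for s in series_list if len(s)]
    N = sum(int((s.depth > 0).sum()) for s in series_list)
    rows = []
    best = None
    for K, d0 in product(K_grid, d0_grid):
        try:
            res = fit(series_list, K=int(K), d0=float(d0), seed=seed, **fit_kwargs)
            lnL = log_likelihood(res.model, series_list, weighted=False)
            p = 2 * int(K)
            aic = 2 * p - 2 * lnL
            bic = p * np.log(N) - 2 * lnL
            rows.append(
                {
                    "K": int(K), "d0": float(d0), "lnL": lnL, "p": p, "N": N,
                    "AIC": aic, "BIC": bic, "converged": res.converged,
                    "n_iter": res.n_iter,
                }
            )
            if best is None or bic < best[0]:
                best = (bic, res.model)
        except Exception as exc:  # record failure, keep scanning the grid
            logger.warning("fit failed at K=%s d0=%s: %s", K, d0, exc)
            rows.append(
                {
                    "K": int(K), "d0": float(d0), "lnL": np.nan, "p": 2 * int(K),
                    "N": N, "AIC": np.nan, "BIC": np.nan, "converged": False,
                    "n_iter": 0,
                }
            )
    table = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("every (K, d0) combination failed to fit")
    return best[1], table


# ---------------------------------------------------------------------------
# train/test locus sampling
# ---------------------------------------------------------------------------

#: Default chicken chromosome size classes (macro chr1-5, intermediate
#: chr6-10, micro the rest); override via ``chrom_classes``.
def default_chrom_classes(chrom_sizes: dict) -> dict:
    classes = {}
    for chrom in chrom_sizes:
        digits = "".join(c for c in str(chrom).removeprefix("chr") if c.isdigit())
        if digits and int(digits) <= 5 and str(chrom).removeprefix("chr") == digits:
            classes[chrom] = "macro"
        elif digits and int(digits) <= 10 and str(chrom).removeprefix("chr") == digits:
            classes[chrom] = "intermediate"
        else:
            classes[chrom] = "micro"
    return classes


def make_train_test_loci(
    chrom_sizes: dict,
    chrom_classes: dict | None = None,
    n_loci: int = 54,
    locus_len: int = 300_000,
    seed: int = 0,
) -> tuple[list[tuple[str, int, int]], list[tuple[str, int, int]]]:
    """Sample non-overlapping equal-length loci balanced across chromosome classes.

    Draws ``n_loci`` intervals of ``locus_len`` bp with uniformly random
    starts, the same number from each chromosome class (macro / intermediate /
    micro for chicken), then splits each class evenly into train and test
    sets. Deterministic under ``seed``. Intervals are 1-based inclusive.
    """
    if chrom_classes is None:
        chrom_classes = default_chrom_classes(chrom_sizes)
    classes = sorted(set(chrom_classes.values()))
    if n_loci % (2 * len(classes)):
        raise ValueError(
            f"n_loci={n_loci} cannot be split evenly over {len(classes)} classes "
            "and a train/test halving"
        )
    quota = n_loci // len(classes)
    rng = np.random.default_rng(seed)
    train: list[tuple[str, int, int]] = []
    test: list[tuple[str, int, int]] = []
    for cls in classes:
        chroms = [c for c, k in chrom_classes.items() if k == cls and
                  chrom_sizes[c] >= locus_len]
        if not chroms:
            raise ValueError(f"class {cls!r} has no chromosome >= {locus_len} bp")
        weights = np.array([chrom_sizes[c] - locus_len + 1 for c in chroms], float)
        weights /= weights.sum()
        placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        loci = []
        attempts = 0
        while len(loci) < quota:
            attempts += 1
            if attempts > 2000 * quota:
                raise ValueError(
                    f"cannot place {quota} non-overlapping {locus_len} bp loci "
                    f"in chromosome class {cls!r}"
                )
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            start = int(rng.integers(1, chrom_sizes[chrom] - locus_len + 2))
            end = start + locus_len - 1
            if any(s <= end and start <= e for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            loci.append((chrom, start, end))
        order = rng.permutation(quota)
        half = quota // 2
        train += [loci[i] for i in order[:half]]
        test += [loci[i] for i in order[half:]]
    return sorted(train), sorted(test)
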