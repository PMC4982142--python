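"""Circular binary segmentation (CBS) of the pairwise-distance signal.

Per chromosome, the ordered PD values (gap from each DOP-position to the one
on its left) are first trimmed of outliers — very small PDs are
non-overlapping reads from a single amplicon, very large ones are unmappable
stretches (gaps, repeats) — and then segmented into runs of homogeneous mean
PD.  Regions present on the sorted chromosome appear as segments whose mean
PD is an order of magnitude below the whole-genome background.

The segmentation statistic follows the classic CBS recipe for copy-number
data: for an arc of n values with overall mean mu, every boundary pair is a
window of length k starting at i (wrapping allowed on the first level), and
the score is the two-sample t-like statistic comparing the mean inside the
window against the rest,

    T(i, k) = |mean_in - mean_out| / (sigma * sqrt(1/k + 1/(n-k))).

Because the arc standard deviation sigma and mean mu are invariant under
permutation of the arc, T is maximised and compared across permutations via
the equivalent score |W - k*mu| / sqrt(k*(n-k)) with W the window sum; the
permutation p-value of the best window decides whether the split is accepted
(alpha, default 0.01, n_perm label permutations with a fixed seed).  Accepted
splits recurse on the resulting linear pieces; a final pruning pass re-merges
adjacent segments whose means do not differ at alpha.

Ties in the maximum are broken toward the earliest window start, then the
shortest window — deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .positions import PdSeries

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class TrimConfig:
    """Outlier trimming of the PD series before segmentation.

    ``pd_low`` (bp): PDs below this are discarded as near-zero gaps between
    non-overlapping reads of one amplicon (default 300, about the upper
    amplicon length).  ``pd_high_quantile``: PDs above this per-genome
    quantile are discarded as stretches without any mappable positions
    (default 0.995).
    """

    pd_low: int = 300
    pd_high_quantile: float = 0.995

    def __post_init__(self):
        if self.pd_low < 0:
            raise ValueError("pd_low must be >= 0")
        if not (0.5 < self.pd_high_quantile <= 1.0):
            raise ValueError("pd_high_quantile must be in (0.5, 1]")


@dataclasses.dataclass
class CbsConfig:
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 4
    transform: str = "log2p1"  # or "identity"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if self.transform not in ("log2p1", "identity"):
            raise ValueError("transform must be 'log2p1' or 'identity'")


@dataclasses.dataclass
class TrimmedSeries:
    """PD values retained after outlier trimming, with a map to original indices."""

    chrom: str
    values: np.ndarray  # retained PD values (untransformed)
    starts: np.ndarray  # genomic starts of the retained positions
    ends: np.ndarray
    index_map: np.ndarray  # retained idx -> original position idx (strictly increasing)


# ---------------------------------------------------------------------------
# trimming


def trim_outliers(
    series: PdSeries, cfg: TrimConfig, upper: Optional[float] = None
) -> TrimmedSeries:
    """Drop outlier PDs; ``upper`` overrides the per-series quantile cut.

    When segmenting a whole genome the upper cut should be the *genome-wide*
    quantile — :func:`segment_chromosomes` computes it over all chromosomes
    and passes it down.  Retained values are those in [pd_low, upper].
    """
    vals = np.asarray(series.pd, dtype=np.float64)
    if upper is None:
        upper = float(np.quantile(vals, cfg.pd_high_quantile)) if len(vals) else 0.0
    keep = (vals >= cfg.pd_low) & (vals <= upper)
    idx = np.flatnonzero(keep)
    if len(idx) == 0 and len(vals) > 0:
        warnings.warn(
            f"{series.chrom}: all {len(vals)} PD values trimmed; chromosome skipped",
            stacklevel=2,
        )
    return TrimmedSeries(
        chrom=series.chrom,
        values=vals[idx],
        starts=series.starts[idx],
        ends=series.ends[idx],
        index_map=idx,
    )


# ---------------------------------------------------------------------------
# max-statistic kernels

_KERNEL_CACHE: dict = {}


def _py_max_stat(c2, n, min_width, circular, total):
    """Best window by |W - k*mu|/sqrt(k(n-k)); ties to smallest (i, k)."""
    mu = total / n
    best, bi, bk = -1.0, -1, -1
    i_max = n if circular else n - min_width
    for i in range(i_max):
        for k in range(min_width, n - min_width + 1):
            if not circular and i + k > n:
                break
            # every resulting piece must have >= min_width points (or be empty)
            if i + k <= n:
                left = i
                right = n - i - k
                if (0 < left < min_width) or (0 < right < min_width):
                    continue
            else:
                a = i + k - n
                if a < min_width or n - i < min_width:
                    continue
            w = c2[i + k] - c2[i]
            stat = abs(w - k * mu) / math.sqrt(k * (n - k))
            if stat > best + 1e-12:
                best, bi, bk = stat, i, k
    return best, bi, bk


def _py_perm_exceed(x, obs, n_perm, min_width, circular, allowed, seed):
    rng = np.random.RandomState(seed)
    n = len(x)
    y = x.copy()
    e = 0
    for t in range(n_perm):
        rng.shuffle(y)
        c2 = np.concatenate([[0.0], np.cumsum(np.concatenate([y, y]))])
        best, _, _ = _py_max_stat(c2, n, min_width, circular, float(np.sum(y)))
        if best >= obs - 1e-9:
            e += 1
            if e > allowed:
                return e, t + 1
    return e, n_perm


if _HAVE_NUMBA:

    @njit(cache=True)
    def _nb_max_stat(c2, n, min_width, circular, total):  # pragma: no cover - jit
        mu = total / n
        best = -1.0
        bi = -1
        bk = -1
        i_max = n if circular else n - min_width
        for i in range(i_max):
            for k in range(min_width, n - min_width + 1):
                if (not circular) and i + k > n:
                    break
                if i + k <= n:
                    left = i
                    right = n - i - k
                    if (0 < left < min_width) or (0 < right < min_width):
                        continue
                else:
                    a = i + k - n
                    if a < min_width or n - i < min_width:
                        continue
                w = c2[i + k] - c2[i]
                stat = abs(w - k * mu) / math.sqrt(k * (n - k))
                if stat > best + 1e-12:
                    best = stat
                    bi = i
                    bk = k
        return best, bi, bk

    @njit(cache=True)
    def _nb_perm_exceed(x, obs, n_perm, min_width, circular, allowed, seed):  # pragma: no cover - jit
        np.random.seed(seed)
        n = x.shape[0]
        y = x.copy()
        c2 = np.empty(2 * n + 1)
        e = 0
        t_done = 0
        for t in range(n_perm):
            np.random.shuffle(y)
            total = 0.0
            c2[0] = 0.0
            for q in range(n):
                total += y[q]
                c2[q + 1] = c2[q]
                c2[q + 1] += y[q]
            for q in range(n):
                c2[n + q + 1] = c2[n + q] + y[q]
            mu = total / n
            exceeded = False
            i_max = n if circular else n - min_width
            for i in range(i_max):
                if exceeded:
                    break
                for k in range(min_width, n - min_width + 1):
                    if (not circular) and i + k > n:
                        break
                    if i + k <= n:
                        left = i
                        right = n - i - k
                        if (0 < left < min_width) or (0 < right < min_width):
                            continue
                    else:
                        a = i + k - n
                        if a < min_width or n - i < min_width:
                            continue
                    w = c2[i + k] - c2[i]
                    stat = abs(w - k * mu) / math.sqrt(k * (n - k))
                    if stat >= obs - 1e-9:
                        exceeded = True
                        break
            t_done = t + 1
            if exceeded:
                e += 1
                if e > allowed:
                    return e, t_done
        return e, t_done


def _max_stat(x: np.ndarray, min_width: int, circular: bool):
    n = len(x)
    c2 = np.concatenate([[0.0], np.cumsum(np.concatenate([x, x]))])
    total = float(np.sum(x))
    if _HAVE_NUMBA:
        return _nb_max_stat(c2, n, min_width, circular, total)
    return _py_max_stat(c2, n, min_width, circular, total)


def _perm_pvalue_accepts(
    x: np.ndarray, obs: float, cfg: CbsConfig, circular: bool, seed: int
) -> bool:
    """True iff the permutation p-value of ``obs`` is < alpha.

    Early-stops once enough permuted maxima exceed ``obs`` that p >= alpha is
    certain; acceptance always runs the full ``n_perm`` permutations.
    p-hat = (1 + #exceedances) / (1 + n_perm).
    """
    a_bound = cfg.alpha * (1 + cfg.n_perm)
    allowed = int(math.floor(a_bound - 1.0 - 1e-9))  # largest e with (1+e) < a_bound
    if allowed < 0:
        return False  # alpha too small for this n_perm to ever reject
    fn = _nb_perm_exceed if _HAVE_NUMBA else _py_perm_exceed
    e, _ = fn(
        np.asarray(x, dtype=np.float64),
        float(obs),
        int(cfg.n_perm),
        int(cfg.min_width),
        bool(circular),
        int(allowed),
        int(seed) % (2**32),
    )
    return e <= allowed


# ---------------------------------------------------------------------------
# recursion and pruning


def cbs_segment(values: Sequence[float], cfg: CbsConfig) -> List[Tuple[int, int]]:
    """Segment a (transformed) series; returns inclusive (first, last) index pairs.

    The first level treats the series as circular (wrap-around windows
    allowed); accepted splits cut the series at the window boundaries and the
    recursion continues on linear pieces.  Adjacent segments whose means do
    not differ at alpha (Welch t-test) are re-merged in a pruning pass.
    Deterministic given ``cfg.seed``.
    """
    x = np.asarray(values, dtype=np.float64)
    if len(x) == 0:
        return []
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in segmentation input")
    ss = np.random.SeedSequence(cfg.seed)
    seed_pool = iter(ss.generate_state(4096, dtype=np.uint32))

    cuts: List[int] = []

    def recurse(lo: int, hi: int, circular: bool) -> None:
        n = hi - lo
        if n < 2 * cfg.min_width:
            return
        arc = x[lo:hi]
        if float(np.ptp(arc)) == 0.0:
            return  # constant: no split can be significant
        best, i, k = _max_stat(arc, cfg.min_width, circular)
        if best <= 0 or i < 0:
            return
        if not _perm_pvalue_accepts(arc, best, cfg, circular, int(next(seed_pool))):
            return
        if i + k <= n:
            local_cuts = [c for c in (i, i + k) if 0 < c < n]
        else:  # wrap-around window: cut where it re-enters and where it starts
            local_cuts = [c for c in (i + k - n, i) if 0 < c < n]
        pieces = sorted(set(local_cuts))
        cuts.extend(lo + c for c in pieces)
        bounds = [lo] + [lo + c for c in pieces] + [hi]
        for a, b in zip(bounds[:-1], bounds[1:]):
            recurse(a, b, False)

    recurse(0, len(x), True)
    bounds = [0] + sorted(set(cuts)) + [len(x)]
    segs = [(a, b - 1) for a, b in zip(bounds[:-1], bounds[1:])]
    return _prune_segments(x, segs, cfg.alpha)


def _prune_segments(
    x: np.ndarray, segs: List[Tuple[int, int]], alpha: float
) -> List[Tuple[int, int]]:
    """Merge adjacent segments whose means do not differ at ``alpha``."""
    segs = list(segs)
    changed = True
    while changed and len(segs) > 1:
        changed = False
        best_p, best_i = -1.0, -1
        for i in range(len(segs) - 1):
            a = x[segs[i][0] : segs[i][1] + 1]
            b = x[segs[i + 1][0] : segs[i + 1][1] + 1]
            if a.std() == 0.0 and b.std() == 0.0:
                p = 1.0 if a.mean() == b.mean() else 0.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = float(_scipy_stats.ttest_ind(a, b, equal_var=False).pvalue)
                if not np.isfinite(p):
                    p = 1.0
            if p > best_p:
                best_p, best_i = p, i
        if best_p >= alpha:
            i = best_i
            segs[i : i + 2] = [(segs[i][0], segs[i + 1][1])]
            changed = True
    return segs


# ---------------------------------------------------------------------------
# whole-genome driver


def transform_values(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log2p1":
        return np.log2(np.asarray(values, dtype=np.float64) + 1.0)
    return np.asarray(values, dtype=np.float64)


def segment_chromosomes(
    pd_series: Sequence[PdSeries],
    trim_cfg: Optional[TrimConfig] = None,
    cbs_cfg: Optional[CbsConfig] = None,
) -> pd.DataFrame:
    """Trim and CBS-segment every chromosome's PD series.

    The upper trim quantile is computed genome-wide (over the pooled PDs of
    all chromosomes).  Returns one row per segment with the genomic span of
    its outermost retained positions and the mean PD on the *untransformed*
    scale; chromosomes with fewer than ``min_width`` retained positions
    become a single segment flagged ``trivial``.
    """
    trim_cfg = trim_cfg or TrimConfig()
    cbs_cfg = cbs_cfg or CbsConfig()
    pd_series = list(pd_series)

    pooled = np.concatenate([s.pd for s in pd_series]) if pd_series else np.array([])
    upper = (
        float(np.quantile(pooled.astype(np.float64), trim_cfg.pd_high_quantile))
        if len(pooled)
        else 0.0
    )

    rows = []
    ss = np.random.SeedSequence(cbs_cfg.seed)
    chrom_seeds = ss.generate_state(max(len(pd_series), 1), dtype=np.uint32)
    for ci, series in enumerate(sorted(pd_series, key=lambda s: s.chrom)):
        trimmed = trim_outliers(series, trim_cfg, upper=upper)
        nv = len(trimmed.values)
        if nv == 0:
            continue
        cfg_c = dataclasses.replace(cbs_cfg, seed=int(chrom_seeds[ci % len(chrom_seeds)]))
        if nv < cbs_cfg.min_width:
            segs = [(0, nv - 1)]
            flagged = True
        else:
            tx = transform_values(trimmed.values, cbs_cfg.transform)
            segs = cbs_segment(tx, cfg_c)
            flagged = False
        for first, last in segs:
            vals = trimmed.values[first : last + 1]
            rows.append(
                {
                    "chrom": trimmed.chrom,
                    "first_idx": first,
                    "last_idx": last,
                    "start_bp": int(trimmed.starts[first]),
                    "end_bp": int(trimmed.ends[last]),
                    "n_positions": last - first + 1,
                    "mean_pd": float(vals.mean()),
                    "segment_stat": float(
                        transform_values(vals, cbs_cfg.transform).mean()
                    ),
                    "trivial": flagged,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "first_idx",
            "last_idx",
            "start_bp",
            "end_bp",
            "n_positions",
            "mean_pd",
            "segment_stat",
            "trivial",
        ],
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator facade


class CBSSegmenter:
    """Circular-binary-segmentation changepoint estimator, sklearn style.

    Parameters mirror :class:`CbsConfig`.  ``fit(X)`` segments a 1-D series
    (or single-column array); fitted attributes are ``segments_`` (inclusive
    index pairs), ``labels_`` (segment id per point) and ``means_``.
    ``predict(X)`` returns ``labels_`` for the fitted series.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        n_perm: int = 1000,
        min_width: int = 4,
        transform: str = "identity",
        seed: int = 0,
    ):
        self.alpha = alpha
        self.n_perm = n_perm
        self.min_width = min_width
        self.transform = transform
        self.seed = seed

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "min_width": self.min_width,
            "transform": self.transform,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "CBSSegmenter":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> CbsConfig:
        return CbsConfig(
            alpha=self.alpha,
            n_perm=self.n_perm,
            min_width=self.min_width,
            transform=self.transform,
            seed=self.seed,
        )

    def fit(self, X, y=None) -> "CBSSegmenter":
        x = np.asarray(X, dtype=np.float64)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("CBSSegmenter expects a 1-D series")
        cfg = self._config()
        tx = transform_values(x, cfg.transform)
        self.segments_ = cbs_segment(tx, cfg)
        labels = np.empty(len(x), dtype=np.int64)
        for sid, (a, b) in enumerate(self.segments_):
            labels[a : b + 1] = sid
        self.labels_ = labels
        self.means_ = np.array([x[a : b + 1].mean() for a, b in self.segments_])
        self.n_features_in_ = 1
        return self

    def predict(self, X=None) -> np.ndarray:
        if not hasattr(self, "labels_"):
            raise RuntimeError("CBSSegmenter is not fitted")
        return self.labels_

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict()
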