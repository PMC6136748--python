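"""Monte-Carlo bootstrap of the t-test rejection proportion.

The procedure estimates how reliably an unpooled (Welch) two-sample
t-test detects a group difference under resampling: in each bootstrap
iteration a number of subsample pairs is drawn with replacement from the
two observed pools (each side re-balanced to a common subsample size),
each pair is tested at level alpha, and the rejection indicator is
recorded.  An outer replication loop repeats the whole experiment to
attach empirical 95% percentile confidence limits to the mean rejection
proportion.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats


@dataclasses.dataclass(frozen=True)
class BootstrapConfig:
    """Counts and level of the rejection-proportion bootstrap.

    Defaults follow the original design: 1000 bootstrap iterations, each
    producing 12 subsample pairs of size 17 per side, the whole procedure
    replicated 100 times for the confidence limits.  Subsampling is with
    replacement, so subsample_n may exceed a source-pool size.
    """

    n_boot: int = 1000
    pairs_per_sample: int = 12
    subsample_n: int = 17
    n_outer: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_boot, self.pairs_per_sample, self.n_outer) < 1:
            raise ValueError("all bootstrap counts must be >= 1")
        if self.subsample_n < 2:
            raise ValueError("subsample_n must be >= 2 for the t-test to be defined")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclasses.dataclass(frozen=True)
class BootstrapResult:
    mean_rejection: float
    ci_low: float
    ci_high: float
    per_outer_means: tuple[float, ...]


def _welch_reject(
    a: np.ndarray, b: np.ndarray, alpha: float
) -> np.ndarray:
    """Vectorized Welch test over rows of a and b; True where p <= alpha."""
    n1 = a.shape[1]
    n2 = b.shape[1]
    m1 = a.mean(axis=1)
    m2 = b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1) / n1
    v2 = b.var(axis=1, ddof=1) / n2
    se2 = v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate resamples (zero variance on both sides) cannot reject
    p = np.where(np.isfinite(p), p, 1.0)
    return p <= alpha


def rejection_bootstrap(
    group_a: Sequence[float], group_b: Sequence[float], cfg: BootstrapConfig
) -> BootstrapResult:
    """Bootstrap estimate of the Welch-test rejection proportion.

    For each of cfg.n_outer outer replicates: draw cfg.n_boot x
    cfg.pairs_per_sample subsample pairs (cfg.subsample_n draws with
    replacement from each pool), test each pair two-tailed at
    cfg.alpha, and average the rejection indicators.  The overall mean
    and the 2.5/97.5 empirical percentiles of the outer means are
    returned.  Each outer replicate uses an independent child stream
    spawned from the root seed, so results are reproducible and outer
    replicates are order-independent.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_tests = cfg.n_boot * cfg.pairs_per_sample
    per_outer = np.empty(cfg.n_outer)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_outer)
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        idx_a = rng.integers(0, a.size, size=(n_tests, cfg.subsample_n))
        idx_b = rng.integers(0, b.size, size=(n_tests, cfg.subsample_n))
        rejected = _welch_reject(a[idx_a], b[idx_b], cfg.alpha)
        per_outer[i] = rejected.mean()
    ci_low, ci_high = np.percentile(per_outer, [2.5, 97.5])
    return BootstrapResult(
        mean_rejection=float(per_outer.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        per_outer_means=tuple(per_outer.tolist()),
    )
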