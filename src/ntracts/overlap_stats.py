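"""Segment sharing between genomes and desert-depletion permutation tests.

Sharing is quantified on binary ancestry vectors: the genome is cut into
fixed windows (default 100 kb) and each window is flagged if any
Neanderthal segment overlaps it.  Vector pairs are compared by Pearson
correlation with a block-bootstrap CI (5 Mb blocks, respecting linkage);
groups of correlations are compared by the two-sided Wilcoxon rank-sum
test.  Depletion of segments in introgression deserts is tested by
permutation: each segment is re-placed uniformly at random within the
callable portion of its own chromosome, preserving its length, and the
one-sided p-value is the fraction of permutations with desert overlap at
most the observed one (add-one corrected).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import RegionSet


@dataclasses.dataclass
class WindowRegistry:
    window_bp: int
    windows: pd.DataFrame  # chrom, start, end

    def __len__(self):
        return len(self.windows)


@dataclasses.dataclass
class OverlapTest:
    r: float
    ci95: tuple[float, float]
    n_windows: int
    flagged: bool = False


@dataclasses.dataclass
class DesertTest:
    observed_bp: int
    total_segment_bp: int
    n_permutations: int
    p_depletion: float
    null_mean: float
    null_quantiles: tuple[float, float, float]  # 2.5%, 50%, 97.5%
    seed: int


def make_window_registry(chrom_sizes: dict[str, int],
                         window_bp: int = 100_000) -> WindowRegistry:
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, window_bp)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + window_bp, size))))
    return WindowRegistry(window_bp, pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def ancestry_vector(segments: RegionSet, registry: WindowRegistry) -> np.ndarray:
    """1 per window overlapped by any segment, else 0."""
    out = np.zeros(len(registry), dtype=np.int8)
    w = registry.windows
    for chrom, grp in w.groupby("chrom", sort=False):
        ivs = segments.intervals.get(chrom)
        if ivs is None:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for s, e in ivs:
            out[grp.index[(starts < e) & (ends > s)]] = 1
    return out


def overlap_correlation(vec_a: np.ndarray, vec_b: np.ndarray,
                        registry: WindowRegistry | None = None,
                        block_kb: float = 5000.0, n_boot: int = 1000,
                        seed: int = 0) -> OverlapTest:
    """Pearson correlation of two binary vectors with block-bootstrap CI."""
    vec_a = np.asarray(vec_a, float)
    vec_b = np.asarray(vec_b, float)
    if vec_a.shape != vec_b.shape:
        raise ValueError("vectors must share one window registry")
    if vec_a.std() == 0 or vec_b.std() == 0:
        return OverlapTest(np.nan, (np.nan, np.nan), len(vec_a), flagged=True)
    r = float(np.corrcoef(vec_a, vec_b)[0, 1])
    if registry is not None:
        wpb = max(int(block_kb * 1000 // registry.window_bp), 1)
        codes, _ = pd.factorize(pd.MultiIndex.from_arrays(
            [registry.windows["chrom"],
             registry.windows["start"].to_numpy() // (wpb * registry.window_bp)]))
    else:
        wpb = max(int(block_kb * 1000 // 100_000), 1)
        codes = np.arange(len(vec_a)) // wpb
    n_blocks = codes.max() + 1
    if n_blocks < 2:
        raise ValueError("need at least 2 bootstrap blocks")
    members = [np.flatnonzero(codes == b) for b in range(n_blocks)]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.integers(0, n_blocks, n_blocks)
        idx = np.concatenate([members[b] for b in pick])
        a, b_ = vec_a[idx], vec_b[idx]
        if a.std() == 0 or b_.std() == 0:
            boots[i] = np.nan
        else:
            boots[i] = np.corrcoef(a, b_)[0, 1]
    lo, hi = np.nanquantile(boots, [0.025, 0.975])
    return OverlapTest(r, (float(lo), float(hi)), len(vec_a))


def compare_groups(corrs_a, corrs_b):
    """Two-sided Wilcoxon/Mann-Whitney rank-sum comparison of correlations.

    Uses the exact null distribution for small samples without ties and
    the tie-corrected normal approximation otherwise.
    """
    corrs_a = np.asarray(corrs_a, float)
    corrs_b = np.asarray(corrs_b, float)
    if len(corrs_a) == 0 or len(corrs_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(corrs_a, corrs_b, alternative="two-sided",
                             method="auto")
    return float(res.statistic), float(res.pvalue)


def desert_overlap_test(segments: RegionSet, deserts: RegionSet,
                        callable_regions: RegionSet, n_perm: int = 10_000,
                        seed: int = 0) -> DesertTest:
    """One-sided depletion test of segment overlap with deserts.

    Each permutation independently re-places every segment uniformly at
    random within a callable interval of its own chromosome (length
    preserved; overlaps among placed segments permitted).
    """
    rng = np.random.default_rng(seed)
    observed = segments.overlap_bp(deserts)
    total = segments.total_bp()

    null = np.zeros(n_perm)
    for chrom in segments.chromosomes:
        segs = segments.intervals[chrom]
        call = callable_regions.intervals.get(chrom)
        if call is None:
            raise ValueError(f"no callable regions on chromosome {chrom}")
        des = deserts.intervals.get(chrom, np.empty((0, 2), dtype=np.int64))
        # cumulative desert coverage G(x): overlap of [s,e) with deserts
        # is G(e) - G(s); G is piecewise linear with slope 1 inside deserts
        if len(des):
            xs = des.ravel().astype(float)
            widths = des[:, 1] - des[:, 0]
            gvals = np.zeros(2 * len(des))
            gvals[0::2] = np.concatenate([[0], np.cumsum(widths)[:-1]])
            gvals[1::2] = np.cumsum(widths)
            G = lambda x: np.interp(x, xs, gvals,
                                    left=0.0, right=float(widths.sum()))
        else:
            G = lambda x: np.zeros_like(np.asarray(x, float))
        call_len = (call[:, 1] - call[:, 0]).astype(np.int64)
        for s0, e0 in segs:
            L = int(e0 - s0)
            room = call_len - L
            ok = room >= 0
            if not ok.any():
                raise ValueError(
                    f"segment of {L} bp exceeds callable span on {chrom}")
            w = np.where(ok, room + 1, 0).astype(float)
            iv = rng.choice(len(call), size=n_perm, p=w / w.sum())
            starts = call[iv, 0] + (rng.random(n_perm) * (room[iv] + 1)).astype(np.int64)
            null += G(starts + L) - G(starts)
    p = (1 + int((null <= observed).sum())) / (1 + n_perm)
    q = np.quantile(null, [0.025, 0.5, 0.975])
    return DesertTest(observed_bp=int(observed), total_segment_bp=int(total),
                      n_permutations=n_perm, p_depletion=float(p),
                      null_mean=float(null.mean()),
                      null_quantiles=(float(q[0]), float(q[1]), float(q[2])),
                      seed=seed)
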