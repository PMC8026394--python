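"""f-statistics (f2, f3, f4, D) with weighted block jackknife and f4-ratios.

All statistics are moments of population derived-allele frequencies.  A SNP
enters a statistic only if every population in that statistic has data
there (listwise deletion per statistic).  Standard errors come from a
weighted block jackknife over fixed physical windows (default 5 Mb,
anchored at position 0 of each chromosome), with block weights equal to
their SNP counts — the usual treatment for linked markers.

``f2``/``f3`` apply small-sample heterozygosity corrections by default
(dropped for any population observed on a single chromosome, where the
correction is undefined); ``f4``/``D`` are unbiased without correction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .formats_io import MISSING, GenotypeData


@dataclasses.dataclass
class FreqTable:
    """Per-population derived-allele frequencies and observed chromosome counts."""

    pops: list[str]
    freq: np.ndarray   # (n_snps, n_pops), NaN = missing
    n: np.ndarray      # (n_snps, n_pops), observed chromosomes
    chrom: np.ndarray  # (n_snps,) str
    pos_bp: np.ndarray  # (n_snps,) int

    def col(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError:
            raise KeyError(f"population {pop!r} not in table") from None

    def p(self, pop: str) -> np.ndarray:
        return self.freq[:, self.col(pop)]

    def nn(self, pop: str) -> np.ndarray:
        return self.n[:, self.col(pop)]


@dataclasses.dataclass
class FStatResult:
    kind: str
    pops: tuple
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_snps: int


@dataclasses.dataclass
class F4RatioResult:
    alpha: float
    se: float
    ci95: tuple[float, float]
    numerator: FStatResult
    denominator: FStatResult
    reliable: bool


def allele_freqs(data: GenotypeData, pop_spec: dict[str, str] | None = None) -> FreqTable:
    """Population frequency table from genotypes.

    ``pop_spec`` maps sample_id -> population; defaults to the sample
    table's own population column.  Diploid samples contribute two
    chromosomes per observed genotype, pseudo-haploid samples one.
    """
    samples = data.samples
    if pop_spec is None:
        pop_of = dict(zip(samples["sample_id"], samples["population"]))
    else:
        unknown = set(pop_spec) - set(samples["sample_id"])
        if unknown:
            raise KeyError(f"pop_spec samples not in data: {sorted(unknown)}")
        pop_of = dict(pop_spec)

    use = samples["sample_id"].isin(pop_of).to_numpy()
    pops = sorted({pop_of[s] for s in samples.loc[use, "sample_id"]})
    n_snps = data.n_snps
    der = np.zeros((n_snps, len(pops)))
    tot = np.zeros((n_snps, len(pops)))
    ph = (samples["ploidy"] == "pseudo_haploid").to_numpy()
    for k, sid in enumerate(samples["sample_id"]):
        if sid not in pop_of:
            continue
        j = pops.index(pop_of[sid])
        g = data.geno[:, k].astype(float)
        obs = g != MISSING
        if ph[k]:
            der[obs, j] += g[obs] / 2.0
            tot[obs, j] += 1.0
        else:
            der[obs, j] += g[obs]
            tot[obs, j] += 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(tot > 0, der / np.maximum(tot, 1), np.nan)
    freq[tot == 0] = np.nan
    return FreqTable(
        pops=pops,
        freq=freq,
        n=tot,
        chrom=data.snp["chrom"].to_numpy(str),
        pos_bp=data.snp["pos_bp"].to_numpy(np.int64),
    )


def freq_table_from_arrays(pops, freq, n=None, chrom=None, pos_bp=None) -> FreqTable:
    """Assemble a FreqTable directly from frequency arrays (simulation path)."""
    freq = np.asarray(freq, dtype=float)
    n_snps = freq.shape[0]
    if n is None:
        n = np.full_like(freq, 1e9)
    if chrom is None:
        chrom = np.repeat("1", n_snps)
    if pos_bp is None:
        pos_bp = np.arange(1, n_snps + 1, dtype=np.int64)
    return FreqTable(list(pops), freq, np.asarray(n, float),
                     np.asarray(chrom, str), np.asarray(pos_bp, np.int64))


# ---------------------------------------------------------------------------
# per-SNP contributions
# ---------------------------------------------------------------------------

def _het_corr(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """p(1-p)/(n-1) where n > 1, else 0 (correction undefined at n = 1)."""
    out = np.zeros_like(p)
    ok = n > 1
    out[ok] = p[ok] * (1 - p[ok]) / (n[ok] - 1)
    return out


def f2(freqs: FreqTable, i: str, j: str, corrected: bool = True) -> np.ndarray:
    pi, pj = freqs.p(i), freqs.p(j)
    out = (pi - pj) ** 2
    if corrected:
        out = out - _het_corr(pi, freqs.nn(i)) - _het_corr(pj, freqs.nn(j))
    return out


def f3(freqs: FreqTable, c: str, a: str, b: str, corrected: bool = True) -> np.ndarray:
    pc, pa, pb = freqs.p(c), freqs.p(a), freqs.p(b)
    out = (pc - pa) * (pc - pb)
    if corrected:
        out = out - _het_corr(pc, freqs.nn(c))
    return out


def f4_and_d(freqs: FreqTable, a: str, b: str, c: str, d: str):
    """Per-SNP f4 numerator and the ABBA-BABA denominator series.

    D is the ratio of sums: sum(num) / sum(den).
    """
    pa, pb, pc, pd_ = (freqs.p(x) for x in (a, b, c, d))
    num = (pa - pb) * (pc - pd_)
    den = (pa + pb - 2 * pa * pb) * (pc + pd_ - 2 * pc * pd_)
    return num, den


# ---------------------------------------------------------------------------
# weighted block jackknife
# ---------------------------------------------------------------------------

def assign_blocks(chrom, pos_bp, block_mb: float = 5.0) -> np.ndarray:
    """Block index per SNP: fixed windows of ``block_mb`` from 0 per chromosome."""
    width = int(block_mb * 1_000_000)
    win = np.asarray(pos_bp, np.int64) // width
    ccodes, _ = pd.factorize(np.asarray(chrom, str), sort=True)
    combined = ccodes.astype(np.int64) * (int(win.max()) + 1) + win
    _, codes = np.unique(combined, return_inverse=True)
    return codes


def block_jackknife(num, den, chrom, pos_bp, block_mb: float = 5.0,
                    kind: str = "ratio", pops: tuple = ()) -> FStatResult:
    """Weighted delete-one-block jackknife for a ratio-of-sums statistic.

    For mean-type statistics pass ``den = np.ones_like(num)``.  Block
    weights are SNP counts; with equal weights this reduces to the plain
    delete-one jackknife variance.
    """
    num = np.asarray(num, float)
    den = np.asarray(den, float)
    ok = np.isfinite(num) & np.isfinite(den)
    num, den = num[ok], den[ok]
    blocks = assign_blocks(np.asarray(chrom)[ok], np.asarray(pos_bp)[ok], block_mb)
    g = blocks.max() + 1 if len(blocks) else 0
    if g < 2:
        raise ValueError("block jackknife needs at least 2 non-empty blocks")

    n = len(num)
    m = np.bincount(blocks, minlength=g).astype(float)
    num_b = np.bincount(blocks, weights=num, minlength=g)
    den_b = np.bincount(blocks, weights=den, minlength=g)
    N, D = num_b.sum(), den_b.sum()
    theta = N / D
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_j = (N - num_b) / (D - den_b)
    if not np.isfinite(theta_j).all():
        raise ValueError("leave-one-out estimate undefined (zero denominator)")

    h = n / m
    est_j = g * theta - np.sum((1.0 - m / n) * theta_j)
    tau = h * theta - (h - 1.0) * theta_j
    var = np.sum((tau - est_j) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(max(var, 0.0)))
    z = float(theta / se) if se > 0 else (0.0 if theta == 0 else np.inf * np.sign(theta))
    return FStatResult(kind=kind, pops=tuple(pops), estimate=float(theta),
                       se=se, z=z, n_blocks=int(g), n_snps=int(n))


def _mean_stat(freqs: FreqTable, contrib: np.ndarray, kind: str, pops,
               block_mb: float) -> FStatResult:
    return block_jackknife(contrib, np.ones_like(contrib), freqs.chrom,
                           freqs.pos_bp, block_mb, kind=kind, pops=pops)


def f2_stat(freqs, i, j, corrected=True, block_mb=5.0) -> FStatResult:
    return _mean_stat(freqs, f2(freqs, i, j, corrected), "f2", (i, j), block_mb)


def f3_stat(freqs, c, a, b, corrected=True, block_mb=5.0) -> FStatResult:
    return _mean_stat(freqs, f3(freqs, c, a, b, corrected), "f3", (c, a, b), block_mb)


def f4_stat(freqs, a, b, c, d, block_mb=5.0) -> FStatResult:
    num, _ = f4_and_d(freqs, a, b, c, d)
    return _mean_stat(freqs, num, "f4", (a, b, c, d), block_mb)


def d_stat(freqs, a, b, c, d, block_mb=5.0) -> FStatResult:
    num, den = f4_and_d(freqs, a, b, c, d)
    return block_jackknife(num, den, freqs.chrom, freqs.pos_bp, block_mb,
                           kind="D", pops=(a, b, c, d))


def f4_ratio(freqs: FreqTable, A: str, O: str, X: str, C: str, B: str,
             block_mb: float = 5.0) -> F4RatioResult:
    """Admixture proportion as f4(A,O;X,C) / f4(A,O;B,C).

    In the archaic-ancestry preset A and B are the two high-quality
    archaic genomes (A the more distant relative of the introgressing
    population, B the closer), O and C two African populations and X the
    test individual; alpha is then X's archaic ancestry proportion.
    X = B gives alpha = 1 and X = C gives alpha = 0.
    """
    num, _ = f4_and_d(freqs, A, O, X, C)
    den, _ = f4_and_d(freqs, A, O, B, C)
    ok = np.isfinite(num) & np.isfinite(den)
    res = block_jackknife(num[ok], den[ok], freqs.chrom[ok], freqs.pos_bp[ok],
                          block_mb, kind="f4_ratio", pops=(A, O, X, C, B))
    num_res = block_jackknife(num[ok], np.ones(ok.sum()), freqs.chrom[ok],
                              freqs.pos_bp[ok], block_mb, "f4", (A, O, X, C))
    den_res = block_jackknife(den[ok], np.ones(ok.sum()), freqs.chrom[ok],
                              freqs.pos_bp[ok], block_mb, "f4", (A, O, B, C))
    ci = (res.estimate - 1.96 * res.se, res.estimate + 1.96 * res.se)
    return F4RatioResult(alpha=res.estimate, se=res.se, ci95=ci,
                         numerator=num_res, denominator=den_res,
                         reliable=abs(den_res.z) >= 3.0)
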