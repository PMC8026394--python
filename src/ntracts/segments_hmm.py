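"""Diploid HMM for Neanderthal-ancestry tracts in genetic-map coordinates.

The genome is cut into fixed-width genetic bins (default 0.05 cM).  Hidden
states are Neanderthal copy numbers {0, 1, 2}; the chain factorises over
the two haplotypes, each an independent two-state Markov process with
stationary Neanderthal fraction ``F`` and switch intensity ``tau`` per cM
(so tract lengths are ~Exp(tau) in cM at stationarity).  Emissions are
per-read: a read at a SNP is contaminant with probability ``c`` (drawing
from the contaminant-population frequency) and otherwise copies one of
the two haplotypes, whose allele frequency is a mixture of the archaic
and African panels according to the copy number; sequencing error ``e``
flips alleles.  Reads are treated as independent given the state — a
deliberate simplification that ignores within-individual read
correlation at a site.

Decoding is exact forward–backward in log space; parameters can be
re-estimated by bounded likelihood maximisation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .formats_io import GeneticMap, RegionSet


@dataclasses.dataclass
class BinTrack:
    """Binned genome skeleton plus per-SNP read counts and frequencies."""

    gmap: GeneticMap
    bin_cm: float
    n_bins: dict[str, int]
    edges_cm: dict[str, np.ndarray]           # n_bins+1 edges per chromosome
    snp: pd.DataFrame                          # chrom, cm, bin, n_der, n_anc,
                                               # p_nea, p_afr, p_cont
    emissions: dict[str, np.ndarray] | None = None  # (n_bins, 3) logliks


@dataclasses.dataclass
class AncestrySegment:
    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    mean_posterior: float
    copies: int

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclasses.dataclass
class SegmentSummary:
    total_cm: float
    longest_cm: float
    n_segments_gt5cm: int
    per_chrom: pd.DataFrame


@dataclasses.dataclass
class DecodedTrack:
    track: BinTrack
    posteriors: dict[str, np.ndarray]   # (n_bins, 3)
    loglik: float
    params: dict


def bin_genome(gmap: GeneticMap, panel: pd.DataFrame,
               bin_cm: float = 0.05) -> BinTrack:
    """Bin every chromosome of the map and assign each panel SNP to a bin.

    Bins are right-open ``[lo + i*w, lo + (i+1)*w)``; the terminal bin may
    be shorter.  A SNP on a boundary belongs to the bin it opens.
    """
    n_bins, edges = {}, {}
    for chrom in gmap.chromosomes:
        lo, hi = gmap.span_cm(chrom)
        nb = max(int(np.ceil((hi - lo) / bin_cm - 1e-9)), 1)
        e = lo + bin_cm * np.arange(nb + 1)
        e[-1] = hi
        n_bins[chrom], edges[chrom] = nb, e
    snp = panel[["chrom", "pos_bp", "cm"]].copy().reset_index(drop=True)
    bins = np.zeros(len(snp), dtype=np.int64)
    for chrom, grp in snp.groupby("chrom", sort=False):
        if chrom not in n_bins:
            raise KeyError(f"panel chromosome {chrom!r} not in map")
        lo, _ = gmap.span_cm(chrom)
        # epsilon keeps boundary SNPs in the right-open bin they start
        b = np.floor((grp["cm"].to_numpy() - lo + 1e-9) / bin_cm).astype(np.int64)
        bins[grp.index] = np.clip(b, 0, n_bins[chrom] - 1)
    snp["bin"] = bins
    for col in ("n_der", "n_anc"):
        snp[col] = 0
    return BinTrack(gmap=gmap, bin_cm=bin_cm, n_bins=n_bins, edges_cm=edges,
                    snp=snp)


def smooth_freq(p: np.ndarray, n: float = 100.0) -> np.ndarray:
    """Pseudo-count smoothing (add 0.5/(n+1)) keeping frequencies off 0/1."""
    return (np.asarray(p, float) * n + 0.5) / (n + 1.0)


def add_read_counts(track: BinTrack, frags: pd.DataFrame,
                    freqs: dict[str, np.ndarray],
                    freq_n: float = 100.0) -> BinTrack:
    """Attach per-SNP derived/ancestral read counts and source frequencies."""
    f = frags[frags["snp_index"] >= 0]
    idx = f["snp_index"].to_numpy()
    der = f["allele"].to_numpy()
    n = len(track.snp)
    track.snp["n_der"] = np.bincount(idx, weights=der, minlength=n).astype(int)
    track.snp["n_anc"] = (np.bincount(idx, minlength=n)
                          - track.snp["n_der"]).astype(int)
    track.snp["p_nea"] = smooth_freq(freqs["nea"], freq_n)
    track.snp["p_afr"] = smooth_freq(freqs["afr"], freq_n)
    track.snp["p_cont"] = smooth_freq(freqs.get("contaminant", freqs["afr"]),
                                      freq_n)
    return track


def site_emission_loglik(n_der, n_anc, p_nea, p_afr, p_cont,
                         c: float, e: float) -> np.ndarray:
    """Per-site log-likelihood for each copy-number state, shape (n, 3).

    P(derived read | k) = c p_cont + (1-c)[(1-e) q_k + e (1-q_k)] with
    q_k = (k/2) p_nea + (1-k/2) p_afr.
    """
    out = np.empty((len(np.atleast_1d(n_der)), 3))
    n_der = np.asarray(n_der, float)
    n_anc = np.asarray(n_anc, float)
    for k in range(3):
        q = (k / 2.0) * p_nea + (1 - k / 2.0) * p_afr
        p = c * p_cont + (1 - c) * ((1 - e) * q + e * (1 - q))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        out[:, k] = n_der * np.log(p) + n_anc * np.log1p(-p)
    return out


def compute_emissions(track: BinTrack, c: float = 0.0,
                      e: float = 0.001) -> BinTrack:
    """Aggregate per-site log-likelihoods into per-bin emission terms."""
    s = track.snp
    site = site_emission_loglik(s["n_der"].to_numpy(), s["n_anc"].to_numpy(),
                                s["p_nea"].to_numpy(), s["p_afr"].to_numpy(),
                                s["p_cont"].to_numpy(), c, e)
    emissions = {}
    for chrom, nb in track.n_bins.items():
        m = (s["chrom"] == chrom).to_numpy()
        E = np.zeros((nb, 3))
        for k in range(3):
            E[:, k] = np.bincount(s["bin"].to_numpy()[m], weights=site[m, k],
                                  minlength=nb)
        emissions[chrom] = E
    track.emissions = emissions
    return track


# ---------------------------------------------------------------------------
# transitions and decoding
# ---------------------------------------------------------------------------

def _transition_matrix(F: float, tau: float, d_cm: float) -> np.ndarray:
    """3-state copy-number transition over distance d, haplotype-factorised."""
    a = np.exp(-tau * d_cm)
    tmm = a + (1 - a) * (1 - F)
    tmn = (1 - a) * F
    tnm = (1 - a) * (1 - F)
    tnn = a + (1 - a) * F
    return np.array([
        [tmm * tmm, 2 * tmm * tmn, tmn * tmn],
        [tnm * tmm, tnn * tmm + tnm * tmn, tnn * tmn],
        [tnm * tnm, 2 * tnn * tnm, tnn * tnn],
    ])


def _logsumexp(a, axis=None):
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))).squeeze(axis)


def decode(track: BinTrack, F: float = 0.03, tau: float = 0.2,
           c: float = 0.0, e: float = 0.001,
           recompute_emissions: bool = True) -> DecodedTrack:
    """Posterior copy-number probabilities by log-space forward-backward.

    ``F`` is the stationary Neanderthal fraction per haplotype and ``tau``
    the switch intensity per cM.  With no reads anywhere the posteriors
    equal the stationary distribution.
    """
    if not (0 < F < 1) or tau <= 0:
        raise ValueError("need 0 < F < 1 and tau > 0")
    if recompute_emissions or track.emissions is None:
        compute_emissions(track, c=c, e=e)
    log_pi = np.log(np.array([(1 - F) ** 2, 2 * F * (1 - F), F ** 2]))
    posteriors, ll_total = {}, 0.0
    for chrom, nb in track.n_bins.items():
        E = track.emissions[chrom]
        if not np.isfinite(E).all():
            bad = int(np.argwhere(~np.isfinite(E))[0][0])
            raise FloatingPointError(
                f"non-finite emission log-likelihood at {chrom} bin {bad}")
        widths = np.diff(track.edges_cm[chrom])
        logT = [np.log(_transition_matrix(F, tau, d)) for d in widths[1:]] if nb > 1 else []
        if nb > 1 and np.allclose(widths[1:], widths[1]):
            logT = [np.log(_transition_matrix(F, tau, widths[1]))] * (nb - 1)
        alpha = np.empty((nb, 3))
        alpha[0] = log_pi + E[0]
        for t in range(1, nb):
            alpha[t] = _logsumexp(alpha[t - 1][:, None] + logT[t - 1], axis=0) + E[t]
        beta = np.zeros((nb, 3))
        for t in range(nb - 2, -1, -1):
            beta[t] = _logsumexp(logT[t] + (E[t + 1] + beta[t + 1])[None, :], axis=1)
        ll_f = float(_logsumexp(alpha[-1], axis=0))
        post = np.exp(alpha + beta - ll_f)
        post /= post.sum(axis=1, keepdims=True)
        posteriors[chrom] = post
        ll_total += ll_f
    return DecodedTrack(track=track, posteriors=posteriors, loglik=ll_total,
                        params={"F": F, "tau": tau, "c": c, "e": e})


def backward_loglik(track: BinTrack, F: float, tau: float) -> float:
    """Total log-likelihood recomputed from the backward recursion only."""
    log_pi = np.log(np.array([(1 - F) ** 2, 2 * F * (1 - F), F ** 2]))
    ll = 0.0
    for chrom, nb in track.n_bins.items():
        E = track.emissions[chrom]
        widths = np.diff(track.edges_cm[chrom])
        beta = np.zeros(3)
        for t in range(nb - 2, -1, -1):
            logT = np.log(_transition_matrix(F, tau, widths[t + 1]))
            beta = _logsumexp(logT + (E[t + 1] + beta)[None, :], axis=1)
        ll += float(_logsumexp(log_pi + E[0] + beta, axis=0))
    return ll


def fit_params(track: BinTrack, F0: float = 0.03, tau0: float = 0.2,
               c0: float = 0.0, e0: float = 0.001, fit_c: bool = False,
               tol: float = 1e-4, max_iter: int = 100) -> DecodedTrack:
    """Re-estimate (F, tau[, c]) by bounded likelihood maximisation."""
    from scipy import optimize

    def unpack(x):
        F = 1 / (1 + np.exp(-x[0]))
        tau = np.exp(x[1])
        c = 1 / (1 + np.exp(-x[2])) if fit_c else c0
        return F, tau, c

    def nll(x):
        F, tau, c = unpack(x)
        compute_emissions(track, c=c, e=e0)
        d = decode(track, F, tau, c=c, e=e0, recompute_emissions=False)
        return -d.loglik

    x0 = [np.log(F0 / (1 - F0)), np.log(tau0)]
    if fit_c:
        x0.append(np.log(max(c0, 1e-3) / (1 - max(c0, 1e-3))))
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": tol, "fatol": tol,
                                     "maxiter": max_iter})
    F, tau, c = unpack(res.x)
    compute_emissions(track, c=c, e=e0)
    return decode(track, F, tau, c=c, e=e0, recompute_emissions=False)


# ---------------------------------------------------------------------------
# segment calling
# ---------------------------------------------------------------------------

def call_segments(decoded: DecodedTrack, threshold: float = 0.9,
                  min_cm: float = 0.2, merge_gap_bins: int = 1
                  ) -> tuple[list[AncestrySegment], SegmentSummary]:
    """Maximal runs of bins with P(copies >= 1) >= threshold.

    Runs separated by fewer than ``merge_gap_bins`` sub-threshold bins are
    merged; segments shorter than ``min_cm`` are dropped.
    """
    track = decoded.track
    segments: list[AncestrySegment] = []
    for chrom, post in decoded.posteriors.items():
        p_any = post[:, 1] + post[:, 2]
        above = p_any >= threshold
        edges = track.edges_cm[chrom]
        runs = _runs(above, max_gap=merge_gap_bins - 1)
        for s, e in runs:
            start_cm, end_cm = float(edges[s]), float(edges[e])
            if end_cm - start_cm < min_cm:
                continue
            seg_post = p_any[s:e]
            copies = 2 if post[s:e, 2].sum() > post[s:e, 1].sum() else 1
            segments.append(AncestrySegment(
                chrom=chrom,
                start_bp=int(track.gmap.interpolate_bp(chrom, start_cm)),
                end_bp=int(np.ceil(track.gmap.interpolate_bp(chrom, end_cm))),
                start_cm=start_cm, end_cm=end_cm,
                mean_posterior=float(seg_post.mean()), copies=copies))
    return segments, summarize_segments(segments)


def _runs(mask: np.ndarray, max_gap: int = 0) -> list[tuple[int, int]]:
    """[start, end) index runs of True, bridging gaps of <= max_gap."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    runs = []
    s = p = idx[0]
    for i in idx[1:]:
        if i - p - 1 <= max_gap:
            p = i
        else:
            runs.append((s, p + 1))
            s = p = i
    runs.append((s, p + 1))
    return runs


def summarize_segments(segments: list[AncestrySegment]) -> SegmentSummary:
    lengths = np.array([s.length_cm for s in segments]) if segments else np.array([])
    per = pd.DataFrame([
        {"chrom": s.chrom, "start_bp": s.start_bp, "end_bp": s.end_bp,
         "start_cm": s.start_cm, "end_cm": s.end_cm,
         "length_cm": s.length_cm, "mean_posterior": s.mean_posterior,
         "copies": s.copies}
        for s in segments
    ], columns=["chrom", "start_bp", "end_bp", "start_cm", "end_cm",
                "length_cm", "mean_posterior", "copies"])
    return SegmentSummary(
        total_cm=float(lengths.sum()),
        longest_cm=float(lengths.max()) if len(lengths) else 0.0,
        n_segments_gt5cm=int((lengths > 5.0).sum()),
        per_chrom=per,
    )


def segments_to_regions(segments: list[AncestrySegment]) -> RegionSet:
    return RegionSet([(s.chrom, s.start_bp, s.end_bp) for s in segments])


def write_segments_bed(segments: list[AncestrySegment], path) -> None:
    """BED6+ with cM start/end, length and posterior columns."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start_bp}\t{s.end_bp}\tnea_{s.copies}x\t"
                f"{s.mean_posterior:.4f}\t+\t{s.start_cm:.6f}\t{s.end_cm:.6f}\t"
                f"{s.length_cm:.6f}\n")
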