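"""Ancient-DNA authentication, pseudo-haploid calling and specimen QC.

Fragments are authenticated by terminal C-to-T deamination (present in
endogenous ancient molecules, absent from present-day contaminants).
Pseudo-haploid genotypes are called by sampling one read per site with
damage masking.  Contamination is estimated two ways — a conditional
deamination estimator and a likelihood estimator on X-chromosome
polymorphisms in males — alongside genetic-sex determination from the
X/autosome fragment ratio and pairwise-mismatch identity checks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .formats_io import MISSING


@dataclasses.dataclass
class ContaminationEstimate:
    c_hat: float
    se: float
    method: str  # 'conditional_deamination' or 'x_polymorphism'
    n_informative: int
    flagged: bool = False
    note: str = ""


@dataclasses.dataclass
class SexCall:
    x_auto_ratio: float
    ci_low: float
    ci_high: float
    call: str  # 'male' / 'female' / 'unresolved'


@dataclasses.dataclass
class PmrResult:
    pmr: float
    n_overlapping_sites: int
    verdict: str  # 'same_individual' / 'different_individuals' / 'inconclusive'


def filter_deaminated(frags: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Retain fragments with C-to-T in the first and/or last ``k`` positions.

    ``k`` must equal the window the flags were computed with (default 3);
    the 'and/or' is an inclusive OR of the two ends.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    keep = frags["ct_5p"] | frags["ct_3p"]
    return frags[keep].reset_index(drop=True)


def pseudohaploid_call(frags: pd.DataFrame, panel: pd.DataFrame,
                       min_bq: int = 30, mask_k: int = 5,
                       seed: int = 0) -> np.ndarray:
    """One randomly sampled allele per covered SNP, with damage masking.

    A read is ineligible at a SNP if its base quality is below ``min_bq``
    or if its allele is damage-consistent — a T on the + strand or an A
    on the - strand — within ``mask_k`` positions of either fragment end.
    Returns an int array over the panel: 0/1 calls, MISSING elsewhere.
    Deterministic given ``seed``.
    """
    n_snps = len(panel)
    calls = np.full(n_snps, MISSING, dtype=np.int64)
    f = frags[frags["snp_index"] >= 0]
    if len(f) == 0:
        return calls
    snp_idx = f["snp_index"].to_numpy()
    allele = f["allele"].to_numpy()
    base = np.where(allele == 1,
                    panel["alt_allele"].to_numpy(str)[snp_idx],
                    panel["ref_allele"].to_numpy(str)[snp_idx])
    near_end = (np.minimum(f["pos_5p"].to_numpy(), f["pos_3p"].to_numpy())
                <= mask_k)
    damage_like = ((base == "T") & (f["strand"].to_numpy() == "+")) | \
                  ((base == "A") & (f["strand"].to_numpy() == "-"))
    eligible = (f["base_quality"].to_numpy() >= min_bq) & \
               ~(near_end & damage_like)
    snp_idx, allele = snp_idx[eligible], allele[eligible]
    if len(snp_idx) == 0:
        return calls
    rng = np.random.default_rng(seed)
    # uniform choice among eligible reads per SNP: random keys, take argmin
    keys = rng.random(len(snp_idx))
    order = np.lexsort((keys, snp_idx))
    first = np.ones(len(order), dtype=bool)
    first[1:] = snp_idx[order][1:] != snp_idx[order][:-1]
    pick = order[first]
    calls[snp_idx[pick]] = allele[pick]
    return calls


# ---------------------------------------------------------------------------
# contamination
# ---------------------------------------------------------------------------

def estimate_contamination_deam(frags: pd.DataFrame) -> ContaminationEstimate:
    """Conditional-deamination contamination estimate.

    For each terminal position k (1..3 from either end), C-to-T rates at
    reference-C positions are observed in two strata: over *all*
    fragments, where the rate is (1-c) delta_k (contaminants carry no
    deamination), and over fragments already deaminated at the
    *opposite* end — an endogenous-only subset, assuming the two ends
    deaminate independently — where the rate is delta_k itself.  The
    contamination fraction c and the nuisance rates delta_k are
    estimated by joint binomial maximum likelihood over the six (end,
    position) count pairs; the SE comes from the profile curvature.

    The simple one-position form of this estimator is c = 1 - r_u/r_c
    with r_u, r_c the unconditional and conditional terminal rates.
    """
    from scipy import optimize

    frags = frags.drop_duplicates("fragment_id")
    N = len(frags)
    if N == 0:
        return ContaminationEstimate(np.nan, np.nan, "conditional_deamination",
                                     0, flagged=True, note="no fragments")
    flag_counts = [int(frags["ct_5p"].sum()), int(frags["ct_3p"].sum())]
    strata = []  # (end_idx_of_condition, v, n_v, w, n_w) per (end, position)
    n_inf = 0
    for cond_idx, (cond_end, obs_ref, obs_ct) in enumerate(
            (("ct_3p", "ref_c_5p_mask", "ct_5p_mask"),
             ("ct_5p", "ref_c_3p_mask", "ct_3p_mask"))):
        cond_flag = frags[cond_end].to_numpy()
        ref_mask = frags[obs_ref].to_numpy()
        ct_mask = frags[obs_ct].to_numpy()
        for k in range(3):
            bit = 1 << k
            has_ref = (ref_mask & bit) > 0
            has_ct = ((ct_mask & bit) > 0) & has_ref
            in_v = has_ref & cond_flag
            in_w = has_ref & ~cond_flag
            n_v, n_w = int(in_v.sum()), int(in_w.sum())
            if n_v == 0:
                continue
            strata.append((1 - cond_idx, k, int(has_ct[in_v].sum()), n_v,
                           int(has_ct[in_w].sum()), n_w))
            n_inf += n_v
    if not strata or not any(s[2] for s in strata):
        return ContaminationEstimate(np.nan, np.nan, "conditional_deamination",
                                     n_inf, flagged=True,
                                     note="no informative deaminated fragments")
    cond_of, pos_of, v, n_v, w, n_w = (np.array(x) for x in zip(*strata))
    # cond_of holds the *conditioning* end index (0 = 5', 1 = 3') per stratum

    def nll(theta):
        # theta = (c, beta_5p, beta_3p, delta_1..delta_3)
        c, beta, delta = theta[0], theta[1:3], theta[3:]
        q = np.clip((1 - c) * beta, 1e-12, 1 - 1e-12)
        ll = (flag_counts[0] * np.log(q[0]) + (N - flag_counts[0]) * np.log1p(-q[0])
              + flag_counts[1] * np.log(q[1]) + (N - flag_counts[1]) * np.log1p(-q[1]))
        d = np.clip(delta[pos_of], 1e-12, 1 - 1e-12)
        # endogenous share among fragments NOT deaminated at the conditioning end
        a = ((1 - c) * (1 - beta[cond_of])) / np.clip(1 - q[cond_of], 1e-12, None)
        rw = np.clip(a * d, 1e-12, 1 - 1e-12)
        ll += (v * np.log(d) + (n_v - v) * np.log1p(-d)).sum()
        ll += (w * np.log(rw) + (n_w - w) * np.log1p(-rw)).sum()
        return -ll

    beta0 = np.clip(np.array(flag_counts, float) / N, 1e-4, 0.999)
    delta0 = np.clip(np.bincount(pos_of, weights=v, minlength=3)
                     / np.maximum(np.bincount(pos_of, weights=n_v, minlength=3), 1),
                     1e-4, 0.999)
    x0 = np.concatenate([[0.1], beta0, delta0])
    bounds = [(0.0, 0.999)] + [(1e-6, 0.999)] * 5
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    c_hat = float(res.x[0])
    h = 1e-4
    c0 = float(np.clip(c_hat, h, 0.999 - h))

    def pnll(c):  # profile over the nuisance rates at fixed c
        r = optimize.minimize(lambda d: nll(np.concatenate([[c], d])),
                              res.x[1:], method="L-BFGS-B", bounds=bounds[1:])
        return r.fun

    d2 = (pnll(c0 + h) - 2 * pnll(c0) + pnll(c0 - h)) / h ** 2
    se = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan
    return ContaminationEstimate(c_hat, se, "conditional_deamination", n_inf,
                                 flagged=not np.isfinite(se),
                                 note="" if np.isfinite(se) else
                                 "curvature SE undefined (boundary estimate)")


def estimate_contamination_x(frags: pd.DataFrame, panel: pd.DataFrame,
                             x_freqs: np.ndarray, sex: str = "male",
                             max_error: float = 0.1) -> ContaminationEstimate:
    """Maximum-likelihood contamination from X polymorphisms in a male.

    A male has a single X, so every endogenous read should match the
    consensus allele up to sequencing error; mismatches tracking the
    contaminant-population frequencies indicate contamination.  The
    likelihood P(read) = c q_read + (1-c)[(1-e) if match else e] is
    maximised over (c, e); the SE comes from the profile curvature in c.
    """
    if sex != "male":
        raise ValueError("X-polymorphism estimator requires a male (single X)")
    f = frags[(frags["chrom"] == "X") & (frags["snp_index"] >= 0)]
    snp_idx = f["snp_index"].to_numpy()
    allele = f["allele"].to_numpy()
    # leave-one-out majority consensus: a read never votes for itself,
    # so depth-1 sites (trivially self-matching) drop out
    der = np.bincount(snp_idx, weights=allele, minlength=len(panel))
    tot = np.bincount(snp_idx, minlength=len(panel))
    der_loo = der[snp_idx] - allele
    tot_loo = tot[snp_idx] - 1
    # require a clear majority (margin >= 2) among the other reads so a
    # single contaminant read cannot flip the consensus
    ok = np.abs(der_loo * 2 - tot_loo) >= 2
    snp_idx, allele = snp_idx[ok], allele[ok]
    match = allele == (der_loo[ok] * 2 > tot_loo[ok]).astype(int)
    q_read = np.where(allele == 1, x_freqs[snp_idx], 1 - x_freqs[snp_idx])
    q_read = np.clip(q_read, 1e-6, 1 - 1e-6)
    n_sites = int((tot > 0).sum())
    flagged = n_sites < 50

    def nll(theta):
        c, e = theta
        p = c * q_read + (1 - c) * np.where(match, 1 - e, e)
        return -np.log(np.clip(p, 1e-300, None)).sum()

    res = optimize.minimize(nll, x0=[0.05, 0.005], method="L-BFGS-B",
                            bounds=[(0.0, 0.999), (1e-6, max_error)])
    c_hat, e_hat = res.x
    # curvature-based SE on c at the joint optimum
    h = 1e-4
    c0 = float(np.clip(c_hat, h, 0.999 - h))
    d2 = (nll([c0 + h, e_hat]) - 2 * nll([c0, e_hat]) + nll([c0 - h, e_hat])) / h ** 2
    se = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan
    return ContaminationEstimate(float(c_hat), se, "x_polymorphism",
                                 n_sites, flagged=flagged)


# ---------------------------------------------------------------------------
# sex and identity
# ---------------------------------------------------------------------------

def determine_sex(frags: pd.DataFrame, n_x_sites: int, n_auto_sites: int,
                  deaminated_only: bool = True,
                  male_below: float = 0.6, female_above: float = 0.8) -> SexCall:
    """Genetic sex from the X/autosome ratio of (deaminated) fragment rates.

    rho = (X fragments / X target sites) / (autosomal fragments /
    autosomal sites); ~0.5 for males, ~1 for females.  The CI comes from
    the exact binomial (Clopper-Pearson) interval on the X share of
    fragments; the call requires the whole CI on one side.
    """
    f = filter_deaminated(frags) if deaminated_only else frags
    f = f.drop_duplicates("fragment_id")
    x = int((f["chrom"] == "X").sum())
    a = int((f["chrom"] != "X").sum())
    if a == 0:
        raise ValueError("no autosomal fragments")
    rho = (x / n_x_sites) / (a / n_auto_sites)
    n = x + a
    lo_p = stats.beta.ppf(0.025, x, n - x + 1) if x > 0 else 0.0
    hi_p = stats.beta.ppf(0.975, x + 1, n - x) if x < n else 1.0
    to_rho = lambda p: (p / max(1 - p, 1e-12)) * (n_auto_sites / n_x_sites)
    ci_low, ci_high = to_rho(lo_p), to_rho(hi_p)
    if ci_high < male_below:
        call = "male"
    elif ci_low > female_above:
        call = "female"
    else:
        call = "unresolved"
    return SexCall(float(rho), float(ci_low), float(ci_high), call)


def pairwise_mismatch_rate(calls_a: np.ndarray, calls_b: np.ndarray,
                           threshold: float = 0.18,
                           min_sites: int = 500) -> PmrResult:
    """Mismatch rate between two pseudo-haploid call sets on one panel.

    Same-individual pairs show a markedly lower rate than unrelated pairs
    (roughly half, since two samplings of one diploid agree at
    heterozygous sites half the time while unrelated genomes differ
    independently); ``threshold`` is the decision midpoint.
    """
    calls_a = np.asarray(calls_a)
    calls_b = np.asarray(calls_b)
    if calls_a.shape != calls_b.shape:
        raise ValueError("call sets must be on the same panel")
    both = (calls_a != MISSING) & (calls_b != MISSING)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no overlapping called sites")
    pmr = float((calls_a[both] != calls_b[both]).mean())
    if n < min_sites:
        verdict = "inconclusive"
    elif pmr < threshold:
        verdict = "same_individual"
    else:
        verdict = "different_individuals"
    return PmrResult(pmr, n, verdict)
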