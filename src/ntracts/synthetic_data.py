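"""Synthetic inputs with the statistical structure the analyses assume.

Three generators:

* graph-drifted population allele frequencies (Balding–Nichols drift along
  each edge of an admixture graph, so realised f2 between parent and child
  matches the edge length in expectation);
* pedigree recombination of a recent Neanderthal ancestor ``g``
  generations back (Haldane model: crossovers a Poisson process at 1 per
  100 cM, no interference) on top of an old, ~2,000-generation
  introgression background (stationary two-state Markov process along the
  map);
* ancient-DNA read sampling: Poisson coverage over a SNP panel,
  present-day contamination at rate ``c`` (contaminant reads carry no
  deamination), sequencing error ``e``, and terminal C-to-T deamination
  with probability ``delta * rho**(k-1)`` at distance ``k`` from each end.

Everything is reproducible bit-exact given (spec, seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .formats_io import (FRAGMENT_COLUMNS, GeneticMap, RegionSet,
                         make_genotype_data, _typed_fragments)
from .graph_fit import Admixture, AdmixtureGraph, DriftEdge

#: human-autosome-like relative genetic lengths (22 chromosomes)
_CHR_CM = np.array([284, 269, 223, 214, 204, 192, 187, 168, 166, 181, 158,
                    174, 126, 119, 141, 134, 128, 117, 107, 108, 62, 74],
                   dtype=float)

#: probability that a terminal position carries a reference C
REF_C_PROB = 0.25


def default_genome_map(total_cm: float = 3500.0, n_chrom: int = 22,
                       bp_per_cm: float = 1_000_000.0) -> GeneticMap:
    """A 22-autosome map with human-like relative lengths and uniform rate."""
    lens = _CHR_CM[:n_chrom] * (total_cm / _CHR_CM[:n_chrom].sum())
    anchors = {
        str(i + 1): (np.array([0.0, lens[i] * bp_per_cm]),
                     np.array([0.0, lens[i]]))
        for i in range(n_chrom)
    }
    return GeneticMap(anchors)


# ---------------------------------------------------------------------------
# graph-drifted allele frequencies
# ---------------------------------------------------------------------------

def simulate_graph_frequencies(graph: AdmixtureGraph, n_snps: int, seed: int,
                               root_low: float = 0.05,
                               root_high: float = 0.95) -> dict[str, np.ndarray]:
    """Allele frequencies for every node of ``graph`` at ``n_snps`` SNPs.

    Root frequencies are Uniform(root_low, root_high).  A drift edge of
    length ``f`` (f2 units of squared frequency difference) applies
    Balding–Nichols sampling — Beta with mean ``p`` and variance
    ``F p (1-p)``, with the inbreeding-style parameter ``F`` scaled by
    the parent's mean heterozygosity so that the realised parent-child f2
    equals ``f`` in expectation — hence f2 is additive along drift paths.
    Admixture nodes mix parental frequencies linearly.
    """
    rng = np.random.default_rng(seed)
    freqs: dict[str, np.ndarray] = {}
    drift_parent = {e.child: (e.parent, e.length) for e in graph.drift_edges}
    for node in reversed(graph._order):  # parents before children
        if node == graph.root:
            freqs[node] = rng.uniform(root_low, root_high, n_snps)
        elif node in graph.admixtures:
            a = graph.admixtures[node]
            if a.alpha is None:
                raise ValueError(f"admixture proportion unset for {node}")
            freqs[node] = a.alpha * freqs[a.parent1] + (1 - a.alpha) * freqs[a.parent2]
        else:
            parent, f = drift_parent[node]
            if f is None:
                raise ValueError(f"drift length unset on edge {node}<-{parent}")
            p = freqs[parent]
            if f == 0:
                freqs[node] = p.copy()
            else:
                het = float(np.mean(p * (1 - p)))
                F = f / het
                if F >= 1:
                    raise ValueError(
                        f"drift length {f} too large on edge {node}<-{parent} "
                        f"(implied Balding-Nichols F = {F:.3f} >= 1)")
                k = (1.0 - F) / F
                child = rng.beta(np.maximum(p * k, 1e-9),
                                 np.maximum((1 - p) * k, 1e-9))
                freqs[node] = np.clip(child, 1e-9, 1 - 1e-9)
    return freqs


# ---------------------------------------------------------------------------
# pedigree tracts
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PedigreeSimSpec:
    g: int                     # generations to the Neanderthal ancestor
    map: GeneticMap
    alpha_bg: float = 0.02     # stationary background Neanderthal fraction
    t_bg: float = 2000.0       # background admixture age (generations)
    seed: int = 0

    def __post_init__(self):
        if self.g < 1:
            raise ValueError("g must be >= 1")
        if not (0 <= self.alpha_bg < 1):
            raise ValueError("alpha_bg must be in [0, 1)")


@dataclasses.dataclass
class TruthSet:
    """Per-haplotype Neanderthal-ancestry intervals in cM, plus parameters.

    ``hap_intervals[h][chrom]`` is a list of (start_cm, end_cm, label)
    with label in {"recent", "background"}; haplotype 0 is the carrier of
    the recent-ancestor tracts.
    """

    map: GeneticMap
    hap_intervals: list[dict[str, list[tuple[float, float, str]]]]
    params: dict

    def recent_lengths_cm(self) -> np.ndarray:
        out = [e - s
               for chrom_ivs in self.hap_intervals[0].values()
               for s, e, lab in chrom_ivs if lab == "recent"]
        return np.array(out, dtype=float)

    def ancestry_at(self, chrom: str, cm_pos: np.ndarray, hap: int) -> np.ndarray:
        """Boolean Neanderthal-ancestry indicator at genetic positions."""
        ivs = self.hap_intervals[hap].get(chrom, [])
        out = np.zeros(len(cm_pos), dtype=bool)
        for s, e, _ in ivs:
            out |= (cm_pos >= s) & (cm_pos < e)
        return out

    def regions_bp(self, hap: int, label: str | None = None,
                   min_cm: float = 0.0) -> RegionSet:
        recs = []
        for chrom, ivs in self.hap_intervals[hap].items():
            for s, e, lab in ivs:
                if label is not None and lab != label:
                    continue
                if e - s < min_cm:
                    continue
                recs.append((chrom, int(self.map.interpolate_bp(chrom, s)),
                             int(np.ceil(self.map.interpolate_bp(chrom, e)))))
        return RegionSet(recs)

    def recent_fraction(self) -> float:
        """Fraction of the carrier haplotype covered by recent tracts."""
        tot = self.map.total_cm()
        return float(self.recent_lengths_cm().sum() / tot) if tot > 0 else 0.0


def _intersect_float(a: list[tuple[float, float]],
                     b: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _meiosis(ivs, length_cm, rng) -> list[tuple[float, float]]:
    """One gamete: keep the parts of ``ivs`` inherited from the carrier homolog."""
    n_x = rng.poisson(length_cm / 100.0)
    points = np.sort(rng.uniform(0.0, length_cm, n_x))
    edges = np.concatenate([[0.0], points, [length_cm]])
    phase = rng.integers(0, 2)  # which homolog the gamete starts on
    carrier = [(edges[k], edges[k + 1])
               for k in range(len(edges) - 1) if (k + phase) % 2 == 0]
    return _intersect_float(ivs, carrier)


def _background_intervals(length_cm, alpha_bg, t_bg, rng):
    """Stationary two-state Markov tract process on [0, length_cm]."""
    if alpha_bg <= 0:
        return []
    mean_n = 100.0 / t_bg
    mean_m = mean_n * (1 - alpha_bg) / alpha_bg
    out = []
    pos = 0.0
    state = rng.random() < alpha_bg
    while pos < length_cm:
        seg = rng.exponential(mean_n if state else mean_m)
        end = min(pos + seg, length_cm)
        if state and end > pos:
            out.append((pos, end))
        pos = end
        state = not state
    return out


def simulate_pedigree_tracts(spec: PedigreeSimSpec) -> TruthSet:
    """Recent tracts from ``g`` meioses plus old background on both haplotypes.

    The carrier haplotype lineage starts as a fully Neanderthal gamete and
    recombines against fully modern homologs in each of ``g`` successive
    meioses, so recent-tract lengths are ~Exp(g/100 per cM) away from
    chromosome ends and the expected carrier-haplotype Neanderthal
    fraction is 2^-g.
    """
    if not spec.map.chromosomes:
        raise ValueError("empty genetic map")
    rng = np.random.default_rng(spec.seed)
    haps: list[dict] = [{}, {}]
    for chrom in spec.map.chromosomes:
        lo, hi = spec.map.span_cm(chrom)
        L = hi - lo
        ivs = [(0.0, L)]
        for _ in range(spec.g):
            ivs = _meiosis(ivs, L, rng)
        recent = [(lo + s, lo + e, "recent") for s, e in ivs]
        haps[0][chrom] = recent
        haps[1][chrom] = []
        for h in (0, 1):
            bg = _background_intervals(L, spec.alpha_bg, spec.t_bg, rng)
            haps[h][chrom] = sorted(
                haps[h][chrom] + [(lo + s, lo + e, "background") for s, e in bg]
            )
    params = {"g": spec.g, "alpha_bg": spec.alpha_bg, "t_bg": spec.t_bg,
              "seed": spec.seed}
    return TruthSet(map=spec.map, hap_intervals=haps, params=params)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReadSimSpec:
    coverage: float = 2.0        # mean depth per SNP (Poisson)
    contamination: float = 0.0   # present-day contaminant read fraction
    error: float = 0.001         # per-base sequencing error
    deamination: float = 0.3     # 5'/3' terminal C-to-T probability (delta)
    deamination_decay: float = 0.5  # geometric decay rho per position
    mean_length: float = 50.0    # mean fragment length (min 35)
    mapq: int = 37
    base_quality: int = 40
    sex: str = "female"          # 'male' halves X depth, single X haplotype
    seed: int = 0

    def __post_init__(self):
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        for name in ("contamination", "error", "deamination", "deamination_decay"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")


def descend_tracts(truth: TruthSet, extra_g: int, seed: int) -> TruthSet:
    """A descendant's carrier haplotype: ``extra_g`` further meioses.

    Both descendants of one admixed ancestor share tract positions, which
    is what segment-overlap correlations measure.
    """
    rng = np.random.default_rng(seed)
    haps = [{}, {}]
    for chrom in truth.map.chromosomes:
        lo, hi = truth.map.span_cm(chrom)
        L = hi - lo
        ivs = [(s - lo, e - lo) for s, e, _ in truth.hap_intervals[0].get(chrom, [])]
        for _ in range(extra_g):
            ivs = _meiosis(ivs, L, rng)
        haps[0][chrom] = [(lo + s, lo + e, "recent") for s, e in ivs]
        haps[1][chrom] = []
    params = dict(truth.params)
    params["g"] = params.get("g", 0) + extra_g
    return TruthSet(map=truth.map, hap_intervals=haps, params=params)


def simulate_reads(truth: TruthSet, panel: pd.DataFrame,
                   freqs: dict[str, np.ndarray], spec: ReadSimSpec,
                   specimen_id: str = "sim",
                   hap_alleles: np.ndarray | None = None):
    """Fragment table over ``panel`` SNPs plus the true haplotype alleles.

    ``freqs`` holds per-SNP derived-allele frequencies for populations
    ``nea`` (Neanderthal source), ``modern`` (endogenous non-archaic) and
    ``contaminant``.  Each endogenous read copies the allele of a
    uniformly chosen haplotype, whose allele was drawn once from the
    frequency of its true ancestry source; contaminant reads draw from
    the contaminant population and never carry deamination.

    Returns ``(fragments, hap_alleles)`` where ``hap_alleles`` has shape
    (2, n_snps) with -1 on the absent X haplotype of a male.
    """
    rng = np.random.default_rng(spec.seed)
    n_snps = len(panel)
    clip = lambda p: np.clip(np.asarray(p, float), 0.001, 0.999)
    p_nea, p_mod, p_cont = (clip(freqs[k]) for k in ("nea", "modern", "contaminant"))
    chroms = panel["chrom"].to_numpy(str)
    cm = panel["cm"].to_numpy(float)
    pos_bp = panel["pos_bp"].to_numpy(np.int64)
    is_x = chroms == "X"
    male = spec.sex == "male"

    # fixed haplotype alleles (optionally supplied, e.g. to resample reads
    # from the same individual)
    if hap_alleles is None:
        hap_alleles = np.full((2, n_snps), -1, dtype=np.int64)
        for h in (0, 1):
            src = np.zeros(n_snps, dtype=bool)
            for chrom in np.unique(chroms):
                m = chroms == chrom
                src[m] = truth.ancestry_at(chrom, cm[m], h) \
                    if chrom in truth.map.anchors else False
            p = np.where(src, p_nea, p_mod)
            hap_alleles[h] = (rng.random(n_snps) < p).astype(np.int64)
        if male:
            hap_alleles[1, is_x] = -1
    else:
        hap_alleles = np.asarray(hap_alleles, dtype=np.int64).copy()

    lam = np.full(n_snps, spec.coverage)
    if male:
        lam[is_x] = spec.coverage / 2.0
    depth = rng.poisson(lam)
    snp_idx = np.repeat(np.arange(n_snps), depth)
    R = len(snp_idx)

    contam = rng.random(R) < spec.contamination
    hap = rng.integers(0, 2, R)
    if male:
        hap[is_x[snp_idx]] = 0
    endo_allele = hap_alleles[hap, snp_idx]
    cont_allele = (rng.random(R) < p_cont[snp_idx]).astype(np.int64)
    allele = np.where(contam, cont_allele, endo_allele)
    flip = rng.random(R) < spec.error
    allele = np.where(flip, 1 - allele, allele)

    length = 35 + rng.geometric(1.0 / max(spec.mean_length - 34.0, 1.0), R) - 1
    left_off = (rng.random(R) * length).astype(np.int64)
    strand_minus = rng.random(R) < 0.5
    pos_5p = np.where(strand_minus, length - left_off, left_off + 1)
    pos_3p = length + 1 - pos_5p
    start_bp = pos_bp[snp_idx] - 1 - left_off

    # terminal deamination, endogenous reads only
    delta, rho = spec.deamination, spec.deamination_decay
    endo = ~contam
    ct5 = np.zeros((3, R), dtype=bool)
    ct3 = np.zeros((3, R), dtype=bool)
    refc5 = rng.random((3, R)) < REF_C_PROB
    refc3 = rng.random((3, R)) < REF_C_PROB
    for k in range(3):
        pk = delta * rho ** k
        ct5[k] = endo & refc5[k] & (rng.random(R) < pk)
        ct3[k] = endo & refc3[k] & (rng.random(R) < pk)
    bits = 1 << np.arange(3)

    def pack(rows):
        return (rows * bits[:, None]).sum(axis=0).astype(np.int64)

    frags = pd.DataFrame({
        "specimen_id": specimen_id,
        "fragment_id": np.arange(R, dtype=np.int64),
        "chrom": chroms[snp_idx],
        "start_bp": start_bp,
        "length_bp": length,
        "strand": np.where(strand_minus, "-", "+"),
        "mapq": spec.mapq,
        "ct_5p": ct5.any(axis=0),
        "ct_3p": ct3.any(axis=0),
        "ref_c_5p_mask": pack(refc5),
        "ct_5p_mask": pack(ct5),
        "ref_c_3p_mask": pack(refc3),
        "ct_3p_mask": pack(ct3),
        "snp_index": snp_idx.astype(np.int64),
        "allele": allele,
        "base_quality": spec.base_quality,
        "pos_5p": pos_5p,
        "pos_3p": pos_3p,
    })
    return _typed_fragments(frags[FRAGMENT_COLUMNS]), hap_alleles


# ---------------------------------------------------------------------------
# null panel (jackknife calibration)
# ---------------------------------------------------------------------------

def simulate_null_panel(n_pops: int, n_snps: int, seed: int,
                        drift: float = 0.02, n_ind: int = 10,
                        span_mb: float = 200.0):
    """Star phylogeny with equal drift: every D statistic has expectation 0."""
    if n_pops < 4:
        raise ValueError("need at least 4 populations for D statistics")
    rng = np.random.default_rng(seed)
    root = rng.uniform(0.05, 0.95, n_snps)
    k = (1.0 - drift) / drift
    pop_names = [f"Pop{i}" for i in range(n_pops)]
    geno_cols, sample_rows = [], []
    for pop in pop_names:
        p = np.clip(rng.beta(root * k, (1 - root) * k), 1e-9, 1 - 1e-9)
        g = rng.binomial(2, p[:, None], size=(n_snps, n_ind)).astype(np.int8)
        geno_cols.append(g)
        sample_rows += [{"sample_id": f"{pop}_i{j}", "population": pop}
                        for j in range(n_ind)]
    geno = np.concatenate(geno_cols, axis=1)
    pos = np.linspace(1, span_mb * 1e6, n_snps).astype(np.int64)
    pos = np.unique(pos)[:n_snps]
    snp = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(len(pos))],
        "chrom": "1",
        "pos_bp": pos,
        "cm": pos / 1e6,
        "ref_allele": "A",
        "alt_allele": "C",
    })
    return make_genotype_data(snp, pd.DataFrame(sample_rows), geno[:len(pos)])


def archaic_panel(gmap: GeneticMap, snps_per_cm: float = 50.0, seed: int = 0,
                  sep: float = 0.85) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """An archaic-informative SNP panel over ``gmap`` with source frequencies.

    Emulates ascertainment of sites where archaic genomes differ from
    Africans: Neanderthal and modern (African) frequencies are pushed
    apart by ``sep`` on average; the contaminant population tracks the
    modern frequencies with mild drift.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in gmap.chromosomes:
        lo, hi = gmap.span_cm(chrom)
        n = int(round((hi - lo) * snps_per_cm))
        cms = np.sort(rng.uniform(lo, hi, n))
        bps = np.asarray(gmap.interpolate_bp(chrom, cms), dtype=np.int64)
        bps, keep = np.unique(bps, return_index=True)
        for c, b in zip(cms[keep], bps):
            rows.append((chrom, int(b), float(c)))
    panel = pd.DataFrame(rows, columns=["chrom", "pos_bp", "cm"])
    panel.insert(0, "snp_id", [f"arch{i}" for i in range(len(panel))])
    panel["ref_allele"] = "A"
    bases = np.array(["C", "G", "T"])
    panel["alt_allele"] = bases[rng.integers(0, 3, len(panel))]
    n = len(panel)
    high = rng.random(n) < 0.5  # which side carries the derived allele
    p_nea = np.where(high, rng.uniform(sep, 0.999, n), rng.uniform(0.001, 1 - sep, n))
    p_mod = 1.0 - p_nea + rng.normal(0, 0.02, n)
    p_mod = np.clip(p_mod, 0.001, 0.999)
    p_cont = np.clip(p_mod + rng.normal(0, 0.02, n), 0.001, 0.999)
    freqs = {"nea": p_nea, "modern": p_mod, "contaminant": p_cont}
    return panel, freqs


# ---------------------------------------------------------------------------
# reference study-condition graphs
# ---------------------------------------------------------------------------

def f4_ratio_demo_graph(alpha: float = 0.03) -> AdmixtureGraph:
    """Archaic-ancestry scenario for f4-ratio recovery experiments.

    Roles: A and B are two archaic genomes (B the closer relative of the
    introgressing lineage NI), O and C two African populations, X a
    modern test population carrying ``alpha`` archaic ancestry.  The
    direct f4 ratio f4(A,O;X,C)/f4(A,O;B,C) then equals ``alpha``.
    """
    edges = [DriftEdge("O", "R", 0.05), DriftEdge("E", "R", 0.02),
             DriftEdge("N", "E", 0.08), DriftEdge("Afr", "E", 0.03),
             DriftEdge("A", "N", 0.03), DriftEdge("NB", "N", 0.02),
             DriftEdge("B", "NB", 0.02), DriftEdge("NI", "NB", 0.01),
             DriftEdge("C", "Afr", 0.01), DriftEdge("C2", "Afr", 0.005),
             DriftEdge("X", "Xm", 0.005)]
    return AdmixtureGraph(edges, [Admixture("Xm", "NI", "C2", alpha)])


def admixture_recovery_graphs(alpha: float = 0.3):
    """(true, free, misspecified) graphs for admixture-fit experiments.

    The admixing sources M1 and M2 each have a sampled reference leaf
    (Q1, Q2), which makes the mixing proportion identifiable from the
    outgroup-f3 basis.  ``free`` is the same topology with all parameters
    free; ``misspecified`` removes the admixture event and hangs X as a
    sister of Q1.
    """
    edges = [DriftEdge("O", "R", 0.05), DriftEdge("I", "R", 0.02),
             DriftEdge("J1", "I", 0.02), DriftEdge("J2", "I", 0.02),
             DriftEdge("P2", "J1", 0.02), DriftEdge("M1", "J1", 0.03),
             DriftEdge("P3", "J2", 0.02), DriftEdge("M2", "J2", 0.03),
             DriftEdge("Q1", "M1", 0.02), DriftEdge("Q2", "M2", 0.02),
             DriftEdge("X", "Xm", 0.01)]
    true = AdmixtureGraph(edges, [Admixture("Xm", "M1", "M2", alpha)])
    free = AdmixtureGraph(
        [DriftEdge(e.child, e.parent, None) for e in edges],
        [Admixture("Xm", "M1", "M2", None)])
    miss_edges = [DriftEdge("O", "R", None), DriftEdge("I", "R", None),
                  DriftEdge("J1", "I", None), DriftEdge("J2", "I", None),
                  DriftEdge("P2", "J1", None), DriftEdge("M1", "J1", None),
                  DriftEdge("P3", "J2", None), DriftEdge("M2", "J2", None),
                  DriftEdge("M1a", "M1", None), DriftEdge("Q1", "M1a", None),
                  DriftEdge("X", "M1a", None), DriftEdge("Q2", "M2", None)]
    miss = AdmixtureGraph(miss_edges, [])
    return true, free, miss
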