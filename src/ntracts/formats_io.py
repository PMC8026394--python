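"""Readers/writers for the external formats and the shared coordinate conventions.

Formats handled here:

* EIGENSTRAT geno/snp/ind triplets (packed-ASCII ``0/1/2/9`` geno dialect).
  The geno value is the *derived* (alt) allele count; ``9`` is missing.
  Our ``.ind`` dialect writes a fourth column carrying the ploidy
  (``diploid`` or ``pseudo_haploid``); plain three-column files read as
  diploid.
* BED3(+) region files, 0-based half-open, normalised (sorted, merged) on
  load.
* Genetic maps as three-column TSV ``chrom, pos_bp, cm`` with one header
  line; interpolation is piecewise linear with constant extrapolation
  beyond the terminal anchors.
* Fragment tables: one TSV row per (fragment, overlapped SNP) pair — the
  per-read evidence unit for all ancient-DNA work.  Fragments overlapping
  no panel SNP carry ``snp_index = -1``.

Conventions: SNP ``pos_bp`` is 1-based (EIGENSTRAT convention); BED and all
internal interval sets are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("ntracts")

MISSING = -1  # in-memory missing code for allele counts

SNP_COLUMNS = ["snp_id", "chrom", "pos_bp", "cm", "ref_allele", "alt_allele"]
SAMPLE_COLUMNS = ["sample_id", "sex", "population", "ploidy"]

#: fragment-table schema; one row per (fragment, SNP) pair
FRAGMENT_COLUMNS = [
    "specimen_id",
    "fragment_id",
    "chrom",
    "start_bp",      # 0-based
    "length_bp",
    "strand",        # '+' or '-'
    "mapq",
    "ct_5p",         # C-to-T within first 3 aligned positions
    "ct_3p",         # C-to-T within last 3 aligned positions
    "ref_c_5p_mask",  # bit k-1 set: reference C at 5' position k (k = 1..3)
    "ct_5p_mask",     # bit k-1 set: C-to-T observed at 5' position k
    "ref_c_3p_mask",
    "ct_3p_mask",
    "snp_index",     # row index into the SNP panel, -1 if none
    "allele",        # 0 ancestral/ref, 1 derived/alt, -1 if no SNP
    "base_quality",
    "pos_5p",        # 1-based distance of the SNP from the 5' end
    "pos_3p",
]

_FRAG_BOOL = ["ct_5p", "ct_3p"]
_FRAG_INT = ["start_bp", "length_bp", "mapq", "ref_c_5p_mask", "ct_5p_mask",
             "ref_c_3p_mask", "ct_3p_mask", "snp_index", "allele",
             "base_quality", "pos_5p", "pos_3p"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenotypeData:
    """SNP panel, sample table and derived-allele count matrix.

    ``geno`` has shape (n_snps, n_samples), values in {0, 1, 2, MISSING}.
    Pseudo-haploid samples are never heterozygous (0/2/missing only).
    """

    snp: pd.DataFrame
    samples: pd.DataFrame
    geno: np.ndarray

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_snps(self) -> int:
        return len(self.snp)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        if self.geno.shape != (len(self.snp), len(self.samples)):
            raise FormatError(
                f"geno shape {self.geno.shape} does not match panel "
                f"({len(self.snp)} SNPs) x samples ({len(self.samples)})"
            )
        bad = ~np.isin(self.geno, [0, 1, 2, MISSING])
        if bad.any():
            raise FormatError("allele counts must be 0/1/2/missing")
        ph = (self.samples["ploidy"] == "pseudo_haploid").to_numpy()
        if ph.any() and (self.geno[:, ph] == 1).any():
            raise FormatError("pseudo-haploid sample contains heterozygous call")


def read_eigenstrat(prefix_or_geno, snp_path=None, ind_path=None) -> GenotypeData:
    """Read an EIGENSTRAT triplet, either by common prefix or explicit paths."""
    if snp_path is None:
        prefix = str(prefix_or_geno)
        geno_path, snp_path, ind_path = (prefix + s for s in (".geno", ".snp", ".ind"))
    else:
        geno_path = prefix_or_geno

    samples = _read_ind(ind_path)
    snp = _read_snp(snp_path)

    rows = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if len(line) != len(samples):
                raise FormatError(
                    f"{geno_path}:{lineno}: line width {len(line)} != "
                    f"{len(samples)} samples"
                )
            rows.append(line)
    if len(rows) != len(snp):
        raise FormatError(
            f"{geno_path}: {len(rows)} geno lines but {len(snp)} snp records"
        )
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(
        len(rows), len(samples)
    ) - ord("0")
    geno = arr.astype(np.int8)
    if not np.isin(geno, [0, 1, 2, 9]).all():
        raise FormatError(f"{geno_path}: geno codes must be 0/1/2/9")
    geno[geno == 9] = MISSING
    return GenotypeData(snp=snp, samples=samples, geno=geno)


def write_eigenstrat(data: GenotypeData, prefix) -> None:
    """Write ``data`` as ``prefix``.geno/.snp/.ind (lossless round trip)."""
    if data.n_samples == 0:
        raise FormatError("cannot write EIGENSTRAT files with no samples")
    prefix = str(prefix)
    geno = data.geno.copy()
    geno[geno == MISSING] = 9
    chars = (geno.astype(np.uint8) + ord("0")).tobytes().decode()
    with open(prefix + ".geno", "w") as fh:
        n = data.n_samples
        for i in range(data.n_snps):
            fh.write(chars[i * n:(i + 1) * n])
            fh.write("\n")
    with open(prefix + ".snp", "w") as fh:
        for rec in data.snp.itertuples(index=False):
            # EIGENSTRAT .snp stores the genetic position in Morgans
            fh.write(
                f"{rec.snp_id}\t{rec.chrom}\t{rec.cm / 100.0:.8f}\t"
                f"{rec.pos_bp}\t{rec.ref_allele}\t{rec.alt_allele}\n"
            )
    with open(prefix + ".ind", "w") as fh:
        for rec in data.samples.itertuples(index=False):
            fh.write(f"{rec.sample_id}\t{rec.sex}\t{rec.population}\t{rec.ploidy}\n")


def _read_snp(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            rows.append(
                (parts[0], parts[1], float(parts[2]) * 100.0, int(parts[3]),
                 parts[4], parts[5])
            )
    snp = pd.DataFrame(rows, columns=["snp_id", "chrom", "cm", "pos_bp",
                                      "ref_allele", "alt_allele"])
    snp = snp[SNP_COLUMNS]
    _validate_snp(snp, path)
    return snp.reset_index(drop=True)


def _validate_snp(snp: pd.DataFrame, origin="panel") -> None:
    if not snp["ref_allele"].isin(list("ACGT")).all() or \
            not snp["alt_allele"].isin(list("ACGT")).all():
        raise FormatError(f"{origin}: alleles must be A/C/G/T")
    for chrom, grp in snp.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy()
        cm = grp["cm"].to_numpy()
        if (np.diff(pos) <= 0).any():
            raise FormatError(f"{origin}: pos_bp not strictly increasing on {chrom}")
        if (np.diff(cm) < 0).any() or (cm < 0).any():
            raise FormatError(f"{origin}: cm must be non-negative, non-decreasing on {chrom}")


def _read_ind(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 3:
                parts = parts + ["diploid"]
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 3 or 4 columns")
            if parts[3] not in ("diploid", "pseudo_haploid"):
                raise FormatError(f"{path}:{lineno}: bad ploidy {parts[3]!r}")
            rows.append(tuple(parts))
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def make_genotype_data(snp, samples, geno) -> GenotypeData:
    """Build a validated GenotypeData, filling sample-table defaults."""
    samples = samples.copy()
    if "sex" not in samples:
        samples["sex"] = "U"
    if "ploidy" not in samples:
        samples["ploidy"] = "diploid"
    snp = snp[SNP_COLUMNS].reset_index(drop=True)
    _validate_snp(snp)
    return GenotypeData(snp=snp, samples=samples[SAMPLE_COLUMNS].reset_index(drop=True),
                        geno=np.asarray(geno, dtype=np.int8))


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

class GeneticMap:
    """Per-chromosome (pos_bp, cm) anchors with linear interpolation.

    Both coordinates must be strictly increasing within a chromosome;
    queries beyond the terminal anchors return the terminal cM value
    (constant extrapolation), so interpolation is monotone non-decreasing.
    """

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.anchors = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size == 0:
                raise FormatError(f"empty anchor list for chromosome {chrom}")
            if (np.diff(bp) <= 0).any() or (np.diff(cm) <= 0).any():
                raise FormatError(f"map anchors not strictly increasing on {chrom}")
            if cm[0] < 0:
                raise FormatError(f"negative cM anchor on {chrom}")
            self.anchors[chrom] = (bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    def interpolate_cm(self, chrom: str, pos_bp) -> np.ndarray | float:
        """Genetic position (cM) of physical position(s) on ``chrom``."""
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} not in map")
        bp, cm = self.anchors[chrom]
        return np.interp(pos_bp, bp, cm)

    def interpolate_bp(self, chrom: str, cm_pos) -> np.ndarray | float:
        """Inverse query: physical position of genetic position(s)."""
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} not in map")
        bp, cm = self.anchors[chrom]
        return np.interp(cm_pos, cm, bp)

    def span_cm(self, chrom: str) -> tuple[float, float]:
        bp, cm = self.anchors[chrom]
        return float(cm[0]), float(cm[-1])

    def total_cm(self) -> float:
        return sum(c[-1] - c[0] for _, c in self.anchors.values())


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos_bp", "cm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    anchors = {
        str(chrom): (grp["pos_bp"].to_numpy(float), grp["cm"].to_numpy(float))
        for chrom, grp in df.groupby("chrom", sort=False)
    }
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    rows = [
        {"chrom": chrom, "pos_bp": int(b), "cm": c}
        for chrom, (bp, cm) in gmap.anchors.items()
        for b, c in zip(bp, cm)
    ]
    pd.DataFrame(rows, columns=["chrom", "pos_bp", "cm"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Region sets (BED)
# ---------------------------------------------------------------------------

class RegionSet:
    """Sorted, merged 0-based half-open intervals keyed by chromosome."""

    def __init__(self, intervals=None, label: str | None = None):
        # intervals: iterable of (chrom, start, end) or dict chrom -> (n,2)
        self.label = label
        per: dict[str, list[tuple[int, int]]] = {}
        if intervals is None:
            intervals = []
        if isinstance(intervals, dict):
            intervals = [
                (c, int(s), int(e)) for c, arr in intervals.items() for s, e in arr
            ]
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start >= end:
                raise FormatError(f"invalid interval {chrom}:{start}-{end}")
            per.setdefault(str(chrom), []).append((start, end))
        self.intervals: dict[str, np.ndarray] = {}
        for chrom, ivs in per.items():
            self.intervals[chrom] = _merge(np.array(sorted(ivs), dtype=np.int64))

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.intervals)

    def total_bp(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.intervals.values())
        )

    def to_records(self) -> list[tuple[str, int, int]]:
        return [
            (chrom, int(s), int(e))
            for chrom in self.chromosomes
            for s, e in self.intervals[chrom]
        ]

    def overlap_bp(self, other: "RegionSet") -> int:
        """Total bp of intersection with ``other``."""
        total = 0
        for chrom, a in self.intervals.items():
            b = other.intervals.get(chrom)
            if b is None:
                continue
            total += _intersect_total(a, b)
        return int(total)

    def intersect(self, other: "RegionSet") -> "RegionSet":
        recs = []
        for chrom, a in self.intervals.items():
            b = other.intervals.get(chrom)
            if b is None:
                continue
            for s, e in _intersect_arrays(a, b):
                recs.append((chrom, s, e))
        return RegionSet(recs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.to_records() == other.to_records()

    def __len__(self) -> int:
        return sum(len(a) for a in self.intervals.values())


def _merge(arr: np.ndarray) -> np.ndarray:
    if len(arr) <= 1:
        return arr
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def _intersect_arrays(a: np.ndarray, b: np.ndarray):
    i = j = 0
    out = []
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((int(s), int(e)))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return out


def _intersect_total(a: np.ndarray, b: np.ndarray) -> int:
    return sum(e - s for s, e in _intersect_arrays(a, b))


def read_regions(bed_path, label=None) -> RegionSet:
    recs = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{bed_path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{bed_path}:{lineno}: start >= end")
            recs.append((chrom, start, end))
    return RegionSet(recs, label=label)


def write_regions(rs: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in rs.to_records():
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Fragment tables
# ---------------------------------------------------------------------------

def empty_fragment_table() -> pd.DataFrame:
    return _typed_fragments(pd.DataFrame(columns=FRAGMENT_COLUMNS))


def _typed_fragments(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _FRAG_BOOL:
        df[col] = df[col].astype(bool)
    for col in _FRAG_INT:
        df[col] = df[col].astype(np.int64)
    df["specimen_id"] = df["specimen_id"].astype(str)
    df["fragment_id"] = df["fragment_id"].astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)
    df["strand"] = df["strand"].astype(str)
    return df[FRAGMENT_COLUMNS]


def read_fragments(tsv_path) -> pd.DataFrame:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str, "specimen_id": str})
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{tsv_path}: missing fragment columns {missing}")
    return _typed_fragments(df)


def write_fragments(frags: pd.DataFrame, path) -> None:
    out = frags[FRAGMENT_COLUMNS].copy()
    for col in _FRAG_BOOL:
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def standard_filter(frags: pd.DataFrame, min_length: int = 35,
                    min_mapq: int = 25) -> pd.DataFrame:
    """Length >= 35 bp and MQ >= 25, the default authenticity-independent filter."""
    keep = (frags["length_bp"] >= min_length) & (frags["mapq"] >= min_mapq)
    out = frags[keep].reset_index(drop=True)
    logger.info(
        "stage=standard_filter in=%d out=%d min_length=%d min_mapq=%d",
        len(frags), len(out), min_length, min_mapq,
    )
    return out
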