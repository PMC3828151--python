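"""Shared data model and file I/O.

Coordinate conventions: physical positions (``pos_bp``) are 1-based inclusive
internally; BED output is 0-based half-open.  Genetic positions are stored in
centiMorgans (cM); demographic machinery downstream works in Morgans.
"""

from __future__ import annotations

import io
import logging
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("admixkit")

#: Approximate sex-averaged genetic lengths of the 22 human autosomes, in
#: Morgans.  Used as the default "realistic" chromosome set for simulation
#: and tract-model work when no genetic map is supplied.
HUMAN_AUTOSOME_MORGANS: tuple[float, ...] = (
    2.86, 2.69, 2.23, 2.14, 2.04, 1.92, 1.87, 1.70, 1.68, 1.81, 1.58,
    1.75, 1.26, 1.19, 1.41, 1.34, 1.29, 1.18, 1.08, 1.08, 0.62, 0.74,
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

TRACT_COLUMNS = [
    "haplotype", "chrom", "start_cM", "end_cM", "start_bp", "end_bp",
    "ancestry", "is_whole_chromosome",
]


@dataclass
class VariantTable:
    """Ordered table of biallelic SNP loci.

    ``pos_bp`` must be strictly increasing and ``pos_cM`` non-decreasing
    within each chromosome.
    """

    df: pd.DataFrame

    REQUIRED = ("chrom", "pos_bp", "pos_cM", "ref", "alt", "id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"VariantTable missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        for chrom, sub in self.df.groupby("chrom", sort=False):
            bp = sub["pos_bp"].to_numpy()
            cm = sub["pos_cM"].to_numpy(dtype=float)
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"pos_bp not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"pos_cM decreasing on {chrom}")
            if np.any(bp < 1):
                raise ValueError("pos_bp must be >= 1 (1-based)")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_slice(self, chrom) -> np.ndarray:
        """Integer indices of the variants on one chromosome."""
        return np.flatnonzero((self.df["chrom"] == chrom).to_numpy())


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix, two rows (phases) per sample.

    Rows are ordered sample-major: haplotype ``2*i + phase`` belongs to
    ``samples[i]``.  ``labels`` maps sample id to population label.
    """

    alleles: np.ndarray
    samples: list
    variants: VariantTable
    labels: dict

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x variants)")
        if self.alleles.shape[0] != 2 * len(self.samples):
            raise ValueError("row count must be 2 x sample count")
        if self.alleles.shape[1] != len(self.variants):
            raise ValueError("column count must equal variant count")
        bad = ~np.isin(self.alleles, (0, 1))
        if bad.any():
            raise ValueError("alleles must be 0/1 with no missing entries")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def haplotype_ids(self) -> list[tuple]:
        return [(s, phase) for s in self.samples for phase in (0, 1)]

    def haplotype_labels(self) -> list:
        """Population label of each haplotype row."""
        return [self.labels.get(s) for s, _ in self.haplotype_ids]

    def subset_populations(self, pops) -> "HaplotypePanel":
        keep = [i for i, s in enumerate(self.samples) if self.labels.get(s) in pops]
        rows = np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in keep]))
        samples = [self.samples[i] for i in keep]
        return HaplotypePanel(self.alleles[rows], samples, self.variants,
                              {s: self.labels[s] for s in samples})


@dataclass
class GeneticMap:
    """Per-chromosome piecewise-linear bp -> cM map."""

    knots: dict = field(default_factory=dict)  # chrom -> (bp array, cM array)

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (bp, cm) in self.knots.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            order = np.argsort(bp)
            bp, cm = bp[order], cm[order]
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"map cM decreasing on {chrom}")
            clean[chrom] = (bp, cm)
        self.knots = clean

    def chrom_length_cM(self, chrom) -> float:
        bp, cm = self.knots[chrom]
        return float(cm[-1] - cm[0])


@dataclass
class TractSet:
    """Continuous ancestry intervals per haplotype, in cM and bp."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRACT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"TractSet missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        if len(self.df):
            if np.any(self.df["end_cM"].to_numpy() < self.df["start_cM"].to_numpy()):
                raise ValueError("tract end_cM < start_cM")
            if np.any(self.df["end_bp"].to_numpy() <= self.df["start_bp"].to_numpy()):
                raise ValueError("tract end_bp <= start_bp")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths_cM(self) -> np.ndarray:
        return (self.df["end_cM"] - self.df["start_cM"]).to_numpy(dtype=float)

    @property
    def lengths_morgans(self) -> np.ndarray:
        return self.lengths_cM / 100.0

    def for_ancestry(self, ancestry) -> "TractSet":
        return TractSet(self.df[self.df["ancestry"] == ancestry].copy())


@dataclass
class IBDSegmentSet:
    """Pairwise IBD segments with pair keys normalized (id1 < id2)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["id1", "id2", "chrom", "start_bp", "end_bp", "length_Mb"]
        missing = [c for c in req if c not in self.df.columns]
        if missing:
            raise ValueError(f"IBDSegmentSet missing columns: {missing}")
        if (self.df["id1"] == self.df["id2"]).any():
            raise ValueError("IBD segment with id1 == id2")
        if (self.df["length_Mb"] <= 0).any():
            raise ValueError("non-positive IBD segment length")

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_phased_haplotypes(vcf, labels: dict | None = None) -> HaplotypePanel:
    """Read a phased VCF into a :class:`HaplotypePanel`.

    ``vcf`` may be a path or an open text stream.  Every genotype must be
    present and phased (``|`` separator); multi-allelic records are skipped
    with a warning.  Haplotype row order follows the phase order in GT.
    """
    import cyvcf2

    tmp_path = None
    if hasattr(vcf, "read"):
        # cyvcf2 (htslib) wants a real file; spool stream contents
        fd, tmp_path = tempfile.mkstemp(suffix=".vcf")
        with os.fdopen(fd, "w") as fh:
            fh.write(vcf.read())
        path = tmp_path
    else:
        path = os.fspath(vcf)

    try:
        reader = cyvcf2.VCF(path)
        samples = list(reader.samples)
        rows_meta = []
        columns = []
        for rec in reader:
            if len(rec.ALT) != 1:
                logger.warning("skipping multi-allelic record %s:%s", rec.CHROM, rec.POS)
                continue
            gts = rec.genotypes  # [a0, a1, phased] per sample
            col = np.empty(2 * len(samples), dtype=np.int8)
            for i, g in enumerate(gts):
                a0, a1, phased = g[0], g[1], g[-1]
                if a0 < 0 or a1 < 0:
                    raise ValueError(
                        f"missing GT at {rec.CHROM}:{rec.POS} sample {samples[i]}")
                if not phased:
                    raise ValueError(
                        f"unphased genotype at {rec.CHROM}:{rec.POS} sample {samples[i]}")
                col[2 * i] = a0
                col[2 * i + 1] = a1
            rows_meta.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                              rec.ID or f"{rec.CHROM}:{rec.POS}"))
            columns.append(col)
        reader.close()
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)

    if not columns:
        raise ValueError("no usable biallelic records in VCF")
    alleles = np.stack(columns, axis=1)
    vdf = pd.DataFrame(rows_meta, columns=["chrom", "pos_bp", "ref", "alt", "id"])
    vdf["pos_cM"] = 0.0
    variants = VariantTable(vdf[["chrom", "pos_bp", "pos_cM", "ref", "alt", "id"]])
    return HaplotypePanel(alleles, samples, variants, dict(labels or {}))


def read_genetic_map(source) -> GeneticMap:
    """Read a 3-column (chrom, bp, cM) tab/whitespace map, optional header."""
    df = pd.read_csv(source, sep=r"\s+", header=None, comment="#", dtype=str)
    # tolerate a header row (non-numeric second column)
    try:
        float(df.iloc[0, 1])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    knots = {}
    for chrom, sub in df.groupby(0, sort=False):
        knots[chrom] = (sub[1].astype(float).to_numpy(),
                        sub[2].astype(float).to_numpy())
    return GeneticMap(knots)


def interpolate_genetic_positions(variants: VariantTable, gmap: GeneticMap) -> VariantTable:
    """Fill ``pos_cM`` by linear interpolation between map knots.

    Positions outside the knot range are clamped to the terminal knots
    (``numpy.interp`` semantics).
    """
    df = variants.df.copy()
    cm_out = np.empty(len(df), dtype=float)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in gmap.knots:
            raise ValueError(f"chromosome {chrom!r} absent from genetic map")
        bp_knots, cm_knots = gmap.knots[chrom]
        cm_out[sub.index.to_numpy()] = np.interp(
            sub["pos_bp"].to_numpy(dtype=float), bp_knots, cm_knots)
    df["pos_cM"] = cm_out
    return VariantTable(df)


BED_HEADER = "#chrom\tstart\tend\tname\tscore\tis_whole_chromosome"


def write_tracts_bed(tracts: TractSet, stream) -> None:
    """Write tracts as BED-like text (0-based half-open bp intervals).

    name = ``sample|phase:ancestry``; score = tract length in cM x 100,
    rounded to the nearest integer.  Exact cM coordinates are carried in two
    trailing columns so that a write -> read round trip is lossless.
    """
    close = False
    if isinstance(stream, (str, os.PathLike)):
        stream = open(stream, "w")
        close = True
    try:
        stream.write(BED_HEADER + "\tstart_cM\tend_cM\n")
        for rec in tracts.df.itertuples(index=False):
            hap = rec.haplotype
            if isinstance(hap, tuple):
                hap = f"{hap[0]}|{hap[1]}"
            score = round((rec.end_cM - rec.start_cM) * 100)
            stream.write(
                f"{rec.chrom}\t{rec.start_bp - 1}\t{rec.end_bp}\t"
                f"{hap}:{rec.ancestry}\t{score}\t{int(rec.is_whole_chromosome)}"
                f"\t{rec.start_cM!r}\t{rec.end_cM!r}\n")
    finally:
        if close:
            stream.close()


def read_tracts_bed(stream) -> TractSet:
    """Inverse of :func:`write_tracts_bed`."""
    close = False
    if isinstance(stream, (str, os.PathLike)):
        stream = open(stream)
        close = True
    try:
        rows = []
        for line in stream:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, _score, whole, s_cm, e_cm = line.rstrip("\n").split("\t")
            hap, ancestry = name.rsplit(":", 1)
            if "|" in hap:
                sample, phase = hap.rsplit("|", 1)
                hap = (sample, int(phase))
            rows.append((hap, chrom, float(s_cm), float(e_cm),
                         int(start) + 1, int(end), ancestry, bool(int(whole))))
    finally:
        if close:
            stream.close()
    return TractSet(pd.DataFrame(rows, columns=TRACT_COLUMNS))


def read_ibd_segments(source) -> IBDSegmentSet:
    """Parse a whitespace table (id1, id2, chrom, start bp, end bp, ...).

    Pair keys are normalized so that id1 < id2 lexicographically; length is
    computed in Mb.  A segment with end <= start raises, naming the row.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 5:
        raise ValueError("IBD table needs >= 5 columns (id1 id2 chrom start end)")
    df = df.iloc[:, :5]
    df.columns = ["id1", "id2", "chrom", "start_bp", "end_bp"]
    df["id1"] = df["id1"].astype(str)
    df["id2"] = df["id2"].astype(str)
    bad = df.index[df["end_bp"] <= df["start_bp"]]
    if len(bad):
        raise ValueError(f"IBD segment with end <= start at row {bad[0] + 1}")
    flip = df["id1"] > df["id2"]
    df.loc[flip, ["id1", "id2"]] = df.loc[flip, ["id2", "id1"]].to_numpy()
    df["length_Mb"] = (df["end_bp"] - df["start_bp"]) / 1e6
    return IBDSegmentSet(df.reset_index(drop=True))


def uniform_variant_table(n_variants: int, chrom_lengths_morgans,
                          bp_per_cM: float = 1_000_000) -> VariantTable:
    """Evenly spaced synthetic variants across a set of chromosomes.

    Used by the simulator: ``chrom_lengths_morgans`` maps chromosome name to
    genetic length; markers are spread uniformly in cM with a constant
    bp-per-cM scale.
    """
    total = float(sum(chrom_lengths_morgans.values()))
    rows = []
    for chrom, L in chrom_lengths_morgans.items():
        k = max(2, int(round(n_variants * L / total)))
        cm = np.linspace(0.0, L * 100.0, k)
        bp = np.maximum(1, np.round(cm * bp_per_cM)).astype(np.int64)
        bp = np.maximum.accumulate(bp)
        bp += np.arange(k)  # enforce strict increase
        for j in range(k):
            rows.append((chrom, int(bp[j]), float(cm[j]), "A", "G", f"{chrom}_{j}"))
    return VariantTable(pd.DataFrame(
        rows, columns=["chrom", "pos_bp", "pos_cM", "ref", "alt", "id"]))


def write_phased_vcf(panel: HaplotypePanel, stream) -> None:
    """Write a panel as a minimal phased VCF (GT only)."""
    close = False
    if isinstance(stream, (str, os.PathLike)):
        stream = open(stream, "w")
        close = True
    try:
        stream.write("##fileformat=VCFv4.2\n")
        stream.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.variants.chroms:
            stream.write(f"##contig=<ID={chrom}>\n")
        stream.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(str(s) for s in panel.samples) + "\n")
        A = panel.alleles
        for j, rec in enumerate(panel.variants.df.itertuples(index=False)):
            gts = "\t".join(f"{A[2 * i, j]}|{A[2 * i + 1, j]}"
                            for i in range(len(panel.samples)))
            stream.write(f"{rec.chrom}\t{rec.pos_bp}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                         f"\t.\t.\t.\tGT\t{gts}\n")
    finally:
        if close:
            stream.close()
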