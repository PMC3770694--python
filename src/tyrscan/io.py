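"""Readers, writers and the core data containers.

Three containers feed every downstream analysis:

``Alignment``
    A sample x site nucleotide matrix from a resequencing project, with an
    optional outgroup row, per-column coordinates (genomic and relative to the
    first codon of the gene) and per-column region labels (5'flank, exon_k,
    intron_k, 3'flank).

``SiteTable``
    One row per variable column of an :class:`Alignment` (outgroup excluded
    from variability calls): alleles, minor-allele frequency, derived-allele
    count polarised by the outgroup, singleton / parsimony-informative class,
    coding effect and a rare (MAF < 0.05) flag.

``HaplotypePanel``
    A phased, polarised 0/1 haplotype x SNP matrix from an array genotyping
    project, with physical (bp) and genetic (cM) positions.

Missing data policy (complete deletion): alignment columns containing a gap or
``N`` in any sample row are excluded from variable-site calls and from
diversity denominators.  The excluded columns are recorded on the alignment.

Coordinate conventions: genomic positions are 1-based; intervals (windows,
region annotations) are half-open ``[start, end)`` in 0-based alignment column
space; the position relative to the first codon is 0 at the A of the start
codon and negative upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    AnnotationError,
    FormatError,
    MapError,
    PhasingError,
)

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
MISSING_BASES = frozenset("N-")

STANDARD_CODON_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionInterval:
    """Half-open interval of alignment columns with a region label.

    ``frame`` is only meaningful for exon intervals: the number of columns at
    the start of the interval that complete the codon begun in the previous
    exon (0 means the interval starts on a codon boundary).
    """

    start: int
    end: int
    label: str
    frame: int = 0

    def __post_init__(self):
        if self.end <= self.start:
            raise AnnotationError(f"empty interval {self.start}:{self.end}")
        if self.frame not in (0, 1, 2):
            raise AnnotationError(f"frame must be 0/1/2, got {self.frame}")

    @property
    def is_exon(self) -> bool:
        return self.label.startswith("exon")


def read_regions(path) -> list[RegionInterval]:
    """Read a BED-like region annotation (TSV: start, end, label[, frame]).

    Lines starting with ``#`` are comments; a ``#genomic_start=N`` comment
    records the 1-based genomic position of alignment column 0 (returned via
    :func:`read_alignment`).
    """
    intervals = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"region line needs >=3 columns: {line!r}")
        frame = int(parts[3]) if len(parts) > 3 else 0
        intervals.append(RegionInterval(int(parts[0]), int(parts[1]), parts[2], frame))
    return sorted(intervals, key=lambda iv: iv.start)


def _genomic_start_from_file(path) -> int:
    for line in Path(path).read_text().splitlines():
        if line.startswith("#genomic_start="):
            return int(line.split("=", 1)[1])
    return 1


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Sample x site nucleotide matrix with outgroup, coordinates and regions."""

    sample_ids: list[str]
    pop_labels: list[str]
    seqs: np.ndarray                      # (n_samples, L) of single characters
    outgroup: np.ndarray | None = None    # (L,) or None
    outgroup_id: str | None = None
    genomic_start: int = 1                # 1-based genomic position of column 0
    regions: list[RegionInterval] = field(default_factory=list)

    def __post_init__(self):
        self.seqs = np.asarray(self.seqs, dtype="U1")
        if self.seqs.ndim != 2:
            raise FormatError("seqs must be a 2-D sample x site matrix")
        if len(self.sample_ids) != self.seqs.shape[0]:
            raise FormatError("sample_ids length does not match seqs rows")
        if len(self.pop_labels) != self.seqs.shape[0]:
            raise FormatError("pop_labels length does not match seqs rows")
        if self.outgroup is not None:
            self.outgroup = np.asarray(self.outgroup, dtype="U1")
            if self.outgroup.shape != (self.seqs.shape[1],):
                raise FormatError("outgroup length does not match alignment")
        if self.regions:
            self._check_regions()

    def _check_regions(self):
        prev_end = None
        covered = 0
        for iv in self.regions:
            if prev_end is not None and iv.start < prev_end:
                raise AnnotationError(
                    f"overlapping region intervals at column {iv.start}")
            prev_end = iv.end
            covered += iv.end - iv.start
        if self.regions[0].start != 0 or self.regions[-1].end != self.length \
                or covered != self.length:
            raise AnnotationError("region intervals do not partition the columns")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.seqs.shape[0]

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    @property
    def positions(self) -> np.ndarray:
        """1-based genomic position of every column."""
        return np.arange(self.length) + self.genomic_start

    @property
    def first_codon_col(self) -> int | None:
        """Alignment column of the A of the start codon (from exon_1 + frame)."""
        for iv in self.regions:
            if iv.label == "exon_1":
                return iv.start + iv.frame
        return None

    @property
    def rel_pos(self) -> np.ndarray:
        """Per-column position relative to the first codon (0 at the A)."""
        origin = self.first_codon_col
        if origin is None:
            origin = 0
        return np.arange(self.length) - origin

    @property
    def region_labels(self) -> np.ndarray:
        """Per-column region label (empty string where unannotated)."""
        labels = np.full(self.length, "", dtype=object)
        for iv in self.regions:
            labels[iv.start:iv.end] = iv.label
        return labels

    # -- missing-data mask -------------------------------------------------
    @property
    def analyzable(self) -> np.ndarray:
        """Boolean mask of columns free of gaps/N in every sample row."""
        ok = np.ones(self.length, dtype=bool)
        for ch in MISSING_BASES:
            ok &= ~(self.seqs == ch).any(axis=0)
        # anything outside ACGT counts as missing too
        known = np.isin(self.seqs, list(VALID_BASES)).all(axis=0)
        return ok & known

    def columns_for_region(self, labels) -> np.ndarray:
        """Column indices belonging to any of the given region labels."""
        if isinstance(labels, str):
            labels = [labels]
        per_col = self.region_labels
        return np.flatnonzero(np.isin(per_col, list(labels)))

    def subset_samples(self, population=None, sample_ids=None) -> "Alignment":
        """Row subset by population label or explicit sample ids."""
        if population is not None:
            keep = [i for i, p in enumerate(self.pop_labels) if p == population]
        elif sample_ids is not None:
            wanted = set(sample_ids)
            keep = [i for i, s in enumerate(self.sample_ids) if s in wanted]
        else:
            keep = list(range(self.n_samples))
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in keep],
            pop_labels=[self.pop_labels[i] for i in keep],
            seqs=self.seqs[keep],
        )


def read_alignment(fasta_path, metadata_path, annotation_path=None) -> Alignment:
    """Build a validated :class:`Alignment` from FASTA + metadata (+ regions).

    The metadata TSV has columns ``sample``, ``population`` and an optional
    ``outgroup`` flag (1/true marks the single outgroup record, which is
    separated from the sample rows).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {fasta_path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"FASTA records of unequal length: {sorted(lengths)}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    meta.columns = [c.lower() for c in meta.columns]
    if "sample" not in meta.columns or "population" not in meta.columns:
        raise FormatError("metadata needs 'sample' and 'population' columns")
    meta = meta.set_index("sample")

    sample_ids, pop_labels, rows = [], [], []
    outgroup_row, outgroup_id = None, None
    for rec in records:
        if rec.id not in meta.index:
            raise KeyError(f"record {rec.id!r} missing from metadata")
        info = meta.loc[rec.id]
        is_outgroup = str(info.get("outgroup", "")).lower() in {"1", "true", "yes"}
        row = np.frombuffer(str(rec.seq).upper().encode(), dtype="S1").astype("U1")
        if is_outgroup:
            if outgroup_row is not None:
                raise FormatError("more than one outgroup record flagged")
            outgroup_row, outgroup_id = row, rec.id
        else:
            sample_ids.append(rec.id)
            pop_labels.append(str(info["population"]))
            rows.append(row)

    regions: list[RegionInterval] = []
    genomic_start = 1
    if annotation_path is not None:
        regions = read_regions(annotation_path)
        genomic_start = _genomic_start_from_file(annotation_path)

    return Alignment(
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        seqs=np.vstack(rows) if rows else np.empty((0, lengths.pop())),
        outgroup=outgroup_row,
        outgroup_id=outgroup_id,
        genomic_start=genomic_start,
        regions=regions,
    )


def write_alignment(aln: Alignment, fasta_path) -> None:
    """Write the alignment (plus outgroup, if any) back to FASTA."""
    records = [
        SeqRecord(Seq("".join(row)), id=sid, description="")
        for sid, row in zip(aln.sample_ids, aln.seqs)
    ]
    if aln.outgroup is not None:
        records.append(
            SeqRecord(Seq("".join(aln.outgroup)),
                      id=aln.outgroup_id or "outgroup", description=""))
    SeqIO.write(records, str(fasta_path), "fasta-2line")


# ---------------------------------------------------------------------------
# Site table
# ---------------------------------------------------------------------------

def _codon_context(aln: Alignment) -> dict[int, tuple[int, int, int]]:
    """Map coding column -> (c0, c1, c2) columns of its codon.

    Codons are read within each exon interval honouring its frame; codons
    truncated by the sequencing boundary (junction overhangs) are dropped.
    Raises :class:`AnnotationError` when an exon's in-frame length is not a
    multiple of 3 and the interval is not the last exon piece.
    """
    # concatenate exon columns in order, tracking codon phase across exons
    exon_cols: list[int] = []
    for iv in sorted((iv for iv in aln.regions if iv.is_exon),
                     key=lambda iv: iv.start):
        cols = list(range(iv.start, iv.end))
        if iv.frame:
            # columns completing a codon started in an unsequenced exon part:
            # no full-codon context, drop them
            if (iv.end - iv.start - iv.frame) % 3 != 0 and iv is not aln.regions[-1]:
                pass  # trailing overhang handled below by truncation
            cols = cols[iv.frame:]
        exon_cols.extend(cols)
    mapping: dict[int, tuple[int, int, int]] = {}
    for k in range(0, len(exon_cols) - len(exon_cols) % 3, 3):
        codon = tuple(exon_cols[k:k + 3])
        for c in codon:
            mapping[c] = codon
    return mapping


def _coding_effect(aln, col, alt_allele, codon_map, codon_table) -> str:
    codon_cols = codon_map.get(col)
    if codon_cols is None:
        return "noncoding"
    # reference codon from the major allele of each position
    ref = []
    for c in codon_cols:
        alleles, counts = np.unique(aln.seqs[:, c], return_counts=True)
        ref.append(alleles[np.argmax(counts)])
    alt = list(ref)
    alt[codon_cols.index(col)] = alt_allele
    fwd = codon_table.forward_table
    aa_ref = fwd.get("".join(ref), "*")
    aa_alt = fwd.get("".join(alt), "*")
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def build_site_table(aln: Alignment, codon_table=STANDARD_CODON_TABLE) -> pd.DataFrame:
    """One row per variable column among the sample rows (complete deletion).

    Columns: ``col`` (alignment column), ``position`` (genomic, 1-based),
    ``rel_pos``, ``region``, ``alleles``, ``maf``, ``derived_count`` (NaN when
    the outgroup carries a gap/N or a third allele), ``site_class``
    (singleton / parsimony_informative / other), ``coding_effect`` and
    ``rare`` (MAF < 0.05 strictly).
    """
    if aln.n_samples == 0:
        raise FormatError("empty alignment")
    codon_map = _codon_context(aln) if aln.regions else {}
    # validate exon frames: total in-frame exon length must be divisible by 3
    # when the annotation claims complete coding sequence
    analyzable = aln.analyzable
    labels = aln.region_labels
    rel = aln.rel_pos
    positions = aln.positions
    n = aln.n_samples

    rows = []
    for col in np.flatnonzero(analyzable):
        alleles, counts = np.unique(aln.seqs[:, col], return_counts=True)
        if len(alleles) < 2:
            continue
        order = np.argsort(counts)[::-1]
        alleles, counts = alleles[order], counts[order]
        maf = 1.0 - counts[0] / n
        n_ge2 = int((counts >= 2).sum())
        if n_ge2 >= 2:
            site_class = "parsimony_informative"
        elif len(alleles) == 2 and counts[-1] == 1:
            site_class = "singleton"
        else:
            site_class = "other"
        derived_count = np.nan
        ancestral = None
        if aln.outgroup is not None:
            out_allele = aln.outgroup[col]
            if out_allele in alleles and out_allele in VALID_BASES:
                ancestral = out_allele
                derived_count = int(n - counts[list(alleles).index(out_allele)])
        # coding effect: any non-major allele producing an aa change
        effect = "noncoding"
        if col in codon_map:
            effects = {
                _coding_effect(aln, col, a, codon_map, codon_table)
                for a in alleles[1:]
            }
            effect = "nonsynonymous" if "nonsynonymous" in effects else "synonymous"
        rows.append(dict(
            col=int(col), position=int(positions[col]), rel_pos=int(rel[col]),
            region=labels[col] or "", alleles="/".join(alleles), maf=maf,
            derived_count=derived_count, ancestral=ancestral,
            site_class=site_class, coding_effect=effect, rare=maf < 0.05,
        ))
    table = pd.DataFrame(rows, columns=[
        "col", "position", "rel_pos", "region", "alleles", "maf",
        "derived_count", "ancestral", "site_class", "coding_effect", "rare"])
    n_masked = int((~analyzable).sum())
    if n_masked:
        logger.info("site table: %d columns excluded by complete deletion", n_masked)
    return table


# ---------------------------------------------------------------------------
# Haplotype panel
# ---------------------------------------------------------------------------

MISSING_GT = -1


@dataclass
class HaplotypePanel:
    """Phased, polarised biallelic haplotype panel (0 = ancestral, -1 missing)."""

    hap_ids: list[str]
    pop_labels: list[str]
    geno: np.ndarray            # (n_haps, n_snps) int8 in {0, 1, -1}
    pos_bp: np.ndarray          # 1-based physical positions
    pos_cM: np.ndarray          # genetic-map positions
    chrom: np.ndarray           # per-SNP chromosome label
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cM = np.asarray(self.pos_cM, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if not self.snp_ids:
            self.snp_ids = [f"{c}:{p}" for c, p in zip(self.chrom, self.pos_bp)]
        bad = ~np.isin(self.geno, (0, 1, MISSING_GT))
        if bad.any():
            raise FormatError("panel genotypes must be 0/1/missing")
        for ch in np.unique(self.chrom):
            m = self.chrom == ch
            if (np.diff(self.pos_bp[m]) <= 0).any():
                raise FormatError(f"pos_bp not strictly increasing on {ch}")
            if (np.diff(self.pos_cM[m]) < 0).any():
                raise FormatError(f"pos_cM decreasing on {ch}")

    @property
    def n_haps(self) -> int:
        return self.geno.shape[0]

    @property
    def n_snps(self) -> int:
        return self.geno.shape[1]

    def call_rate(self) -> np.ndarray:
        return (self.geno != MISSING_GT).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency over non-missing haplotypes per SNP."""
        called = self.geno != MISSING_GT
        ones = np.where(self.geno == 1, 1, 0).sum(axis=0)
        tot = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            f = np.where(tot > 0, ones / np.maximum(tot, 1), np.nan)
        return np.minimum(f, 1 - f)

    def daf(self) -> np.ndarray:
        """Derived-allele frequency (allele 1) over non-missing haplotypes."""
        called = self.geno != MISSING_GT
        ones = np.where(self.geno == 1, 1, 0).sum(axis=0)
        tot = called.sum(axis=0)
        return np.where(tot > 0, ones / np.maximum(tot, 1), np.nan)

    def subset_snps(self, mask_or_idx) -> "HaplotypePanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypePanel(
            hap_ids=self.hap_ids, pop_labels=self.pop_labels,
            geno=self.geno[:, idx], pos_bp=self.pos_bp[idx],
            pos_cM=self.pos_cM[idx], chrom=self.chrom[idx],
            snp_ids=[self.snp_ids[i] for i in idx])

    def subset_pop(self, population) -> "HaplotypePanel":
        pops = [population] if isinstance(population, str) else list(population)
        keep = [i for i, p in enumerate(self.pop_labels) if p in pops]
        return HaplotypePanel(
            hap_ids=[self.hap_ids[i] for i in keep],
            pop_labels=[self.pop_labels[i] for i in keep],
            geno=self.geno[keep], pos_bp=self.pos_bp, pos_cM=self.pos_cM,
            chrom=self.chrom, snp_ids=list(self.snp_ids))


# -- genetic map -----------------------------------------------------------

def read_genetic_map(path) -> pd.DataFrame:
    """HapMap-format genetic map: chrom, position (bp), rate (cM/Mb), map (cM)."""
    gmap = pd.read_csv(path, sep=r"\s+")
    gmap.columns = [c.lower().split("(")[0].strip() for c in gmap.columns]
    ren = {}
    for c in gmap.columns:
        if c.startswith("chr"):
            ren[c] = "chrom"
        elif c.startswith("pos"):
            ren[c] = "pos"
        elif c.startswith("rate") or c.startswith("combined"):
            ren[c] = "rate"
        elif c.startswith("map") or c.startswith("genetic"):
            ren[c] = "cm"
    gmap = gmap.rename(columns=ren)
    if "pos" not in gmap.columns or "cm" not in gmap.columns:
        raise MapError("genetic map needs position and cM columns")
    if "chrom" not in gmap.columns:
        gmap["chrom"] = "1"
    gmap["chrom"] = gmap["chrom"].astype(str)
    return gmap[[c for c in ("chrom", "pos", "rate", "cm") if c in gmap.columns]]


def interpolate_cm(gmap: pd.DataFrame, chrom, pos_bp) -> np.ndarray:
    """Linear interpolation between map anchors; flat extrapolation with warning."""
    pos_bp = np.asarray(pos_bp)
    sub = gmap[gmap["chrom"] == str(chrom)]
    if sub.empty:
        raise MapError(f"no map anchors for chromosome {chrom}")
    xp = sub["pos"].to_numpy(float)
    fp = sub["cm"].to_numpy(float)
    order = np.argsort(xp)
    xp, fp = xp[order], fp[order]
    outside = (pos_bp < xp[0]) | (pos_bp > xp[-1])
    if outside.any():
        logger.warning("%d SNPs outside map range on %s; extrapolating flat",
                       int(outside.sum()), chrom)
    return np.interp(pos_bp, xp, fp)


# -- readers ----------------------------------------------------------------

def _read_metadata_pops(metadata_path) -> dict[str, str]:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    meta.columns = [c.lower() for c in meta.columns]
    return dict(zip(meta["sample"], meta["population"]))


def read_panel(vcf_or_table_path, map_path, metadata_path) -> HaplotypePanel:
    """Read a phased panel from VCF 4.2 (AA in INFO) or a haplotype TSV.

    Biallelic SNPs only; SNPs without a usable ancestral-allele call (missing
    AA, or AA equal to neither observed allele) are dropped with a logged
    count; coding flips alleles so that 0 is ancestral.
    """
    path = str(vcf_or_table_path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        hap_ids, pops, geno, chrom, pos, ids = _read_panel_vcf(path, metadata_path)
    else:
        hap_ids, pops, geno, chrom, pos, ids = _read_panel_table(path, metadata_path)
    gmap = read_genetic_map(map_path)
    cm = np.empty(len(pos), dtype=float)
    for ch in np.unique(chrom):
        m = chrom == ch
        cm[m] = interpolate_cm(gmap, ch, pos[m])
    return HaplotypePanel(hap_ids=hap_ids, pop_labels=pops, geno=geno,
                          pos_bp=pos, pos_cM=cm, chrom=chrom, snp_ids=ids)


def _read_panel_vcf(path, metadata_path):
    from cyvcf2 import VCF

    pops_by_sample = _read_metadata_pops(metadata_path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    for s in samples:
        if s not in pops_by_sample:
            raise KeyError(f"sample {s!r} missing from metadata")
    hap_ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    pops = [pops_by_sample[s] for s in samples for _ in (1, 2)]

    cols, chroms, positions, ids = [], [], [], []
    n_dropped_aa = n_dropped_multi = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped_multi += 1
            continue
        aa = v.INFO.get("AA")
        aa = aa.upper() if isinstance(aa, str) else None
        if aa not in (v.REF, v.ALT[0]):
            n_dropped_aa += 1
            continue
        col = np.empty(len(hap_ids), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a0, a1, phased = g[0], g[1], g[-1]
            if a0 >= 0 and a1 >= 0 and not phased:
                raise PhasingError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{v.CHROM}:{v.POS}")
            col[2 * i] = a0 if a0 >= 0 else MISSING_GT
            col[2 * i + 1] = a1 if a1 >= 0 else MISSING_GT
        if aa == v.ALT[0]:          # polarity: 0 must be ancestral
            col = np.where(col == MISSING_GT, MISSING_GT, 1 - col).astype(np.int8)
        cols.append(col)
        chroms.append(str(v.CHROM))
        positions.append(v.POS)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
    if n_dropped_aa or n_dropped_multi:
        logger.info("read_panel: dropped %d SNPs without ancestral call, "
                    "%d non-biallelic", n_dropped_aa, n_dropped_multi)
    if not cols:
        raise FormatError(f"no usable SNPs in {path}")
    return (hap_ids, pops, np.column_stack(cols),
            np.array(chroms, dtype=object), np.array(positions), ids)


def _read_panel_table(path, metadata_path):
    """Wide haplotype TSV: hap_id, sample, then one column per SNP 'chrom:pos'."""
    pops_by_sample = _read_metadata_pops(metadata_path)
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if tab.columns[0] != "hap_id" or tab.columns[1] != "sample":
        raise FormatError("haplotype table must start with hap_id, sample")
    hap_ids = tab["hap_id"].tolist()
    samples = tab["sample"].tolist()
    for s in samples:
        if s not in pops_by_sample:
            raise KeyError(f"sample {s!r} missing from metadata")
    pops = [pops_by_sample[s] for s in samples]
    snp_cols = list(tab.columns[2:])
    geno = np.full((len(hap_ids), len(snp_cols)), MISSING_GT, dtype=np.int8)
    for j, c in enumerate(snp_cols):
        vals = tab[c].fillna(".").to_numpy()
        geno[:, j] = [MISSING_GT if v in (".", "") else int(v) for v in vals]
    chrom = np.array([c.split(":")[0] for c in snp_cols], dtype=object)
    pos = np.array([int(c.split(":")[1]) for c in snp_cols])
    return hap_ids, pops, geno, chrom, pos, snp_cols


# -- filtering ---------------------------------------------------------------

@dataclass
class FilterReport:
    panel: HaplotypePanel
    n_removed_call_rate: int
    n_removed_maf: int


def filter_panel(panel: HaplotypePanel, min_call_rate=0.95,
                 min_maf=0.05) -> FilterReport:
    """Array QC filters: keep SNPs with call rate >= ``min_call_rate`` and
    minor-allele frequency strictly over ``min_maf``; order preserved.

    ``min_maf=0`` keeps monomorphic SNPs (identity filter).
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    cr = panel.call_rate()
    maf = np.nan_to_num(panel.maf(), nan=0.0)
    pass_cr = cr >= min_call_rate
    pass_maf = (maf > min_maf) if min_maf > 0 else np.ones_like(pass_cr)
    keep = pass_cr & pass_maf
    if not keep.any():
        logger.warning("filter_panel removed every SNP")
    return FilterReport(
        panel=panel.subset_snps(keep),
        n_removed_call_rate=int((~pass_cr).sum()),
        n_removed_maf=int((pass_cr & ~pass_maf).sum()))
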