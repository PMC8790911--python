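"""Readers and writers for genotype matrices, VCF, and helper recodings.

Genotype matrices travel as FASTA or relaxed PHYLIP with one row per cell
and one single-character unphased genotype per site (A,C,G,T homozygotes;
IUPAC letters M,R,W,S,Y,K for the six heterozygote allele pairs; '?', 'N'
or '-' for missing).  VCF input is supported in GT mode (called genotypes)
and PL mode (Phred-scaled likelihood triplets per biallelic SNV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import alphabet as ab


@dataclass
class GenotypeMatrix:
    """Cells x sites matrix of unphased genotype state indices.

    ``matrix`` is int8 with values 0..9 (unphased states) or 10 (missing).
    ``site_ids`` are "CHROM:POS" strings for VCF input or column indices
    otherwise; ``ref``/``alt`` hold per-site alleles when known (VCF).
    """

    matrix: np.ndarray
    cell_names: list[str]
    site_ids: list[str] = field(default_factory=list)
    ref: list[str] | None = None
    alt: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (cells x sites)")
        if len(self.cell_names) != self.matrix.shape[0]:
            raise ValueError("cell name count does not match matrix rows")
        if len(set(self.cell_names)) != len(self.cell_names):
            raise ValueError("duplicate cell names")
        if self.matrix.size and (self.matrix.min() < 0
                                 or self.matrix.max() > ab.MISSING_INDEX):
            raise ValueError("matrix entries outside the genotype alphabet")
        if not self.site_ids:
            self.site_ids = [str(i) for i in range(self.matrix.shape[1])]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row_string(self, i: int) -> str:
        return ab.decode_row(self.matrix[i])

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.matrix[:, idx], list(self.cell_names),
            [self.site_ids[i] for i in idx],
            [self.ref[i] for i in idx] if self.ref else None,
            [self.alt[i] for i in idx] if self.alt else None)


def _matrix_from_rows(names: list[str], rows: list[str],
                      source: str) -> GenotypeMatrix:
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"{source}: duplicate cell names {dupes}")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValueError(f"{source}: ragged rows (lengths {sorted(widths)})")
    mat = np.empty((len(rows), rows[0].__len__() if rows else 0), dtype=np.int8)
    for i, row in enumerate(rows):
        for j, c in enumerate(row):
            try:
                mat[i, j] = ab.encode_char(c)
            except ValueError:
                raise ValueError(
                    f"{source}: illegal genotype character {c!r} for cell "
                    f"{names[i]!r} at site {j + 1}") from None
    return GenotypeMatrix(mat, names)


def read_genotype_matrix(path, format: str = "phylip") -> GenotypeMatrix:
    """Read a genotype matrix from FASTA or (relaxed) PHYLIP."""
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no sequences found")
        names = [r.id for r in records]
        rows = [str(r.seq) for r in records]
    elif format == "phylip":
        aln = AlignIO.read(str(path), "phylip-relaxed")
        names = [r.id for r in aln]
        rows = [str(r.seq) for r in aln]
    else:
        raise ValueError(f"unknown format {format!r} (use fasta or phylip)")
    return _matrix_from_rows(names, rows, str(path))


def write_genotype_matrix(data: GenotypeMatrix, path,
                          format: str = "phylip") -> None:
    records = [SeqRecord(Seq(data.row_string(i)), id=name, description="")
               for i, name in enumerate(data.cell_names)]
    if format == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif format == "phylip":
        AlignIO.write(MultipleSeqAlignment(records), str(path),
                      "phylip-relaxed")
    else:
        raise ValueError(f"unknown format {format!r}")


# -- VCF ------------------------------------------------------------------


@dataclass
class PLData:
    """Per-site Phred-scaled genotype likelihood triplets from a VCF.

    ``pl`` has shape (cells, sites, 3) with NaN rows for missing calls.
    """

    pl: np.ndarray
    cell_names: list[str]
    site_ids: list[str]
    ref: list[str]
    alt: list[str]
    skipped: int = 0


def _open_vcf(path):
    import pysam
    return pysam.VariantFile(str(path))


def read_vcf(path, mode: str = "GT"):
    """Read a VCF in GT mode (-> GenotypeMatrix) or PL mode (-> PLData).

    GT mode treats phased and unphased calls identically (the phase bar
    carries no extra information for an unphased model).  PL mode keeps
    only biallelic SNV records with a 3-value PL; skipped records
    (indels, multi-allelic) are counted.
    """
    if mode not in ("GT", "PL"):
        raise ValueError("mode must be GT or PL")
    vf = _open_vcf(path)
    cells = list(vf.header.samples)
    site_ids: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    skipped = 0
    gt_cols: list[np.ndarray] = []
    pl_cols: list[np.ndarray] = []
    for rec in vf:
        alleles = [rec.ref] + list(rec.alts or ())
        if any(a is None or len(a) != 1 or a.upper() not in "ACGT"
               for a in alleles):
            skipped += 1
            continue
        if mode == "PL" and len(alleles) != 2:
            skipped += 1
            continue
        if mode == "GT":
            col = np.full(len(cells), ab.MISSING_INDEX, dtype=np.int8)
            for i, cell in enumerate(cells):
                gt = rec.samples[cell].get("GT")
                if gt is None or any(g is None for g in gt):
                    continue
                if len(gt) != 2:
                    raise ValueError(
                        f"{path}: non-diploid GT at {rec.chrom}:{rec.pos} "
                        f"for {cell}")
                a, b = alleles[gt[0]].upper(), alleles[gt[1]].upper()
                col[i] = ab.unphased_index(a, b)
            gt_cols.append(col)
        else:
            col = np.full((len(cells), 3), np.nan)
            for i, cell in enumerate(cells):
                sample = rec.samples[cell]
                gt = sample.get("GT")
                missing_call = gt is None or all(g is None for g in gt)
                pl = sample.get("PL")
                if pl is None or any(p is None for p in pl):
                    if missing_call:
                        continue  # stays NaN -> uninformative tip
                    raise ValueError(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks PL "
                        f"for sample {cell}")
                if len(pl) != 3:
                    raise ValueError(
                        f"{path}: non-triplet PL at {rec.chrom}:{rec.pos}")
                col[i] = pl
            pl_cols.append(col)
        site_ids.append(f"{rec.chrom}:{rec.pos}")
        refs.append(rec.ref.upper())
        alts.append(alleles[1].upper() if len(alleles) > 1 else rec.ref.upper())
    if mode == "GT":
        mat = (np.stack(gt_cols, axis=1) if gt_cols
               else np.empty((len(cells), 0), dtype=np.int8))
        return GenotypeMatrix(mat, cells, site_ids, refs, alts)
    pl = (np.stack(pl_cols, axis=1) if pl_cols
          else np.empty((len(cells), 0, 3)))
    return PLData(pl, cells, site_ids, refs, alts, skipped)


def write_vcf(path, matrix: GenotypeMatrix,
              pl: np.ndarray | None = None, command: str | None = None) -> None:
    """Write a GenotypeMatrix (optionally with PL triplets) as a VCF.

    Sites lacking ref/alt metadata get placeholder alleles from the
    observed genotypes.
    """
    import pysam
    header = pysam.VariantHeader()
    header.add_line('##source=gtphylo')
    if command:
        header.add_line(f'##gtphylo_command={command}')
    header.contigs.add("1")
    header.formats.add("GT", 1, "String", "Genotype")
    if pl is not None:
        header.formats.add("PL", "G", "Integer",
                           "Phred-scaled genotype likelihoods")
    for name in matrix.cell_names:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(matrix.n_sites):
            ref = matrix.ref[j] if matrix.ref else None
            alt = matrix.alt[j] if matrix.alt else None
            if ref is None or alt is None or ref == alt:
                alleles_here = sorted({a
                                       for i in range(matrix.n_cells)
                                       if matrix.matrix[i, j] != ab.MISSING_INDEX
                                       for a in ab.unphased_alleles(
                                           matrix.matrix[i, j])})
                ref = ref or (alleles_here[0] if alleles_here else "A")
                rest = [a for a in alleles_here if a != ref]
                alt = rest[0] if rest else ("C" if ref == "A" else "A")
            rec = out.new_record(contig="1", start=j, stop=j + 1,
                                 alleles=(ref, alt))
            idx = {ref: 0, alt: 1}
            for i, cell in enumerate(matrix.cell_names):
                g = matrix.matrix[i, j]
                if g == ab.MISSING_INDEX:
                    rec.samples[cell]["GT"] = (None, None)
                else:
                    a, b = ab.unphased_alleles(g)
                    if a in idx and b in idx:
                        rec.samples[cell]["GT"] = tuple(
                            sorted((idx[a], idx[b])))
                    else:
                        rec.samples[cell]["GT"] = (None, None)
                if pl is not None:
                    v = pl[i, j]
                    rec.samples[cell]["PL"] = (
                        None if np.any(np.isnan(v))
                        else tuple(int(round(x)) for x in v))
            out.write(rec)


def convert_sccaller_pl(pl4) -> tuple[int, int, int]:
    """Convert an SC-Caller 4-value PL layout to a standard triplet.

    SC-Caller stores Phred likelihoods for (sequencing noise, amplification
    artifact, heterozygous, homozygous-alternative).  The homozygous
    reference likelihood is taken as the best (minimum Phred) of the first
    two values; the result is shifted so its minimum is 0.
    """
    pl4 = list(pl4)
    if len(pl4) != 4:
        raise ValueError("SC-Caller PL conversion expects 4 values")
    triplet = [min(pl4[0], pl4[1]), pl4[2], pl4[3]]
    m = min(triplet)
    return tuple(int(v - m) for v in triplet)


# -- ternary recoding -----------------------------------------------------

TERNARY_HOM_REF = 0
TERNARY_HET = 1
TERNARY_HOM_ALT = 2
TERNARY_MISSING = 3


def recode_ternary(data: GenotypeMatrix, ref_alleles: list[str],
                   mode: str = "missing") -> np.ndarray:
    """Recode DNA genotypes into ternary 0/1/2/3 calls.

    0 = homozygous reference, 1 = heterozygous, 2 = homozygous
    alternative, 3 = missing.  Multi-allelic sites (more than two alleles
    observed) are handled per ``mode``: "keep" retains every site (any
    heterozygote -> 1, any non-reference homozygote -> 2); "remove" drops
    them; "missing" marks genotypes carrying a minor alternative allele as
    3, preserving the site count.
    """
    if mode not in ("keep", "remove", "missing"):
        raise ValueError("mode must be keep, remove or missing")
    if len(ref_alleles) != data.n_sites:
        raise ValueError("need one reference allele per site")
    out = np.full((data.n_cells, data.n_sites), TERNARY_MISSING, dtype=np.int8)
    keep_site = np.ones(data.n_sites, dtype=bool)
    for j in range(data.n_sites):
        ref = ref_alleles[j].upper()
        col = data.matrix[:, j]
        allele_counts: dict[str, int] = {}
        for g in col:
            if g == ab.MISSING_INDEX:
                continue
            a, b = ab.unphased_alleles(int(g))
            allele_counts[a] = allele_counts.get(a, 0) + 1
            allele_counts[b] = allele_counts.get(b, 0) + 1
        alts = sorted((a for a in allele_counts if a != ref),
                      key=lambda a: (-allele_counts[a], a))
        multi = len(alts) > 1
        if multi and mode == "remove":
            keep_site[j] = False
            continue
        major_alt = alts[0] if alts else None
        for i, g in enumerate(col):
            if g == ab.MISSING_INDEX:
                continue
            a, b = ab.unphased_alleles(int(g))
            if mode == "missing" and multi:
                allowed = {ref, major_alt}
                if not {a, b} <= allowed:
                    continue  # minor alternative allele -> missing
            if a == b == ref:
                out[i, j] = TERNARY_HOM_REF
            elif a == b:
                out[i, j] = TERNARY_HOM_ALT
            elif ref in (a, b):
                out[i, j] = TERNARY_HET
            else:  # heterozygote without the reference allele
                out[i, j] = (TERNARY_HET if mode == "keep"
                             else TERNARY_MISSING)
    if mode == "remove":
        return out[:, keep_site]
    return out


def filter_missing_sites(data: GenotypeMatrix,
                         max_missing_fraction: float = 0.5) -> GenotypeMatrix:
    """Optionally drop sites missing in more than the given cell fraction."""
    frac = (data.matrix == ab.MISSING_INDEX).mean(axis=0)
    return data.take_sites(np.nonzero(frac <= max_missing_fraction)[0])
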