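"""Biallelic SNV table with per-sample genotypes and allele depths.

:class:`VariantTable` is the in-memory substrate of variant filtering, the
dAF scan and marker design.  Genotypes are coded ``0`` hom-ref, ``1`` het,
``2`` hom-alt, ``-1`` missing; allele depths are ``(ref_depth, alt_depth)``
pairs.  VCF v4.2 is the on-disk form (pysam writes, cyvcf2 reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

__all__ = ["VariantTable", "read_vcf", "write_vcf", "HOM_REF", "HET", "HOM_ALT", "MISSING"]


@dataclass
class VariantTable:
    """Column-wise store of biallelic SNV records, sorted by (chrom, pos).

    Attributes
    ----------
    chrom, pos, ref, alt, qual
        Per-record arrays; ``pos`` is 1-based.
    samples
        Sample names, one per genotype/AD column.
    gt
        ``(n_variants, n_samples)`` int8 genotype codes.
    ad
        ``(n_variants, n_samples, 2)`` int32 ``(ref_depth, alt_depth)``.
    tol_is_alt
        Optional per-record orientation flag: ``True`` where the
        tolerant-parent allele is the ALT allele.  Set by the
        high-confidence filter and by the simulator's truth.
    contig_lengths
        Optional ``{chrom: length}`` carried through to VCF headers.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    samples: list[str]
    gt: np.ndarray
    ad: np.ndarray
    tol_is_alt: np.ndarray | None = None
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.pos)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.qual = np.asarray(self.qual, dtype=float)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.ad = np.asarray(self.ad, dtype=np.int32)
        if self.gt.shape != (n, len(self.samples)):
            raise ValueError("gt shape does not match records x samples")
        if self.ad.shape != (n, len(self.samples), 2):
            raise ValueError("ad shape does not match records x samples x 2")
        if np.any(self.ad < 0):
            raise ValueError("allele depths must be non-negative")
        if self.tol_is_alt is not None:
            self.tol_is_alt = np.asarray(self.tol_is_alt, dtype=bool)
            if self.tol_is_alt.shape != (n,):
                raise ValueError("tol_is_alt length mismatch")

    @property
    def n_variants(self) -> int:
        return int(self.pos.size)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in table (have {self.samples})") from None

    def subset(self, mask: np.ndarray) -> "VariantTable":
        """Row subset; keeps sample columns and metadata."""
        mask = np.asarray(mask)
        return replace(
            self,
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            qual=self.qual[mask],
            gt=self.gt[mask],
            ad=self.ad[mask],
            tol_is_alt=None if self.tol_is_alt is None else self.tol_is_alt[mask],
        )

    def site_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "qual": self.qual,
            }
        )
        if self.tol_is_alt is not None:
            df["tol_is_alt"] = self.tol_is_alt
        return df


def write_vcf(table: VariantTable, path: str) -> None:
    """Write the table as an uncompressed VCF v4.2 with GT:AD per sample."""
    import pysam

    header = pysam.VariantHeader()
    seen = dict(table.contig_lengths)
    for c in table.chrom:
        seen.setdefault(str(c), None)
    for name, length in seen.items():
        if length:
            header.contigs.add(name, length=length)
        else:
            header.contigs.add(name)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for s in table.samples:
        header.add_sample(s)

    gt_alleles = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for i in range(table.n_variants):
            rec = out.new_record(
                contig=str(table.chrom[i]),
                start=int(table.pos[i]) - 1,
                alleles=(str(table.ref[i]), str(table.alt[i])),
            )
            rec.qual = float(table.qual[i])
            for j, s in enumerate(table.samples):
                rec.samples[s]["GT"] = gt_alleles[int(table.gt[i, j])]
                rec.samples[s]["AD"] = (int(table.ad[i, j, 0]), int(table.ad[i, j, 1]))
            out.write(rec)


def read_vcf(path: str, drop_non_snv: bool = True) -> tuple[VariantTable, dict]:
    """Read a VCF into a :class:`VariantTable`.

    Returns the table and an ingestion report counting records dropped as
    indels/multiallelic (when ``drop_non_snv``) or retained.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)  # gt_types: 0 hom_ref, 1 het, 2 hom_alt, 3 unknown
    samples = list(vcf.samples)
    contig_lengths: dict[str, int] = {}
    for name in vcf.seqnames:
        try:
            contig_lengths[name] = vcf.seqlens[vcf.seqnames.index(name)]
        except (AttributeError, IndexError):  # header without lengths
            pass

    chrom, pos, ref, alt, qual, gts, ads = [], [], [], [], [], [], []
    report = {"records_in": 0, "kept": 0, "dropped_multiallelic": 0, "dropped_indel": 0}
    bases = {"A", "C", "G", "T"}
    for v in vcf:
        report["records_in"] += 1
        if drop_non_snv:
            if len(v.ALT) != 1:
                report["dropped_multiallelic"] += 1
                continue
            if len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.REF not in bases or v.ALT[0] not in bases:
                report["dropped_indel"] += 1
                continue
        report["kept"] += 1
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        qual.append(v.QUAL if v.QUAL is not None else np.nan)
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        gts.append(gt)
        ad = v.format("AD")
        if ad is None:
            ad = np.zeros((len(samples), 2), dtype=np.int32)
        else:
            ad = np.asarray(ad, dtype=np.int32)[:, :2]
            ad[ad < 0] = 0  # cyvcf2 encodes missing AD as negative sentinels
        ads.append(ad)
    vcf.close()

    n = len(pos)
    table = VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        qual=np.array(qual, dtype=float),
        samples=samples,
        gt=np.array(gts, dtype=np.int8).reshape(n, len(samples)),
        ad=np.array(ads, dtype=np.int32).reshape(n, len(samples), 2),
        contig_lengths=contig_lengths,
    )
    return table, report
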