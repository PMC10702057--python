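"""High-confidence variant filtering for the dAF scan.

A raw multi-sample VCF (two parents, the F1, the phenotype pools) is
reduced to population-informative sites: biallelic SNVs where (1) both
parents are homozygous, (2) the parental genotypes contrast, and (3) the
F1 is heterozygous — plus depth/quality guards.  Surviving records carry
an orientation flag saying which allele (ref or alt) came from the
tolerant parent; the scan needs it to sign the dAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from beetmbs.variants import HET, HOM_ALT, HOM_REF, MISSING, VariantTable, read_vcf

__all__ = ["ingest_vcf", "high_confidence_filter", "FilterReport"]

# rejection reasons in evaluation order; each record is counted once under
# its first failing criterion
REASONS = (
    "missing_genotype",
    "parent_not_homozygous",
    "parents_not_contrasting",
    "f1_not_heterozygous",
    "low_parent_depth",
    "low_qual",
)


@dataclass
class FilterReport:
    records_in: int = 0
    records_out: int = 0
    rejections: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REASONS}
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [("records_in", self.records_in), ("records_out", self.records_out)]
        rows += [(f"rejected_{k}", v) for k, v in self.rejections.items()]
        return pd.DataFrame(rows, columns=["metric", "count"])


def ingest_vcf(path: str, required_samples: list[str] | None = None) -> tuple[VariantTable, dict]:
    """Read a VCF keeping biallelic SNVs only.

    ``required_samples`` (e.g. the two parents, F1 and the pools) are
    checked against the header; a missing one is a hard error naming it.
    Returns the table and a count report of dropped indels/multiallelics.
    """
    table, report = read_vcf(path, drop_non_snv=True)
    if required_samples:
        missing = [s for s in required_samples if s not in table.samples]
        if missing:
            raise ValueError(f"required sample(s) missing from {path}: {missing}")
    return table, report


def high_confidence_filter(
    table: VariantTable,
    parent_sus: str,
    parent_tol: str,
    f1: str,
    min_parent_depth: int = 5,
    min_qual: float = 30.0,
) -> tuple[VariantTable, FilterReport]:
    """Keep parent-homozygous, parent-contrasting, F1-heterozygous SNVs.

    Additional guards: no missing genotype among parents/F1, each parent's
    summed allele depth >= ``min_parent_depth``, site QUAL >= ``min_qual``.
    The returned table has ``tol_is_alt`` set: True where the tolerant
    parent is homozygous for the ALT allele.
    """
    i_sus = table.sample_index(parent_sus)
    i_tol = table.sample_index(parent_tol)
    i_f1 = table.sample_index(f1)

    gt_sus = table.gt[:, i_sus]
    gt_tol = table.gt[:, i_tol]
    gt_f1 = table.gt[:, i_f1]

    checks = [
        (
            "missing_genotype",
            (gt_sus == MISSING) | (gt_tol == MISSING) | (gt_f1 == MISSING),
        ),
        (
            "parent_not_homozygous",
            ~np.isin(gt_sus, (HOM_REF, HOM_ALT)) | ~np.isin(gt_tol, (HOM_REF, HOM_ALT)),
        ),
        ("parents_not_contrasting", gt_sus == gt_tol),
        ("f1_not_heterozygous", gt_f1 != HET),
        (
            "low_parent_depth",
            (table.ad[:, i_sus].sum(axis=1) < min_parent_depth)
            | (table.ad[:, i_tol].sum(axis=1) < min_parent_depth),
        ),
        ("low_qual", ~(table.qual >= min_qual)),
    ]

    report = FilterReport(records_in=table.n_variants)
    rejected = np.zeros(table.n_variants, dtype=bool)
    for reason, fails in checks:
        newly = fails & ~rejected
        report.rejections[reason] = int(newly.sum())
        rejected |= newly
    keep = ~rejected
    report.records_out = int(keep.sum())

    out = table.subset(keep)
    out.tol_is_alt = out.gt[:, i_tol] == HOM_ALT
    return out, report
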