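"""Delta-allele-frequency genome scan and trait-interval delimitation.

For every filtered variant the tolerant-allele frequency is computed per
phenotype pool from summed allele depths, and the delta allele frequency
``dAF = AF_tol - AF_sus`` is averaged over tumbling (non-overlapping)
windows of 10 consecutive unmasked SNPs per chromosome.  A candidate
trait interval is every maximal run of at least five consecutive complete
windows whose mean dAF strictly exceeds 0.5 — the "50 SNP" delimitation
rule.  At a monogenic causal locus with perfectly opposite pools the dAF
is ideally 1; linked neutral background decays toward 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from beetmbs.variants import VariantTable

logger = logging.getLogger(__name__)

__all__ = [
    "pool_allele_frequency",
    "per_variant_daf",
    "window_scan",
    "detect_intervals",
    "scan_report",
    "write_intervals_bed",
]


def pool_allele_frequency(
    ad: tuple[int, int] | np.ndarray,
    tol_is_alt: bool | np.ndarray,
    min_depth: int = 10,
) -> float | np.ndarray:
    """Tolerant-allele frequency from an (ref_depth, alt_depth) pair.

    Masked (NaN) when total depth is below ``min_depth``.  Vectorized:
    ``ad`` may be ``(n, 2)`` with a boolean orientation array.
    """
    arr = np.asarray(ad, dtype=float)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    tol_alt = np.atleast_1d(np.asarray(tol_is_alt, dtype=bool))
    total = arr.sum(axis=1)
    tol_depth = np.where(tol_alt, arr[:, 1], arr[:, 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total >= max(min_depth, 1), tol_depth / total, np.nan)
    return float(af[0]) if scalar else af


def _pool_ad(table: VariantTable, sample_names: list[str]) -> np.ndarray:
    """Merge AD over the libraries of one phenotype class."""
    idx = [table.sample_index(s) for s in sample_names]
    return table.ad[:, idx, :].sum(axis=1)


def per_variant_daf(
    table: VariantTable,
    tol_samples: list[str],
    sus_samples: list[str],
    min_depth: int = 10,
) -> pd.DataFrame:
    """Per-variant pool allele frequencies and dAF.

    ``tol_samples`` / ``sus_samples`` list every library of the respective
    phenotype class (individually sequenced extreme lines plus combined
    pools); their allele depths are summed per class before the frequency
    is computed.  Requires ``table.tol_is_alt`` (set by the confidence
    filter).  Records where either pool is below ``min_depth`` carry a
    masked (NaN) dAF.
    """
    if table.tol_is_alt is None:
        raise ValueError("table has no tolerant-allele orientation; run the filter first")
    ad_tol = _pool_ad(table, tol_samples)
    ad_sus = _pool_ad(table, sus_samples)
    af_tol = pool_allele_frequency(ad_tol, table.tol_is_alt, min_depth)
    af_sus = pool_allele_frequency(ad_sus, table.tol_is_alt, min_depth)
    return pd.DataFrame(
        {
            "chrom": table.chrom,
            "pos": table.pos,
            "af_tol": af_tol,
            "af_sus": af_sus,
            "daf": af_tol - af_sus,
            "depth_tol": ad_tol.sum(axis=1),
            "depth_sus": ad_sus.sum(axis=1),
        }
    )


def window_scan(
    dafs: pd.DataFrame, window_size: int = 10, step: int | None = None
) -> pd.DataFrame:
    """Aggregate unmasked variants into per-chromosome SNP-count windows.

    Tumbling windows of exactly ``window_size`` unmasked variants by
    default; a ``step`` smaller than ``window_size`` gives a sliding scan.
    A trailing window with fewer variants is emitted with its true count
    and ``complete=False`` (excluded from interval detection).  Masked
    records do not occupy window slots.

    Returns chrom, index (0-based per chromosome), start_pos, end_pos,
    n_variants, mean_daf, complete.
    """
    if step is None:
        step = window_size
    if not 1 <= step <= window_size:
        raise ValueError("step must be in [1, window_size]")
    rows = []
    for chrom, grp in dafs.groupby("chrom", sort=False):
        ok = grp[grp["daf"].notna()]
        if ok.empty:
            logger.info("chromosome %s has no unmasked variants; no windows", chrom)
            continue
        pos = ok["pos"].to_numpy()
        daf = ok["daf"].to_numpy()
        w = 0
        for start in range(0, len(ok), step):
            chunk = slice(start, start + window_size)
            n = len(daf[chunk])
            if n == 0:
                break
            rows.append(
                {
                    "chrom": chrom,
                    "index": w,
                    "start_pos": int(pos[chunk][0]),
                    "end_pos": int(pos[chunk][-1]),
                    "n_variants": n,
                    "mean_daf": float(daf[chunk].mean()),
                    "complete": n == window_size,
                }
            )
            w += 1
            if n < window_size:
                break
    return pd.DataFrame(
        rows,
        columns=["chrom", "index", "start_pos", "end_pos", "n_variants", "mean_daf", "complete"],
    )


def detect_intervals(
    windows: pd.DataFrame, threshold: float = 0.5, run_min: int = 5
) -> pd.DataFrame:
    """Delimit candidate trait intervals from qualifying window runs.

    A maximal run of >= ``run_min`` consecutive complete windows with
    ``mean_daf > threshold`` (strict) becomes one interval spanning the
    first window's start_pos through the last window's end_pos.

    Returns chrom, start_pos, end_pos, first_window, last_window,
    n_windows, n_snps, max_mean_daf.
    """
    rows = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp[grp["complete"]].sort_values("index")
        if grp.empty:
            continue
        hot = (grp["mean_daf"].to_numpy() > threshold).astype(int)
        # maximal runs of consecutive hot windows
        edges = np.flatnonzero(np.diff(np.concatenate([[0], hot, [0]])))
        for a, b in zip(edges[::2], edges[1::2]):
            if b - a < run_min:
                continue
            run = grp.iloc[a:b]
            rows.append(
                {
                    "chrom": chrom,
                    "start_pos": int(run["start_pos"].iloc[0]),
                    "end_pos": int(run["end_pos"].iloc[-1]),
                    "first_window": int(run["index"].iloc[0]),
                    "last_window": int(run["index"].iloc[-1]),
                    "n_windows": int(len(run)),
                    "n_snps": int(run["n_variants"].sum()),
                    "max_mean_daf": float(run["mean_daf"].max()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start_pos",
            "end_pos",
            "first_window",
            "last_window",
            "n_windows",
            "n_snps",
            "max_mean_daf",
        ],
    )


def scan_report(windows: pd.DataFrame, intervals: pd.DataFrame) -> dict:
    """Genome-wide summary: per-chromosome window stats, global window-mean
    dAF mean/SD over complete windows, the interval list, and a plot-ready
    track of (chrom, window midpoint, mean_daf)."""
    complete = windows[windows["complete"]]
    per_chrom = (
        windows.groupby("chrom", sort=False)
        .agg(
            n_windows=("index", "size"),
            n_complete=("complete", "sum"),
            mean_daf=("mean_daf", "mean"),
            max_daf=("mean_daf", "max"),
        )
        .reset_index()
    )
    track = windows.assign(
        midpoint=((windows["start_pos"] + windows["end_pos"]) // 2)
    )[["chrom", "midpoint", "mean_daf"]]
    return {
        "per_chromosome": per_chrom,
        "global_mean_daf": float(complete["mean_daf"].mean()) if len(complete) else float("nan"),
        "global_sd_daf": float(complete["mean_daf"].std(ddof=1)) if len(complete) > 1 else float("nan"),
        "n_intervals": int(len(intervals)),
        "intervals": intervals,
        "track": track,
    }


def write_intervals_bed(intervals: pd.DataFrame, path: str) -> None:
    """Export intervals as BED (0-based half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": intervals["chrom"],
            "start": intervals["start_pos"] - 1,
            "end": intervals["end_pos"],
            "name": [
                f"interval_{i + 1}_n{int(s)}snps"
                for i, s in enumerate(intervals["n_snps"])
            ],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
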