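"""KASP-style marker candidate design.

Candidates are clean parent-contrasting SNVs (the confidence-filter
predicate), screened by the design rules: not at a known marker position;
no other variant — from a lenient, unfiltered call set — within 50 bp on
either side; less than 65% GC over the 100 bp of flanking sequence (50 bp
per side); per-contig quotas by call quality (up to 1000 per placed
chromosome, up to 4 per unplaced contig); finally a well-distributed
subset per chromosome by greedy max–min spacing.  Rules are applied
cheap-to-expensive and every rejected candidate carries its first failing
reason.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from beetmbs.variants import VariantTable

logger = logging.getLogger(__name__)

__all__ = [
    "clean_variant_set",
    "flank_variant_check",
    "extract_flanks",
    "gc_filter",
    "per_contig_quota",
    "distribute_subset",
    "design_markers",
    "kasp_format",
]

REASONS = ("existing_marker", "flank_variant", "flank_n", "gc_high", "contig_quota")


def clean_variant_set(
    table: VariantTable, existing_markers: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Seed the candidate frame from an already-filtered variant table.

    ``existing_markers`` is an optional frame with chrom, pos (known
    marker positions to exclude).  Returns one row per variant with
    status ``accepted`` or ``rejected`` + reason ``existing_marker``.
    """
    df = pd.DataFrame(
        {
            "chrom": table.chrom,
            "pos": table.pos,
            "ref": table.ref,
            "alt": table.alt,
            "call_quality": table.qual,
        }
    )
    df["status"] = "accepted"
    df["reason"] = ""
    if existing_markers is not None and len(existing_markers):
        known = set(zip(existing_markers["chrom"], existing_markers["pos"]))
        hit = [(c, p) in known for c, p in zip(df["chrom"], df["pos"])]
        df.loc[hit, ["status", "reason"]] = ["rejected", "existing_marker"]
    return df


def flank_variant_check(
    chrom: str,
    pos: int,
    lenient_positions: dict[str, np.ndarray],
    flank_bp: int = 50,
) -> bool:
    """True (pass) iff no lenient-set variant other than the candidate
    itself lies within ``[pos - flank_bp, pos + flank_bp]``."""
    positions = lenient_positions.get(chrom)
    if positions is None or positions.size == 0:
        return True
    lo = np.searchsorted(positions, pos - flank_bp, side="left")
    hi = np.searchsorted(positions, pos + flank_bp, side="right")
    hits = positions[lo:hi]
    return not np.any(hits != pos)


def extract_flanks(fasta, chrom: str, pos: int, flank_bp: int = 50) -> tuple[str, str] | None:
    """50 bp each side of a 1-based position from a pyfaidx Fasta; None if
    the variant sits within flank_bp of a contig end."""
    seq = fasta[chrom]
    if pos - flank_bp < 1 or pos + flank_bp > len(seq):
        return None
    left = seq[pos - 1 - flank_bp : pos - 1].seq.upper()
    right = seq[pos : pos + flank_bp].seq.upper()
    return left, right


def gc_filter(left_flank: str, right_flank: str, max_gc: float = 0.65) -> tuple[bool, float]:
    """GC screen over the concatenated flanks (100 bp total).

    Returns (pass, gc_fraction); pass iff gc_fraction is strictly below
    ``max_gc``.  Flanks containing N are handled by the caller
    (``flank_n`` rejection).
    """
    joint = (left_flank + right_flank).upper()
    gc = (joint.count("G") + joint.count("C")) / len(joint)
    return gc < max_gc, gc


def per_contig_quota(
    candidates: pd.DataFrame,
    max_per_chrom: int = 1000,
    max_per_unplaced: int = 4,
    placed=lambda name: str(name).startswith("chr"),
) -> pd.DataFrame:
    """Truncate accepted candidates per sequence to the applicable quota.

    Within each sequence, candidates are ranked by descending call
    quality (ties: ascending position) and kept up to 1000 on a placed
    chromosome or 4 on an unplaced contig; the rest are rejected with
    reason ``contig_quota``.
    """
    out = candidates.copy()
    for chrom, grp in out[out["status"] == "accepted"].groupby("chrom", sort=False):
        quota = max_per_chrom if placed(chrom) else max_per_unplaced
        if len(grp) <= quota:
            continue
        ranked = grp.sort_values(
            ["call_quality", "pos"], ascending=[False, True], kind="mergesort"
        )
        drop = ranked.index[quota:]
        out.loc[drop, ["status", "reason"]] = ["rejected", "contig_quota"]
    return out


def _max_min_spacing_indices(pos: np.ndarray, k: int) -> list[int]:
    """Indices of the k-subset of sorted positions maximizing the minimum
    adjacent gap (exact, by binary search on the gap)."""

    def picks(gap: int) -> list[int]:
        out, last = [0], pos[0]
        for i in range(1, len(pos)):
            if len(out) == k:
                break
            if pos[i] - last >= gap:
                out.append(i)
                last = pos[i]
        return out

    lo, hi = 0, int(pos[-1] - pos[0])
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if len(picks(mid)) >= k:
            lo = mid
        else:
            hi = mid - 1
    return picks(lo)


def distribute_subset(
    candidates: pd.DataFrame, k_per_chrom: int, chrom_lengths: dict[str, int] | None = None
) -> pd.DataFrame:
    """Max–min-spacing subset of accepted candidates per chromosome.

    Along one chromosome the minimum pairwise spacing of a subset is its
    smallest adjacent gap, so the best-spread k-subset can be found
    exactly: binary-search the largest achievable minimum gap, then select
    positions left to right taking each candidate that is at least that
    gap beyond the previous pick (deterministic; always contains the
    leftmost candidate).  ``k=1`` degenerates to the candidate nearest
    the chromosome midpoint (half the contig length when known, else the
    midpoint of the candidate span).  If fewer than k candidates exist,
    all are returned with a warning.
    """
    chosen = []
    for chrom, grp in candidates[candidates["status"] == "accepted"].groupby(
        "chrom", sort=False
    ):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        if len(grp) <= k_per_chrom:
            if len(grp) < k_per_chrom:
                logger.warning(
                    "%s: only %d candidates for k=%d; returning all",
                    chrom,
                    len(grp),
                    k_per_chrom,
                )
            chosen.append(grp)
            continue
        if k_per_chrom == 1:
            if chrom_lengths and chrom in chrom_lengths:
                mid = chrom_lengths[chrom] / 2
            else:
                mid = (pos[0] + pos[-1]) / 2
            chosen.append(grp.iloc[[int(np.argmin(np.abs(pos - mid)))]])
            continue
        chosen.append(grp.iloc[_max_min_spacing_indices(pos, k_per_chrom)])
    if not chosen:
        return candidates.iloc[0:0].copy()
    return pd.concat(chosen, ignore_index=True)


def design_markers(
    clean: VariantTable,
    lenient: VariantTable,
    fasta,
    existing_markers: pd.DataFrame | None = None,
    flank_bp: int = 50,
    max_gc: float = 0.65,
    max_per_chrom: int = 1000,
    max_per_unplaced: int = 4,
    k_per_chrom: int | None = None,
    placed=lambda name: str(name).startswith("chr"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full candidate screen.

    Parameters
    ----------
    clean
        High-confidence (filtered) variant table — the candidate pool.
    lenient
        Unfiltered SNV table used for the flanking-variant check.
    fasta
        ``pyfaidx.Fasta`` over the reference.
    k_per_chrom
        If given, additionally compute the distributed final panel.

    Returns
    -------
    candidates, panel
        Candidate frame with flanks, gc_fraction, status, reason; and the
        distributed panel (empty frame when ``k_per_chrom`` is None).
    """
    df = clean_variant_set(clean, existing_markers)
    lenient_positions = {
        str(c): np.sort(lenient.pos[lenient.chrom == c])
        for c in pd.unique(lenient.chrom)
    }
    left_col, right_col, gc_col = [], [], []
    for row in df.itertuples():
        left, right, gc = "", "", np.nan
        if row.status == "accepted":
            if not flank_variant_check(row.chrom, row.pos, lenient_positions, flank_bp):
                df.loc[row.Index, ["status", "reason"]] = ["rejected", "flank_variant"]
            else:
                flanks = extract_flanks(fasta, row.chrom, row.pos, flank_bp)
                if flanks is None or "N" in flanks[0] or "N" in flanks[1]:
                    df.loc[row.Index, ["status", "reason"]] = ["rejected", "flank_n"]
                    if flanks is not None:
                        left, right = flanks
                else:
                    left, right = flanks
                    ok, gc = gc_filter(left, right, max_gc)
                    if not ok:
                        df.loc[row.Index, ["status", "reason"]] = ["rejected", "gc_high"]
        left_col.append(left)
        right_col.append(right)
        gc_col.append(gc)
    df["left_flank"] = left_col
    df["right_flank"] = right_col
    df["gc_fraction"] = gc_col
    df = per_contig_quota(df, max_per_chrom, max_per_unplaced, placed)
    if k_per_chrom is not None:
        panel = distribute_subset(
            df, k_per_chrom, chrom_lengths=dict(clean.contig_lengths) or None
        )
    else:
        panel = df.iloc[0:0].copy()
    return df, panel


def kasp_format(row) -> str:
    """KASP submission style: flank[allele1/allele2]flank."""
    return f"{row.left_flank}[{row.ref}/{row.alt}]{row.right_flank}"
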