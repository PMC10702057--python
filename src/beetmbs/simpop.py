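"""Synthetic F2 pool-seq generator.

Emulates the study design the analysis assumes: a biparental F2 of ~406
lines from a single F1, a single additive trait locus with intermediate
heterozygotes, cyst-count phenotypes scored on selfed F3 plants in
randomized incomplete blocks (boxes), extreme phenotype pools, and ~20x
pooled short-read allele-depth sampling emitted as VCF.

Randomness: one root seed; each stage draws from its own independent
stream ``default_rng([seed, STAGE_TAG])`` so changing, say, the phenotype
noise never perturbs the genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from beetmbs.genmap import GeneticMap
from beetmbs.variants import HET, HOM_ALT, HOM_REF, MISSING, VariantTable

logger = logging.getLogger(__name__)

# sample naming convention of the emitted VCF
PARENT_SUS, PARENT_TOL, F1, POOL_SUS, POOL_TOL = (
    "parent_S",
    "parent_T",
    "F1",
    "pool_sus",
    "pool_tol",
)

# per-stage RNG stream tags (arbitrary distinct constants)
_STAGES = {"meiosis": 1, "phenotype": 2, "blocks": 3, "reads": 4, "sites": 5, "reference": 6}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one simulation stage of one root seed."""
    return np.random.default_rng([int(seed), _STAGES[stage]])


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults reproduce the mapping design at desk scale: 406 F2 lines with
    10 phenotyped F3 plants each, extreme pools of 20 tolerant and 16
    susceptible lines, ~20x pooled coverage.  ``baseline_mean`` is the mean
    cyst count of the susceptible homozygote; each dose of the tolerant
    allele subtracts ``effect`` cysts, so heterozygotes are exactly
    intermediate (purely additive locus, no dominance).

    dispersion
        Negative-binomial overdispersion (variance = mu + mu^2/dispersion);
        ``inf`` gives the Poisson limit.
    error_rate
        Per-read probability of reading the other allele.
    block_sd
        SD of box (incomplete block) effects on the transformed SN scale.
    decoy_fraction
        Fraction of map sites that are NOT parent-contrasting (monomorphic
        or heterozygous-parent sites) — fodder for the confidence filter.
    """

    n_lines: int = 406
    plants_per_line: int = 10
    causal: tuple[str, int] | None = None
    effect: float = 30.0
    baseline_mean: float = 85.0
    dispersion: float = 5.0
    coverage: float = 20.0
    error_rate: float = 0.002
    seed: int = 0
    block_size: int = 120
    block_sd: float = 0.5
    decoy_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ConfigError("n_lines must be >= 1")
        if self.effect < 0:
            raise ConfigError("effect must be >= 0")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be > 0")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.coverage <= 0:
            raise ConfigError("coverage must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")

    def validate_against(self, gmap: GeneticMap) -> None:
        """Check that a configured causal locus is a variant on the map."""
        if self.causal is not None:
            try:
                gmap.variant_index(*self.causal)
            except ValueError as e:
                raise ConfigError(str(e)) from None


@dataclass
class GenotypeMatrix:
    """Per-line dosage of the tolerant-parent allele at every map variant."""

    line_ids: list[str]
    dosage: np.ndarray  # (n_lines, n_variants) int8 in {0,1,2}
    gmap: GeneticMap

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.line_ids), self.gmap.n_variants):
            raise ValueError("dosage shape mismatch")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def causal_dosage(self, causal: tuple[str, int]) -> np.ndarray:
        return self.dosage[:, self.gmap.variant_index(*causal)]


def simulate_f2(gmap: GeneticMap, config: SimConfig) -> GenotypeMatrix:
    """Simulate F2 lines as fusions of two independent F1 gametes.

    Gametes are generated chromosome by chromosome: the allele at the
    first variant is a fair coin, and crossovers between adjacent variants
    occur with the Haldane recombination fraction
    ``r = (1 - exp(-2 d_cM / 100)) / 2`` (no interference).
    """
    config.validate_against(gmap)
    rng = stage_rng(config.seed, "meiosis")
    n = config.n_lines
    blocks = []
    for c in gmap.chromosomes:
        m = c.n_variants
        if m == 0:
            continue
        start = rng.random((2 * n, 1)) < 0.5
        if m > 1:
            d = np.diff(c.cm)
            r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
            switch = rng.random((2 * n, m - 1)) < r
            parity = np.concatenate(
                [np.zeros((2 * n, 1), dtype=np.int64), np.cumsum(switch, axis=1)], axis=1
            )
            hap = (start.astype(np.int64) + parity) % 2
        else:
            hap = start.astype(np.int64)
        blocks.append((hap[0::2] + hap[1::2]).astype(np.int8))
    dosage = np.concatenate(blocks, axis=1) if blocks else np.zeros((n, 0), dtype=np.int8)
    width = max(3, len(str(n)))
    line_ids = [f"L{idx + 1:0{width}d}" for idx in range(n)]
    return GenotypeMatrix(line_ids=line_ids, dosage=dosage, gmap=gmap)


def assign_blocks(
    line_ids: list[str], plants_per_line: int, block_size: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Randomize plants (plants_per_line per line) into boxes of block_size.

    Returns a frame with plant_id, line_id, block_id — the incomplete-block
    layout the greenhouse design implies.
    """
    plants = [(f"{lid}_p{k + 1}", lid) for lid in line_ids for k in range(plants_per_line)]
    order = rng.permutation(len(plants))
    rows = []
    for slot, idx in enumerate(order):
        pid, lid = plants[idx]
        rows.append((pid, lid, f"box{slot // block_size + 1:03d}"))
    return pd.DataFrame(rows, columns=["plant_id", "line_id", "block_id"]).sort_values(
        ["line_id", "plant_id"], ignore_index=True
    )


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimConfig, blocks: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Draw per-plant cyst counts under the additive single-locus model.

    Genetic mean per line is ``max(0, baseline_mean - effect * dosage)``
    at the causal locus (or ``baseline_mean`` for a null simulation).  Box
    effects are additive on the SN scale ``sqrt(mu + 3/8)`` and
    back-transformed, then counts are negative-binomial with the configured
    dispersion (Poisson when dispersion is infinite).
    """
    rng = stage_rng(config.seed, "phenotype")
    if blocks is None:
        blocks = assign_blocks(
            genotypes.line_ids,
            config.plants_per_line,
            config.block_size,
            stage_rng(config.seed, "blocks"),
        )
    if config.causal is not None:
        dose = genotypes.causal_dosage(config.causal).astype(float)
    else:
        dose = np.zeros(genotypes.n_lines)
    mu_line = np.maximum(0.0, config.baseline_mean - config.effect * dose)
    line_mu = dict(zip(genotypes.line_ids, mu_line))

    block_ids = sorted(blocks["block_id"].unique())
    eff = rng.normal(0.0, config.block_sd, size=len(block_ids))
    eff -= eff.mean()  # identifiable: block effects sum to zero
    block_eff = dict(zip(block_ids, eff))

    mu_g = blocks["line_id"].map(line_mu).to_numpy(float)
    sn_mean = np.sqrt(mu_g + 0.375) + blocks["block_id"].map(block_eff).to_numpy(float)
    clamped = sn_mean < 0
    if clamped.any():
        logger.info("clamped %d negative plant means to zero", int(clamped.sum()))
    mu = np.maximum(0.0, sn_mean) ** 2 - 0.375
    mu = np.maximum(0.0, mu)

    if np.isinf(config.dispersion):
        counts = rng.poisson(mu)
    else:
        k = config.dispersion
        p = k / (k + np.maximum(mu, 1e-12))
        counts = np.where(mu > 0, rng.negative_binomial(k, p), 0)
    out = blocks.copy()
    out["cysts"] = counts.astype(np.int64)
    return out


def site_truth(gmap: GeneticMap, config: SimConfig) -> pd.DataFrame:
    """Per-variant ground truth of the emitted VCF.

    Columns: chrom, pos, informative (parent-contrasting site that should
    survive the confidence filter), site_class (contrasting |
    monomorphic | het_parent), tol_is_alt (orientation at informative
    sites), is_causal.
    """
    rng = stage_rng(config.seed, "sites")
    df = gmap.variant_frame()[["chrom", "pos"]].copy()
    nv = len(df)
    u = rng.random(nv)
    cls = np.where(
        u >= config.decoy_fraction,
        "contrasting",
        np.where(u < config.decoy_fraction / 2, "monomorphic", "het_parent"),
    )
    tol_is_alt = rng.random(nv) < 0.5
    df["site_class"] = cls
    df["informative"] = cls == "contrasting"
    df["tol_is_alt"] = np.where(df["informative"], tol_is_alt, False)
    df["is_causal"] = False
    if config.causal is not None:
        i = gmap.variant_index(*config.causal)
        df.loc[i, ["site_class", "informative"]] = ["contrasting", True]
        df.loc[i, "tol_is_alt"] = bool(tol_is_alt[i])
        df.loc[i, "is_causal"] = True
    return df


def reference_sequences(gmap: GeneticMap, seed: int) -> dict[str, np.ndarray]:
    """Deterministic random reference, one byte array of ACGT per chromosome."""
    rng = stage_rng(seed, "reference")
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    return {
        c.name: alphabet[rng.integers(0, 4, size=c.length_bp)] for c in gmap.chromosomes
    }


def write_reference_fasta(gmap: GeneticMap, seed: int, path: str, width: int = 70) -> None:
    seqs = reference_sequences(gmap, seed)
    with open(path, "w") as fh:
        for name, arr in seqs.items():
            fh.write(f">{name}\n")
            s = arr.tobytes().decode("ascii")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def simulate_pool_reads(
    genotypes: GenotypeMatrix,
    pools: tuple[list[str], list[str]],
    config: SimConfig,
    truth: pd.DataFrame | None = None,
) -> VariantTable:
    """Sample pooled allele depths and emit a five-sample variant table.

    Samples: parent_S, parent_T, F1 (fixed genotypes with sampled depths)
    and pool_sus, pool_tol (genotype missing; AD carries the signal).
    Per variant and sample, depth ~ Poisson(coverage) and alt reads ~
    Binomial(depth, q') where q is the true alt-allele frequency of that
    sample and ``q' = q (1-e) + (1-q) e`` mixes in the per-read error
    rate.  Depth 0 is recorded as AD=(0,0).
    """
    tol_ids, sus_ids = pools
    if not tol_ids or not sus_ids:
        raise ValueError("pools must be non-empty")
    if set(tol_ids) & set(sus_ids):
        raise ValueError("pools must be disjoint")
    idx = {lid: i for i, lid in enumerate(genotypes.line_ids)}
    missing = [l for l in list(tol_ids) + list(sus_ids) if l not in idx]
    if missing:
        raise ValueError(f"pool lines not in genotype matrix: {missing[:5]}")

    gmap = genotypes.gmap
    if truth is None:
        truth = site_truth(gmap, config)
    nv = gmap.n_variants
    rng = stage_rng(config.seed, "reads")

    informative = truth["informative"].to_numpy()
    tol_is_alt = truth["tol_is_alt"].to_numpy()
    cls = truth["site_class"].to_numpy()

    # mean tolerant-allele dosage per pool, converted to ALT-allele frequency
    mean_tol = {
        "tol": genotypes.dosage[[idx[l] for l in tol_ids]].mean(axis=0) / 2.0,
        "sus": genotypes.dosage[[idx[l] for l in sus_ids]].mean(axis=0) / 2.0,
    }

    def alt_freq(sample: str) -> np.ndarray:
        q = np.zeros(nv)
        if sample in ("pool_tol", "pool_sus"):
            q_tol = mean_tol["tol" if sample == "pool_tol" else "sus"]
            q[informative] = np.where(
                tol_is_alt[informative], q_tol[informative], 1.0 - q_tol[informative]
            )
            q[cls == "het_parent"] = 0.25  # one het parent segregates 1:1 gametes
        elif sample == PARENT_TOL:
            q[informative & tol_is_alt] = 1.0
            q[cls == "het_parent"] = 0.5
        elif sample == PARENT_SUS:
            q[informative & ~tol_is_alt] = 1.0
        elif sample == F1:
            q[informative] = 0.5
            q[cls == "het_parent"] = 0.25
        return q

    def truth_gt(sample: str) -> np.ndarray:
        g = np.full(nv, HOM_REF, dtype=np.int8)
        if sample in ("pool_tol", "pool_sus"):
            return np.full(nv, MISSING, dtype=np.int8)
        if sample == PARENT_TOL:
            g[informative & tol_is_alt] = HOM_ALT
            g[cls == "het_parent"] = HET
        elif sample == PARENT_SUS:
            g[informative & ~tol_is_alt] = HOM_ALT
        elif sample == F1:
            g[informative] = HET
            g[cls == "het_parent"] = HET
        return g

    samples = [PARENT_SUS, PARENT_TOL, F1, POOL_SUS, POOL_TOL]
    gt = np.stack([truth_gt(s) for s in samples], axis=1)
    ad = np.zeros((nv, len(samples), 2), dtype=np.int32)
    e = config.error_rate
    for j, s in enumerate(samples):
        depth = rng.poisson(config.coverage, size=nv)
        q = alt_freq(s)
        q_obs = q * (1.0 - e) + (1.0 - q) * e
        alt = rng.binomial(depth, q_obs)
        ad[:, j, 0] = depth - alt
        ad[:, j, 1] = alt

    seqs = reference_sequences(gmap, config.seed)
    ref_bases, alt_bases = [], []
    order = "ACGT"
    alt_pick = rng.integers(0, 3, size=nv)
    i = 0
    for c in gmap.chromosomes:
        seq = seqs[c.name]
        for p in c.positions:
            r = seq[p - 1].decode("ascii")
            alts = [b for b in order if b != r]
            ref_bases.append(r)
            alt_bases.append(alts[alt_pick[i]])
            i += 1

    qual = rng.uniform(200.0, 2000.0, size=nv)
    frame = gmap.variant_frame()
    return VariantTable(
        chrom=frame["chrom"].to_numpy(object),
        pos=frame["pos"].to_numpy(np.int64),
        ref=np.array(ref_bases, dtype=object),
        alt=np.array(alt_bases, dtype=object),
        qual=qual,
        samples=samples,
        gt=gt,
        ad=ad,
        tol_is_alt=tol_is_alt.copy(),
        contig_lengths={c.name: c.length_bp for c in gmap.chromosomes},
    )


def write_truth(truth: pd.DataFrame, config: SimConfig, path: str) -> None:
    """Write the per-site truth plus causal locus / effect metadata as TSV."""
    df = truth.copy()
    df["causal_effect"] = np.where(df["is_causal"], config.effect, 0.0)
    df.to_csv(path, sep="\t", index=False)
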