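"""Genetic map container: physical (bp) and genetic (cM) marker coordinates.

A :class:`GeneticMap` lists, per chromosome, the variant positions that
segregate in the cross together with their genetic-map positions.  It is
the shared coordinate system of the simulator and the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ChromosomeMap", "GeneticMap", "beet_like_map"]


@dataclass(frozen=True)
class ChromosomeMap:
    """Variant coordinates of one chromosome.

    Parameters
    ----------
    name
        Chromosome (or contig) identifier, e.g. ``"chr5"``.
    length_bp
        Physical length in base pairs.
    positions
        Strictly increasing 1-based variant positions (bp).
    cm
        Non-decreasing genetic positions (cM), one per variant.
    """

    name: str
    length_bp: int
    positions: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "cm", cm)
        if pos.shape != cm.shape:
            raise ValueError(f"{self.name}: positions and cm differ in length")
        if pos.size and (pos[0] < 1 or pos[-1] > self.length_bp):
            raise ValueError(f"{self.name}: variant positions outside [1, length_bp]")
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"{self.name}: positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"{self.name}: cM positions must be non-decreasing")
        if np.any(cm < 0):
            raise ValueError(f"{self.name}: cM positions must be non-negative")

    @property
    def n_variants(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class GeneticMap:
    """An ordered collection of :class:`ChromosomeMap` objects."""

    chromosomes: tuple[ChromosomeMap, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        chroms = tuple(self.chromosomes)
        names = [c.name for c in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "_index", {c.name: c for c in chroms})

    @property
    def n_variants(self) -> int:
        return sum(c.n_variants for c in self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> ChromosomeMap:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not on map") from None

    def variant_index(self, chrom: str, pos: int) -> int:
        """Global 0-based index of the variant at (chrom, pos).

        Raises ``ValueError`` if the position is not a variant of the map —
        used to validate a configured causal locus.
        """
        offset = 0
        for c in self.chromosomes:
            if c.name == chrom:
                i = int(np.searchsorted(c.positions, pos))
                if i < c.n_variants and c.positions[i] == pos:
                    return offset + i
                raise ValueError(f"no variant at {chrom}:{pos} on the map")
            offset += c.n_variants
        raise ValueError(f"chromosome {chrom!r} not on map")

    def variant_frame(self) -> pd.DataFrame:
        """All variants as a DataFrame with columns chrom, pos, cm."""
        parts = [
            pd.DataFrame({"chrom": c.name, "pos": c.positions, "cm": c.cm})
            for c in self.chromosomes
        ]
        return pd.concat(parts, ignore_index=True)


def beet_like_map(
    n_chromosomes: int = 9,
    variants_per_chromosome: int = 225,
    chrom_length_bp: int = 1_000_000,
    chrom_length_cm: float = 80.0,
    seed: int = 0,
) -> GeneticMap:
    """Random map shaped like a nine-chromosome beet genome at desk scale.

    Defaults give ~2,000 mapped variants spread over nine chromosomes.
    Genetic positions are proportional to physical positions (uniform
    recombination rate), which is adequate for method testing.
    """
    rng = np.random.default_rng([seed, 0x6D61])  # stream tag "ma(p)"
    chroms = []
    for i in range(n_chromosomes):
        # keep 60 bp clear of both ends so 50 bp marker flanks always exist
        lo, hi = 61, chrom_length_bp - 60
        pos = np.sort(
            rng.choice(hi - lo, size=variants_per_chromosome, replace=False) + lo
        ).astype(np.int64)
        cm = pos / chrom_length_bp * chrom_length_cm
        chroms.append(
            ChromosomeMap(
                name=f"chr{i + 1}", length_bp=chrom_length_bp, positions=pos, cm=cm
            )
        )
    return GeneticMap(tuple(chroms))
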