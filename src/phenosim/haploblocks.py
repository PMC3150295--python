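"""Four-gamete compatibility and haploblock partition.

Two biallelic sites are compatible with a single genealogy without
recombination iff at most three of the four gametes 00/01/10/11 are observed
among the sampled chromosomes (the four-gamete test).  Haploblocks are
maximal runs of mutually compatible sites, built greedily left to right: a
site joins the current block only if it is compatible with EVERY site already
in the block, otherwise it starts a new block.  The blocks tile the site
range without gap or overlap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_coalescent import HaplotypeMatrix

__all__ = ["Haploblock", "four_gamete_compatible", "find_haploblocks"]


@dataclass(frozen=True)
class Haploblock:
    """Contiguous block of sites [start_site, end_site], both 0-based inclusive."""

    start_site: int
    end_site: int

    def __post_init__(self) -> None:
        if self.start_site > self.end_site:
            raise ValueError("start_site must not exceed end_site")

    def __contains__(self, site: int) -> bool:
        return self.start_site <= site <= self.end_site

    def sites(self) -> range:
        return range(self.start_site, self.end_site + 1)


def four_gamete_compatible(m: HaplotypeMatrix, site_a: int, site_b: int) -> bool:
    """True iff fewer than four distinct gametes occur at the two sites."""
    n = m.n_sites
    for s in (site_a, site_b):
        if not (0 <= s < n):
            raise IndexError(f"site index {s} out of range for {n} sites")
    gametes = m.alleles[:, site_a] * 2 + m.alleles[:, site_b]
    return len(np.unique(gametes)) < 4


def find_haploblocks(m: HaplotypeMatrix) -> list[Haploblock]:
    """Greedy left-to-right partition into maximal four-gamete-compatible blocks."""
    n = m.n_sites
    if n == 0:
        return []
    blocks: list[Haploblock] = []
    start = 0
    for site in range(1, n):
        # all-pairs rule: candidate must be compatible with every block member
        if all(four_gamete_compatible(m, prev, site) for prev in range(start, site)):
            continue
        blocks.append(Haploblock(start, site - 1))
        start = site
    blocks.append(Haploblock(start, n - 1))
    return blocks
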