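"""Diploid pairing, case/control ascertainment and subsampling.

Coalescent simulators emit haploid chromosomes; diploid individuals are
formed by pairing consecutive chromosomes.  After phenotypes are assigned to
the full simulated population, a study sample is drawn from it: optionally
the causal markers are removed (the causal mutation is frequently not
genotyped), a fixed number of markers is kept, and individuals are either
subsampled uniformly or ascertained to reach a minimum case count — the way
real case/control studies recruit from a larger population.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import INDIVIDUALS, MARKERS, substream
from .errors import AscertainmentError, PairingError, SamplingError, ValidationError
from .io_coalescent import HaplotypeMatrix
from .phenotypes import GenotypeMatrix, Matrix, PhenotypeVector, QTNSpec

__all__ = ["SamplePlan", "pair_diploids", "ascertain_case_control", "subsample"]


@dataclass
class SamplePlan:
    """What to keep from the simulated population.

    ``min_cases`` triggers case/control ascertainment; ``n_controls`` caps
    the controls (when unset, all remaining individuals up to
    ``n_individuals`` serve as controls).
    """

    n_markers: int | None = None
    n_individuals: int | None = None
    remove_causal: bool = False
    min_cases: int | None = None
    n_controls: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_markers", "n_individuals", "min_cases", "n_controls"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValidationError(f"{name} must be positive when given")


def pair_diploids(m: HaplotypeMatrix) -> GenotypeMatrix:
    """Form diploid individuals from chromosome pairs (2i, 2i+1).

    The genotype code is the derived-allele count minus one, giving
    -1 / 0 / +1 for homozygous ancestral / heterozygous / homozygous derived.
    """
    if m.n_chromosomes % 2:
        raise PairingError(
            f"cannot pair an odd number of chromosomes ({m.n_chromosomes})"
        )
    codes = m.alleles[0::2].astype(np.int8) + m.alleles[1::2].astype(np.int8) - 1
    return GenotypeMatrix(
        codes,
        m.positions,
        position_unit=m.position_unit,
        locus_length_bp=m.locus_length_bp,
    )


def ascertain_case_control(statuses: PhenotypeVector, plan: SamplePlan) -> np.ndarray:
    """Select case and control indices from a larger simulated population.

    Draws ``plan.min_cases`` cases uniformly without replacement, then
    controls: ``plan.n_controls`` of them if set, otherwise all remaining
    controls (capped so the total honors ``plan.n_individuals``).  Indices
    are returned sorted ascending.
    """
    if statuses.kind != "case_control":
        raise ValidationError("ascertainment requires a case/control phenotype")
    if plan.min_cases is None:
        raise ValidationError("plan.min_cases must be set for ascertainment")
    cases = np.flatnonzero(statuses.values == 1)
    controls = np.flatnonzero(statuses.values == 0)
    if len(cases) < plan.min_cases:
        raise AscertainmentError(
            f"only {len(cases)} cases in the simulated population, "
            f"{plan.min_cases} requested — simulate a larger population",
            available=len(cases),
        )
    rng = substream(plan.seed, INDIVIDUALS)
    picked_cases = rng.choice(cases, size=plan.min_cases, replace=False)

    if plan.n_controls is not None:
        n_ctrl = plan.n_controls
    elif plan.n_individuals is not None:
        n_ctrl = plan.n_individuals - plan.min_cases
        if n_ctrl < 0:
            raise ValidationError("n_individuals is smaller than min_cases")
    else:
        n_ctrl = len(controls)
    if len(controls) < n_ctrl:
        raise AscertainmentError(
            f"only {len(controls)} controls in the simulated population, "
            f"{n_ctrl} requested — simulate a larger population",
            available=len(controls),
        )
    picked_controls = (
        controls if n_ctrl == len(controls)
        else rng.choice(controls, size=n_ctrl, replace=False)
    )
    return np.sort(np.concatenate([picked_cases, picked_controls]))


def subsample(
    m: Matrix,
    phen: PhenotypeVector,
    qtns: Sequence[QTNSpec],
    plan: SamplePlan,
) -> tuple[Matrix, PhenotypeVector, list[int]]:
    """Draw the study sample: causal removal, marker subset, individual subset.

    Order of operations (fixed): causal columns are deleted first when
    ``plan.remove_causal``; then ``plan.n_markers`` columns are drawn
    uniformly without replacement and re-sorted by position; finally
    individuals are ascertained (``min_cases`` set, case/control phenotype)
    or drawn uniformly (``n_individuals``).  Genotype-phenotype pairing is
    preserved throughout.  Returns the sampled matrix, the matching
    phenotypes and the remapped column indices of any retained causal sites
    (empty when they were removed or not sampled).
    """
    n_rows = m.n_chromosomes if isinstance(m, HaplotypeMatrix) else m.n_individuals
    if len(phen) != n_rows:
        raise ValidationError("phenotype length does not match the matrix")

    qtn_sites = np.array(sorted({q.site for q in qtns}), dtype=np.intp)
    all_cols = np.arange(m.n_sites)
    keep = np.setdiff1d(all_cols, qtn_sites) if plan.remove_causal else all_cols

    if plan.n_markers is not None:
        if plan.n_markers > len(keep):
            raise SamplingError(
                f"{plan.n_markers} markers requested but only {len(keep)} "
                f"available{' after causal removal' if plan.remove_causal else ''}"
            )
        rng = substream(plan.seed, MARKERS)
        keep = np.sort(rng.choice(keep, size=plan.n_markers, replace=False))

    matrix = m.take_sites(keep)
    remapped = [
        int(np.searchsorted(keep, s)) for s in qtn_sites if s in set(keep.tolist())
    ]

    if plan.min_cases is not None and phen.kind == "case_control":
        rows = ascertain_case_control(phen, plan)
    elif plan.n_individuals is not None:
        if plan.n_individuals > n_rows:
            raise SamplingError(
                f"{plan.n_individuals} individuals requested but only {n_rows} simulated"
            )
        rng = substream(plan.seed, INDIVIDUALS)
        rows = np.sort(rng.choice(n_rows, size=plan.n_individuals, replace=False))
    else:
        rows = np.arange(n_rows)

    return matrix.take_individuals(rows), phen.take(rows), remapped
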