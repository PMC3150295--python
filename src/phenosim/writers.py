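"""Serialization into GWAS-tool input formats.

Supported: PLINK PED/MAP, transposed PLINK TPED/TFAM (the dialect EMMAX
consumes), EMMA plain genotype/phenotype matrices, and a generic TSV pair.
All writers are byte-deterministic for a fixed input (LF line endings, no
timestamps) and conserve per-marker derived-allele counts.

Alleles are written as A (ancestral) / T (derived): coalescent output has no
nucleotide identities, so the letters are arbitrary but fixed.  Case/control
phenotypes use the PLINK convention 1 = control, 2 = case; quantitative
values are printed at full precision.  The chromosome field is fixed to 1 —
each replicate simulates a single locus.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io_coalescent import HaplotypeMatrix
from .phenotypes import GenotypeMatrix, Matrix, PhenotypeVector

__all__ = [
    "Dataset",
    "write_plink_ped_map",
    "write_tped_tfam",
    "write_emma",
    "write_tsv",
]


def _fmt(v: float) -> str:
    # repr is the shortest decimal that round-trips the double exactly
    return repr(float(v))


@dataclass
class Dataset:
    """Genotypes + phenotypes + naming, ready for export."""

    genotypes: Matrix
    phenotypes: PhenotypeVector
    positions_bp: np.ndarray
    marker_ids: list[str]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        g = self.genotypes
        n_ind = g.n_chromosomes if isinstance(g, HaplotypeMatrix) else g.n_individuals
        if len(self.phenotypes) != n_ind or len(self.individual_ids) != n_ind:
            raise ValidationError("phenotype / individual-id lengths do not match genotypes")
        if len(self.marker_ids) != g.n_sites or len(self.positions_bp) != g.n_sites:
            raise ValidationError("marker-id / position lengths do not match genotypes")
        if len(self.positions_bp) > 1 and np.any(np.diff(self.positions_bp) <= 0):
            raise ValidationError("base-pair positions must be strictly increasing")
        if self.phenotypes.kind == "quantitative" and not np.isfinite(
            self.phenotypes.values
        ).all():
            raise ValidationError("phenotypes must be finite (no NaN/inf)")

    @classmethod
    def from_matrix(
        cls,
        genotypes: Matrix,
        phenotypes: PhenotypeVector,
        locus_length_bp: int | None = None,
    ) -> "Dataset":
        """Build with generated ids (snp1.., ind1..) and bp-converted positions."""
        g = genotypes
        n_ind = g.n_chromosomes if isinstance(g, HaplotypeMatrix) else g.n_individuals
        return cls(
            genotypes=g,
            phenotypes=phenotypes,
            positions_bp=g.positions_bp(locus_length_bp),
            marker_ids=[f"snp{j + 1}" for j in range(g.n_sites)],
            individual_ids=[f"ind{i + 1}" for i in range(n_ind)],
        )

    @property
    def is_diploid(self) -> bool:
        return isinstance(self.genotypes, GenotypeMatrix)

    def _phenotype_strings(self) -> list[str]:
        if self.phenotypes.kind == "case_control":
            return [str(int(v) + 1) for v in self.phenotypes.values]  # 1=control, 2=case
        return [_fmt(v) for v in self.phenotypes.values]

    def _allele_pairs(self) -> np.ndarray:
        """(n_individuals, n_markers) array of 'X Y' allele-pair strings."""
        if self.is_diploid:
            codes = self.genotypes.codes
        else:
            warnings.warn(
                "haploid genotypes written as homozygous diploids", stacklevel=3
            )
            codes = self.genotypes.alleles.astype(np.int8) * 2 - 1  # 0->-1, 1->+1
        lookup = np.array(["A A", "A T", "T T"])
        return lookup[codes + 1]


def _write_lines(path: Path, lines: Sequence[str]) -> Path:
    with open(path, "w", newline="\n") as fh:
        for line in lines:
            fh.write(line + "\n")
    return path


def write_plink_ped_map(d: Dataset, out_prefix: str | Path) -> list[Path]:
    """PLINK .ped/.map pair.

    ``.map``: chromosome 1, marker id, genetic distance 0, bp.
    ``.ped``: FID IID PID MID sex phenotype, then two allele columns per
    marker.  Each simulated individual is its own family (FID = IID).
    """
    prefix = Path(out_prefix)
    map_lines = [
        f"1\t{mid}\t0\t{bp}" for mid, bp in zip(d.marker_ids, d.positions_bp)
    ]
    pairs = d._allele_pairs()
    phen = d._phenotype_strings()
    ped_lines = []
    for i, iid in enumerate(d.individual_ids):
        fields = [iid, iid, "0", "0", "0", phen[i]]
        fields.extend(pairs[i])
        ped_lines.append("\t".join(fields))
    return [
        _write_lines(Path(str(prefix) + ".ped"), ped_lines),
        _write_lines(Path(str(prefix) + ".map"), map_lines),
    ]


def write_tped_tfam(d: Dataset, out_prefix: str | Path) -> list[Path]:
    """Transposed PLINK .tped/.tfam pair (the layout EMMAX reads).

    ``.tped``: chromosome 1, marker id, 0, bp, then two alleles per
    individual; ``.tfam``: FID IID 0 0 0 phenotype.
    """
    prefix = Path(out_prefix)
    pairs = d._allele_pairs()
    tped_lines = []
    for j, (mid, bp) in enumerate(zip(d.marker_ids, d.positions_bp)):
        fields = ["1", mid, "0", str(bp)]
        fields.extend(pairs[:, j])
        tped_lines.append("\t".join(fields))
    phen = d._phenotype_strings()
    tfam_lines = [
        f"{iid}\t{iid}\t0\t0\t0\t{phen[i]}" for i, iid in enumerate(d.individual_ids)
    ]
    return [
        _write_lines(Path(str(prefix) + ".tped"), tped_lines),
        _write_lines(Path(str(prefix) + ".tfam"), tfam_lines),
    ]


def write_emma(d: Dataset, out_prefix: str | Path) -> list[Path]:
    """EMMA plain matrices: markers x individuals genotypes, one-row phenotypes.

    Diploid codes map to derived-allele dosage fractions {0, 0.5, 1};
    haploid alleles stay {0, 1}.
    """
    prefix = Path(out_prefix)
    if d.is_diploid:
        values = (d.genotypes.codes + 1) / 2.0
        cell = {0.0: "0", 0.5: "0.5", 1.0: "1"}
        geno_lines = [
            "\t".join(cell[v] for v in values[:, j]) for j in range(d.genotypes.n_sites)
        ]
    else:
        alleles = d.genotypes.alleles
        geno_lines = [
            "\t".join(str(int(v)) for v in alleles[:, j])
            for j in range(d.genotypes.n_sites)
        ]
    pheno_line = "\t".join(d._phenotype_strings())
    geno_path = Path(str(prefix) + ".emma.geno")
    pheno_path = Path(str(prefix) + ".emma.pheno")
    return [
        _write_lines(geno_path, geno_lines),
        _write_lines(pheno_path, [pheno_line]),
    ]


def write_tsv(d: Dataset, out_prefix: str | Path) -> list[Path]:
    """Generic TSV pair for interchange and round-trip testing.

    Genotype columns are headed ``<marker_id>:<bp>``; cells carry the raw
    codes (0/1 haploid, -1/0/+1 diploid).  The phenotype file has
    ``individual_id`` and ``phenotype`` columns.
    """
    prefix = Path(out_prefix)
    header = "individual_id\t" + "\t".join(
        f"{mid}:{bp}" for mid, bp in zip(d.marker_ids, d.positions_bp)
    )
    if d.is_diploid:
        rows = d.genotypes.codes
    else:
        rows = d.genotypes.alleles
    geno_lines = [header]
    for i, iid in enumerate(d.individual_ids):
        geno_lines.append(iid + "\t" + "\t".join(str(int(v)) for v in rows[i]))
    phen = d._phenotype_strings()
    pheno_lines = ["individual_id\tphenotype"]
    pheno_lines.extend(
        f"{iid}\t{phen[i]}" for i, iid in enumerate(d.individual_ids)
    )
    return [
        _write_lines(Path(str(prefix) + ".genotypes.tsv"), geno_lines),
        _write_lines(Path(str(prefix) + ".phenotypes.tsv"), pheno_lines),
    ]


WRITERS = {
    "ped": write_plink_ped_map,
    "tped": write_tped_tfam,
    "emma": write_emma,
    "tsv": write_tsv,
}
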