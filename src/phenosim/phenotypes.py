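"""Causal-site selection and phenotype generation.

Quantitative traits
-------------------
Each quantitative trait nucleotide (QTN) *j* is assigned a variance
proportion pi_j; the sum of all effects (plus any epistatic effect pi_E)
equals the trait heritability h^2 < 1.  Individual *i*'s trait value is

    Y_i = sum_j beta_j * g_ij  (+ beta_E * a_iE)  + eps_i,   eps_i ~ N(0, 1)

where g_ij is the genotype coding at QTN j — the 0/1 allelic state a_ij for
haploids, the {-1, 0, +1} code Q_ij for diploids under additivity, or the
dominance recoding (0 for homozygous ancestral, 1 otherwise) for diploids
with dominant QTNs.  The coefficient

    beta_j = sqrt( pi_j / ( v_j * (1 - h^2) ) )

with v_j the variance of the coding (f(1-f) for 0/1 codings at realized
frequency f, 2 f (1-f) for the diploid {-1,0,+1} coding under random
pairing) makes QTN j contribute the proportion pi_j of total phenotypic
variance when QTNs are independent and noise is standard normal.

Epistasis between exactly two QTNs is modeled as a fictive third QTN whose
allelic state is 1 iff the individual carries at least one derived allele at
both basal QTNs; its coefficient uses the realized frequency of that fictive
allele with the 0/1 coding variance.

Qualitative traits
------------------
A penetrance model maps every one- or two-locus genotype to a probability of
being affected; case/control status is an independent Bernoulli draw per
individual.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from ._rng import NOISE, PENETRANCE, QTN_SELECTION, substream
from .errors import EligibilityError, ModelError, ValidationError
from .haploblocks import find_haploblocks
from .io_coalescent import HaplotypeMatrix, _positions_to_bp

__all__ = [
    "GenotypeMatrix",
    "QTNSpec",
    "QuantTraitModel",
    "PenetranceModel",
    "PhenotypeVector",
    "allele_frequency",
    "select_qtns",
    "coding_variance",
    "effect_coefficient",
    "epistatic_state",
    "generate_quantitative",
    "assign_case_control",
    "expected_prevalence",
    "regression_variance_shares",
]


@dataclass
class GenotypeMatrix:
    """Diploid genotypes: rows are individuals, columns are sites.

    Codes: -1 homozygous ancestral, 0 heterozygous, +1 homozygous derived.
    """

    codes: np.ndarray
    positions: np.ndarray
    position_unit: str = "fraction"
    locus_length_bp: int | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValidationError("codes must be a 2-D matrix")
        self.positions = np.asarray(
            self.positions, dtype=np.int64 if self.position_unit == "bp" else float
        )
        if len(self.positions) != self.codes.shape[1]:
            raise ValidationError("positions length must equal the number of sites")
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ValidationError("genotype codes must be -1, 0 or +1")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def positions_bp(self, locus_length_bp: int | None = None) -> np.ndarray:
        length = locus_length_bp if locus_length_bp is not None else self.locus_length_bp
        return _positions_to_bp(self.positions, self.position_unit, length)

    def take_sites(self, site_indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(site_indices, dtype=np.intp)
        return GenotypeMatrix(
            self.codes[:, idx],
            self.positions[idx],
            position_unit=self.position_unit,
            locus_length_bp=self.locus_length_bp,
        )

    def take_individuals(self, row_indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(row_indices, dtype=np.intp)
        return GenotypeMatrix(
            self.codes[idx, :],
            self.positions,
            position_unit=self.position_unit,
            locus_length_bp=self.locus_length_bp,
        )


Matrix = Union[HaplotypeMatrix, GenotypeMatrix]


@dataclass(frozen=True)
class QTNSpec:
    """One causal site: its column index, variance proportion and realized frequency."""

    site: int
    effect: float
    derived_freq: float

    def __post_init__(self) -> None:
        if not 0.0 < self.derived_freq < 1.0:
            raise ValidationError(
                f"QTN at site {self.site} must be polymorphic "
                f"(derived frequency {self.derived_freq})"
            )
        if self.effect < 0:
            raise ValidationError("QTN effect must be non-negative")


@dataclass
class QuantTraitModel:
    """Multi-QTN quantitative trait architecture.

    ``epistatic_effect`` (pi_E) requires exactly two QTNs; ``dominance``
    applies the 0/1 dominance recoding and is diploid-only.
    """

    qtns: list[QTNSpec]
    epistatic_effect: float = 0.0
    dominance: bool = False
    ploidy: str = "haploid"

    def __post_init__(self) -> None:
        if self.ploidy not in ("haploid", "diploid"):
            raise ValidationError(f"unknown ploidy {self.ploidy!r}")
        if self.epistatic_effect < 0:
            raise ValidationError("epistatic effect must be non-negative")
        if self.epistatic_effect > 0 and len(self.qtns) != 2:
            raise ValidationError("an epistatic effect requires exactly two QTNs")
        if self.dominance and self.ploidy != "diploid":
            raise ValidationError("dominance recoding applies to diploids only")
        if self.heritability >= 1.0:
            raise ValidationError(
                f"heritability {self.heritability} must be < 1 "
                "(the sum of QTN effects plus any epistatic effect)"
            )

    @property
    def heritability(self) -> float:
        """h^2 = sum of all QTN effects plus the epistatic effect."""
        return sum(q.effect for q in self.qtns) + self.epistatic_effect


@dataclass
class PenetranceModel:
    """Probability of affection per genotype at one or two loci.

    Table shapes: haploid one-locus (2,) indexed by allele; diploid one-locus
    (3,) indexed by (hom ancestral, het, hom derived); two-locus tables are
    the outer products of those axes, (2, 2) or (3, 3).
    """

    loci: tuple[int, ...]
    table: np.ndarray
    ploidy: str = "diploid"

    def __post_init__(self) -> None:
        self.loci = tuple(int(s) for s in self.loci)
        self.table = np.asarray(self.table, dtype=float)
        if self.ploidy not in ("haploid", "diploid"):
            raise ValidationError(f"unknown ploidy {self.ploidy!r}")
        if len(self.loci) not in (1, 2):
            raise ValidationError("penetrance models support one or two loci")
        k = 2 if self.ploidy == "haploid" else 3
        expected = (k,) * len(self.loci)
        if self.table.shape != expected:
            raise ValidationError(
                f"penetrance table shape {self.table.shape} does not match "
                f"{self.ploidy} {len(self.loci)}-locus model (expected {expected})"
            )
        if not ((self.table >= 0) & (self.table <= 1)).all():
            raise ValidationError("penetrance entries must lie in [0, 1]")


@dataclass
class PhenotypeVector:
    """Per-individual trait values (real) or affection statuses (0/1)."""

    values: np.ndarray
    kind: str = "quantitative"

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "case_control"):
            raise ValidationError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "case_control":
            self.values = np.asarray(self.values, dtype=np.int8)
            if len(self.values) and not np.isin(self.values, (0, 1)).all():
                raise ValidationError("case/control statuses must be 0 or 1")
        else:
            self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_cases(self) -> int:
        if self.kind != "case_control":
            raise ValidationError("n_cases is defined for case/control phenotypes only")
        return int(self.values.sum())

    def take(self, indices: Sequence[int]) -> "PhenotypeVector":
        return PhenotypeVector(self.values[np.asarray(indices, dtype=np.intp)], self.kind)


def allele_frequency(m: Matrix, site: int) -> float:
    """Derived-allele frequency at ``site`` (fraction of sampled chromosomes)."""
    if not 0 <= site < m.n_sites:
        raise IndexError(f"site index {site} out of range for {m.n_sites} sites")
    if isinstance(m, GenotypeMatrix):
        return float((m.codes[:, site] + 1).mean() / 2.0)
    return float(m.alleles[:, site].mean())


def _all_frequencies(m: Matrix) -> np.ndarray:
    if isinstance(m, GenotypeMatrix):
        return (m.codes + 1).mean(axis=0) / 2.0
    return m.alleles.mean(axis=0)


def select_qtns(
    m: Matrix,
    n_qtns: int,
    effects: Sequence[float],
    freq_range: tuple[float, float] | None = None,
    fixed_sites: Sequence[int] | None = None,
    require_common_haploblock: bool = False,
    seed: int | np.random.Generator = 0,
) -> list[QTNSpec]:
    """Pick causal sites and attach effects.

    Sites are drawn uniformly at random (seeded) from the polymorphic sites,
    optionally restricted to a derived-allele frequency range.  Fixed sites
    are honored verbatim (they bypass the frequency filter) and occupy the
    leading effect slots in the order given; randomly chosen sites follow in
    ascending column order.  With ``require_common_haploblock`` (two QTNs
    only) the pair is drawn uniformly from all eligible pairs lying inside a
    single four-gamete haploblock.
    """
    if n_qtns < 1:
        raise ValidationError("n_qtns must be positive")
    if len(effects) != n_qtns:
        raise ValidationError(f"{len(effects)} effects given for {n_qtns} QTNs")
    if require_common_haploblock and n_qtns != 2:
        raise ValidationError("the common-haploblock constraint applies to exactly 2 QTNs")
    fixed = [int(s) for s in (fixed_sites or [])]
    if len(fixed) > n_qtns:
        raise ValidationError("more fixed sites than QTNs")

    freqs = _all_frequencies(m)
    polymorphic = (freqs > 0) & (freqs < 1)
    for s in fixed:
        if not 0 <= s < m.n_sites:
            raise IndexError(f"fixed site {s} out of range")
        if not polymorphic[s]:
            raise EligibilityError(f"fixed site {s} is monomorphic")

    eligible = polymorphic.copy()
    if freq_range is not None:
        lo, hi = freq_range
        eligible &= (freqs >= lo) & (freqs <= hi)
    eligible[fixed] = False
    eligible_sites = np.flatnonzero(eligible)  # ascending: reproducible tie-break

    rng = substream(seed, QTN_SELECTION)
    n_random = n_qtns - len(fixed)

    if require_common_haploblock:
        if isinstance(m, GenotypeMatrix):
            raise ValidationError(
                "haploblock constraint needs haplotypes; select on the "
                "HaplotypeMatrix before diploid pairing"
            )
        blocks = find_haploblocks(m)
        if len(fixed) == 2:
            if not any(fixed[0] in b and fixed[1] in b for b in blocks):
                raise EligibilityError(
                    f"fixed sites {fixed} do not share a four-gamete haploblock"
                )
            chosen = []
        elif len(fixed) == 1:
            block = next(b for b in blocks if fixed[0] in b)
            partners = [s for s in eligible_sites if s in block]
            if not partners:
                raise EligibilityError(
                    f"no eligible partner site in the haploblock of fixed site {fixed[0]}"
                )
            chosen = [int(rng.choice(partners))]
        else:
            pairs: list[tuple[int, int]] = []
            for blk in blocks:
                in_block = [int(s) for s in eligible_sites if s in blk]
                for k, a in enumerate(in_block):
                    pairs.extend((a, b) for b in in_block[k + 1 :])
            if not pairs:
                raise EligibilityError(
                    "no four-gamete haploblock contains two eligible sites"
                    + (f" in frequency range {freq_range}" if freq_range else "")
                )
            chosen = list(pairs[rng.integers(len(pairs))])
    else:
        if len(eligible_sites) < n_random:
            constraint = (
                f"frequency range {freq_range}" if freq_range is not None else "polymorphism"
            )
            raise EligibilityError(
                f"only {len(eligible_sites)} sites satisfy the {constraint} "
                f"constraint; {n_random} needed"
            )
        chosen = sorted(
            int(s) for s in rng.choice(eligible_sites, size=n_random, replace=False)
        )

    sites = fixed + list(chosen)
    return [
        QTNSpec(site=s, effect=float(e), derived_freq=float(freqs[s]))
        for s, e in zip(sites, effects)
    ]


def coding_variance(f: float, ploidy: str = "haploid", dominance: bool = False) -> float:
    """Genotypic variance of the QTN coding at derived-allele frequency ``f``.

    0/1 codings (haploid alleles, dominance indicators, the fictive epistatic
    allele) have variance f(1-f); the diploid {-1, 0, +1} additive coding has
    variance 2 f (1-f) under random pairing of chromosomes.
    """
    if ploidy == "diploid" and not dominance:
        return 2.0 * f * (1.0 - f)
    return f * (1.0 - f)


def effect_coefficient(
    pi_j: float, f_j: float, h2: float, coding_variance: float
) -> float:
    """Regression coefficient beta_j = sqrt(pi_j / (coding_variance * (1 - h^2)))."""
    if not 0.0 < f_j < 1.0:
        raise ModelError(f"QTN frequency {f_j} must lie strictly inside (0, 1)")
    if pi_j < 0:
        raise ModelError("variance proportion must be non-negative")
    if h2 >= 1.0:
        raise ModelError(f"heritability {h2} must be < 1")
    if coding_variance <= 0:
        raise ModelError("coding variance must be positive (monomorphic coding?)")
    return float(np.sqrt(pi_j / (coding_variance * (1.0 - h2))))


def epistatic_state(g1, g2, ploidy: str = "haploid"):
    """Fictive epistatic allele: 1 iff >=1 derived allele at BOTH basal QTNs.

    Accepts scalars or arrays of genotype codes — 0/1 alleles for haploids,
    {-1, 0, +1} for diploids (heterozygotes carry a derived allele, so any
    code >= 0 counts).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if ploidy == "haploid":
        state = (g1 == 1) & (g2 == 1)
    else:
        state = (g1 >= 0) & (g2 >= 0)
    out = state.astype(np.int8)
    return out if out.ndim else int(out)


def _qtn_coding(m: Matrix, model: QuantTraitModel, qtn: QTNSpec):
    """Return (coding column, realized coding variance) for one QTN."""
    if model.ploidy == "haploid":
        col = m.alleles[:, qtn.site].astype(float)
        f = float(col.mean())
        dom = False
    else:
        codes = m.codes[:, qtn.site]
        if model.dominance:
            col = (codes >= 0).astype(float)  # carrier indicator
            f = float(col.mean())
            dom = True
        else:
            col = codes.astype(float)
            f = float((codes + 1).mean() / 2.0)
            dom = False
    if not 0.0 < f < 1.0:
        raise ModelError(f"QTN at site {qtn.site} is monomorphic under its coding")
    return col, coding_variance(f, model.ploidy, dom), f


def epistatic_indicator(m: Matrix, model: QuantTraitModel) -> np.ndarray:
    """Fictive-third-QTN column for a two-QTN model on ``m``."""
    if len(model.qtns) != 2:
        raise ModelError("the epistatic indicator requires exactly two QTNs")
    s1, s2 = model.qtns[0].site, model.qtns[1].site
    if model.ploidy == "haploid":
        return epistatic_state(m.alleles[:, s1], m.alleles[:, s2], "haploid")
    return epistatic_state(m.codes[:, s1], m.codes[:, s2], "diploid")


def generate_quantitative(
    m: Matrix, model: QuantTraitModel, seed: int | np.random.Generator = 0
) -> PhenotypeVector:
    """Simulate trait values: scaled genetic contributions plus N(0, 1) noise."""
    if model.ploidy == "haploid" and not isinstance(m, HaplotypeMatrix):
        raise ModelError("haploid model requires a HaplotypeMatrix")
    if model.ploidy == "diploid" and not isinstance(m, GenotypeMatrix):
        raise ModelError("diploid model requires a GenotypeMatrix (pair chromosomes first)")
    n = m.alleles.shape[0] if isinstance(m, HaplotypeMatrix) else m.n_individuals
    h2 = model.heritability
    rng = substream(seed, NOISE)
    y = rng.standard_normal(n)
    for qtn in model.qtns:
        col, cv, f = _qtn_coding(m, model, qtn)
        y += effect_coefficient(qtn.effect, f, h2, cv) * col
    if model.epistatic_effect > 0:
        a_e = epistatic_indicator(m, model).astype(float)
        f_e = float(a_e.mean())
        if not 0.0 < f_e < 1.0:
            raise ModelError(
                "the fictive epistatic allele is monomorphic in this sample; "
                "re-select the basal QTNs"
            )
        y += effect_coefficient(
            model.epistatic_effect, f_e, h2, coding_variance(f_e)
        ) * a_e
    return PhenotypeVector(y, "quantitative")


def assign_case_control(
    m: Matrix, model: PenetranceModel, seed: int | np.random.Generator = 0
) -> PhenotypeVector:
    """Draw affection status per individual from the penetrance of its genotype."""
    if model.ploidy == "haploid":
        if not isinstance(m, HaplotypeMatrix):
            raise ModelError("haploid penetrance model requires a HaplotypeMatrix")
        idx = [m.alleles[:, s].astype(np.intp) for s in model.loci]
        n = m.n_chromosomes
    else:
        if not isinstance(m, GenotypeMatrix):
            raise ModelError("diploid penetrance model requires a GenotypeMatrix")
        idx = [(m.codes[:, s] + 1).astype(np.intp) for s in model.loci]
        n = m.n_individuals
    p = model.table[idx[0]] if len(idx) == 1 else model.table[idx[0], idx[1]]
    rng = substream(seed, PENETRANCE)
    affected = (rng.random(n) < p).astype(np.int8)
    return PhenotypeVector(affected, "case_control")


def expected_prevalence(
    model: PenetranceModel, genotype_frequencies: Sequence[float] | np.ndarray
) -> float:
    """Population case fraction: sum over genotypes of P(genotype) * penetrance."""
    gf = np.asarray(genotype_frequencies, dtype=float)
    if gf.shape != model.table.shape:
        raise ValidationError(
            f"genotype frequencies shape {gf.shape} does not match "
            f"penetrance table shape {model.table.shape}"
        )
    if abs(gf.sum() - 1.0) > 1e-9:
        raise ValidationError(f"genotype frequencies sum to {gf.sum()}, expected 1")
    return float((gf * model.table).sum())


def regression_variance_shares(
    y: np.ndarray, columns: np.ndarray
) -> tuple[float, np.ndarray]:
    """OLS of ``y`` on ``columns`` (with intercept): total R^2 and per-term shares.

    The share of term j is beta_hat_j^2 Var(x_j) / Var(y) — the marginal
    phenotypic variance carried by that term of the fitted model, which is
    the quantity the generative scaling calibrates to pi_j.  For mutually
    independent predictors it coincides with the increment in R^2 from
    adding the column; for correlated predictors (the epistatic indicator)
    it does not, and is the appropriate reading of a term's contribution.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(columns, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    var_y = y.var()
    r2 = 1.0 - resid.var() / var_y
    shares = beta[1:] ** 2 * X.var(axis=0) / var_y
    return float(r2), shares
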