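# phenosim

Attach simulated phenotypes to coalescent-simulated genotypes, for GWAS
power studies.

Coalescent simulators (ms, msHOT, msms, GENOME) generate genotypes under
rich demographic models orders of magnitude faster than forward-in-time
simulation — but no phenotypes. phenosim adds a phenotype with a known
causal architecture to each simulated individual, subsamples the population
the way a real study would, and writes files that association tools (PLINK,
EMMA/EMMAX) read directly. Simulating genotype + phenotype pairs with known
truth lets you measure the statistical power of an association method under
any population-genetic scenario, compare methods, or size a study.

## Models

**Quantitative traits.** Each quantitative trait nucleotide (QTN) *j* has a
variance proportion π_j; Σ_j π_j (+ π_E) = h² < 1. The phenotype is

    Y_i = Σ_j β_j g_ij (+ β_E a_iE) + ε_i,   ε_i ~ N(0,1),
    β_j = sqrt( π_j / ( v_j (1 − h²) ) )

where g_ij is the 0/1 allelic state (haploid), the {−1, 0, +1} genotype code
(diploid additive) or a 0/1 carrier indicator (diploid dominant), and v_j is
the coding variance at the QTN's realized frequency. Epistasis between two
QTNs is a fictive third QTN whose allele a_iE is 1 iff the individual
carries a derived allele at both basal QTNs. QTN positions are random,
manual, restricted to a frequency range, and/or confined to one haploblock
(four-gamete test) to mimic a causal haplotype.

**Qualitative traits.** A penetrance table gives the probability of being
affected for every one- or two-locus genotype; case/control status is drawn
per individual, and a minimum number of cases can be ascertained from a
larger simulated population, as in real case/control recruitment.

After phenotype assignment, markers and/or individuals are subsampled and
the causal markers optionally removed (the causal mutation is usually not
genotyped). See `docs/methods.md` for the full model description.

## Worked example

Simulate a haplotype fixture (no external simulator needed), then run a
two-QTN quantitative study with the causal markers removed:

```bash
phenosim fixture --chromosomes 400 --sites 120 --seed 7 --out sim.ms
phenosim run --input sim.ms --dialect ms \
    --effects 0.05,0.05 --freq-range 0.2,0.8 \
    --remove-causal --n-markers 100 \
    --format ped,tsv --seed 42 --prefix study
```

which prints

```
wrote 4 files for 1 replicate(s); manifest: study.manifest.json
```

and records in `study.manifest.json` (abridged):

```json
{
  "qtn_sites": [48, 88],
  "qtn_frequencies": [0.205, 0.5575],
  "qtn_positions_bp": [408862, 766986],
  "retained_causal_columns": [],
  "files": {"study.ped": "b83cfe2848b0...", "study.map": "1ae6dd572706...", ...}
}
```

Two causal sites were drawn inside the requested frequency range (realized
derived-allele frequencies 0.205 and 0.5575, together explaining h² = 0.10
of the phenotypic variance), then deleted from the exported marker set
(`retained_causal_columns` is empty) before 100 of the remaining 118
markers were sampled. `study.ped`/`study.map` are standard PLINK text files
— each individual's phenotype (e.g. `1.1038643035946585`) followed by A/T
allele pairs — and the checksums make the run verifiable: the same seed and
config reproduce the files byte for byte.

The same pipeline is available as a library:

```python
import phenosim as ps

m = ps.generate_fixture(20_000, 200, 0.4, seed=1)
qtns = ps.select_qtns(m, 2, [0.05, 0.05], seed=1)
y = ps.generate_quantitative(m, ps.QuantTraitModel(qtns), seed=1)
r2, shares = ps.regression_variance_shares(
    y.values, m.alleles[:, [q.site for q in qtns]]
)
# r2 ~ 0.10, shares ~ (0.05, 0.05)
```

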