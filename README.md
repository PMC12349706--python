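# meiocross

Two-pathway meiotic crossover simulation and fluorescent-tetrad
interference analysis for Arabidopsis-style FTL experiments.

## The problem

In most eukaryotes meiotic crossovers (COs) come from two pathways: an
interfering **Class I** pathway (ZMM proteins; sites marked by MLH1/HEI10
foci) and a non-interfering, MUS81-dependent **Class II** pathway.  A
mutation that re-channels recombination intermediates from Class II into
Class I changes none of the total CO number, but it raises genetic
interference and the MLH1/HEI10 focus count while lowering the residual CO
number seen in *zmm* mutant backgrounds.  Detecting that signature requires
a pipeline that goes from raw pollen-tetrad fluorescence phenotypes to
calibrated interference estimates and genotype comparisons.

`meiocross` provides that pipeline, plus a forward simulator that generates
data with exactly the statistical structure the estimators assume, so every
estimator can be validated against known truth:

* **simulate** — COs on a bivalent carrying three linked fluorescent
  markers (FTL triplet in a *qrt* background, markers in coupling).
  Class I events follow a stationary gamma renewal process on the genetic
  axis (shape `nu`; `nu = 1` is Poisson, larger values give interference);
  Class II events are an independent Poisson process.  Each CO joins one
  chromatid per homolog, uniformly and independently (no chromatid
  interference).  Also simulates ring/rod bivalent configurations at
  metaphase I and per-nucleus focus counts.
* **classify** — tetrad phenotypes into per-interval ditypes (P/T/N) and
  the 12 canonical joint classes A–L, derived by brute-force enumeration
  (the letter key is emitted with every output, and foreign letter
  conventions can be remapped).
* **estimate** — map distances by the Perkins equation,
  `X = 100 (T/2 + 3 NPD) / n` cM, and interference as `1 − CoC` with
  `CoC = f12 / (f1 f2)`, where `f1`, `f2`, `f12` are the fractions of
  tetrads recombinant in interval 1, interval 2, and both.  Standard errors
  by the multinomial delta method, with a seeded tetrad bootstrap as the
  reference alternative.
* **compare** — two-proportion Z-tests for CO frequency and a
  difference-of-interference Z-test between genotypes; Mann–Whitney,
  Kruskal–Wallis + Dunn, and t-tests for cytology counts; focus-count
  histograms over the bins {0}, [1,2], [3,10], [11,20], [21,50], >50.

## Worked example

The in-silico re-channeling experiment: hold the total CO rate at 2 per
bivalent per Morgan and move the Class II fraction from 0.15 to 0.

```sh
python analysis/03_headline_rechanneling.py --seed 0
```

prints

```
    wild-type-like: interference 0.708 +/- 0.012, Class I/meiosis 0.339, d1 9.92 cM, d2 9.94 cM
  class2-deficient: interference 0.974 +/- 0.004, Class I/meiosis 0.400, d1 9.99 cM, d2 10.00 cM

delta interference = +0.266 (21.6 SE); delta Class I = +0.061; delta d1 = +0.07 cM (0.5 SE); delta d2 = +0.06 cM (0.5 SE)
```

Re-channeling raises interference (by 21.6 Monte-Carlo SE here) and the
Class I crossover count per meiosis, while both interval distances — the
measured CO frequencies — stay put within noise.  That is the full
phenotype signature of a Class II→Class I shift at constant CO number.

The other drivers under `analysis/` simulate a two-genotype FTL experiment
and push it through the classify→estimate→compare pipeline
(`01`, `02`), quantify the undercounting bias of the ring=2/rod=1 chiasma
estimator against simulated truth (`04`), and run the estimators over the
synthetic reconstructions of published summary tables (`05`).

A thin CLI mirrors the library: `meiocross simulate | classify | estimate |
compare | reproduce | headline | fixtures`, all accepting `--seed` and
writing a log with the config hash so runs are reproducible bit for bit.

## Data formats

CSV/TSV with header rows throughout: raw tetrads (`spore1..spore4` as
3-bit fluorophore strings), class-count tables (`genotype, plant, A..L,
n`), focus counts (`kind, genotype, treatment, cell_id, count`) and
bivalent shapes (`genotype, cell_id, ring, ring3, rod, univalent_pairs`).
Readers validate and reject malformed rows with line numbers.  Note that
files named `synthetic_*` are deterministic stand-ins generated by
`meiocross.synthetic_tables`, not experimental data; see
`docs/methods.md`.
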