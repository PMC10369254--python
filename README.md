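# stranddecoder

An in-silico implementation of a DNA strand-displacement "genetic
decoder": a molecular circuit that reads a diploid genotype and reports
its clinical interpretation — metabolizer phenotype, drug-dosing category,
or polygenic risk level — as a fluorescence pattern, with no downstream
computation.

The package is for people who design or study molecular classifiers:
it lets you learn the allele weights, compile them into a gate-level
circuit, integrate the mass-action kinetics, and decode the simulated
fluorescence, all from Python.

## The model

A biallelic locus panel encodes a diploid sample as a binary
allele-presence vector **x** (one bit per allele; heterozygotes set both
bits of a locus). Each allele carries a signed weight w_i in 1×
concentration units, learned so that phenotype classes occupy disjoint
intervals of the net score

    X = Σ max(w_i, 0) x_i,   Y = Σ max(−w_i, 0) x_i,   net = X − Y.

The circuit realises this arithmetic chemically: seesaw multiplication
gates (weight = gate concentration, input-regenerating catalysis),
summation gates, a cooperative-hybridization subtraction gate that
annihilates X and Y stoichiometrically, and comparator channels that
threshold the leftover species against the class boundaries. A channel is
ON above 0.4 normalised fluorescence units; the ON/OFF pattern maps to the
class. Polygenic risk scores (PRS = Σ d_v·lnOR_v over dosages d ∈
{0,1,2}) use a ternary encoding: effect-allele gates at 2·lnOR and
other-allele gates at lnOR, so the circuit computes PRS minus a known
offset for absent alleles.

See `docs/methods.md` for the kinetic model, rate constants and the
design analysis behind them.

## Worked example

```python
from stranddecoder.model import GeneticDecoder

fit = GeneticDecoder.from_fixture("CYP2C19").fit()
print(fit.summary())
```

```
Genetic decoder fit
=======================================================
panel:            CYP2C19
genotypes:        10
classes:          PM, IM, EM, UM
boundaries (1x):  [-2.0, 0.0, 4.0]
feasible:         True
achieved margin:  0.500
-------------------------------------------------------
        allele  weight (1x)
          681G        2.500
          681A       -5.000
          636G        1.000
          636A       -5.000
         -806C        0.000
         -806T        1.000
-------------------------------------------------------
         class          score range
            PM       [-6.50, -2.50]
            IM       [-1.50, -0.50]
            EM         [3.50, 3.50]
            UM         [4.50, 4.50]
```

The learner found integer/half-integer weights placing all ten diplotypes
in their class intervals with the maximal feasible margin (0.5 in 1×
units; 1× = 10 nM in the compiled circuit). The loss-of-function alleles
(681A defining \*2, 636A defining \*3) carry −5, the promoter variant
−806T (\*17) +1, so e.g. \*1/\*1 scores +3.5 (extensive metabolizer) and
\*2/\*2 scores −4 (poor metabolizer); the full ranges are printed above.

Simulating one genotype end to end — ligation yields, 2.5 h of
strand-displacement kinetics, fluorescence normalisation:

```python
traj, rfu = fit.simulate_genotype("*2/*17")
print({k: round(v, 2) for k, v in sorted(rfu.items())})
```

```
{'Cy5': 0.04, 'FAM': 0.02, 'ROX': 0.0, 'VIC': 0.99}
```

Only VIC is above the 0.4 demarcation: net score in (−2, 0), an
intermediate metabolizer — the labelled class of \*2/\*17.

The same interface covers the polygenic-score machinery (on an embedded
*synthetic* 22-variant scoring model, not a real catalog accession):

```python
from stranddecoder.model import PRSModel
print(PRSModel.from_synthetic().fit(n=2504, seed=1).summary())
```

```
Polygenic risk score fit
=======================================================
scoring model:      SYNTH022 (22 variants)
cohort size:        2504
mean (lnOR units):  6.968
sd:                 1.029
top decile cut:     8.271
categories:         low=250, intermediate=2004, high=250
literal-encoding offset (mean): 2.601
```

A command-line interface mirrors the library:

```
stranddecoder learn --panel DPYD
stranddecoder decode --panel CYP2C19
stranddecoder prs --simulate 2504 --top-decile-screen
stranddecoder fixtures --out-dir fixtures/
```

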