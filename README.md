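# tmidr — disorder prediction for transmembrane proteins

`tmidr` predicts intrinsically disordered regions (IDRs) in transmembrane
proteins (TMPs). General-purpose disorder predictors are trained mostly on
soluble proteins and struggle on TMPs, whose loops and tails live in very
different chemical environments on the two sides of the membrane. `tmidr`
makes the membrane topology part of the model: it is aimed at structural
bioinformaticians and protein scientists who have a sequence plus a
per-residue topology annotation and want per-residue disorder scores that
respect that topology.

## The model

Every non-membrane residue is assigned to one of four compartments by its
side and its sequence distance *d* to the nearest membrane residue:

| compartment | side | distance |
|---|---|---|
| extracellular-distant | outside | d > 15 |
| extracellular-proximal | outside | d ≤ 15 |
| intracellular-distant | inside | d > 15 |
| intracellular-proximal | inside | d ≤ 15 |

Each compartment has its own convolutional network scoring an 11 × 39
feature matrix built from a ±5-residue window: evolutionary profile (PSSM
or a substitution-matrix fallback), nine amino-acid scales, windowed
ProtParam descriptors (MW, pI, instability), compartment one-hots, relative
solvent accessibility, a SEG-style low-complexity flag and a validity bit.
A bidirectional recurrent smoother then refines the raw track from the CNN
score plus topology encoding, looking 12 residues in each direction;
membrane residues always enter with score 0.

Two output modes are published from the same ensemble:

* **specific** — CNN track, ±4 moving average, cutoff 0.65;
* **sensitive** — smoother track, ±7 moving average, cutoff 0.65.

Display scores are rescaled so the 0.65 cutoff maps to 0.5 (piecewise
linear), making `display ≥ 0.5` exactly the binary disorder call.

The package also implements the full training protocol: 90%-consensus
order/disorder labels, IDR + ≤15-residue-flank fragment selection,
per-compartment class balancing to a 10% tolerance, greedy 40%-identity
redundancy clustering, and a train/validation/test split with a repair
pass guaranteeing no test fragment shares ≥40% identity with training
material. Residue metrics (sensitivity, specificity, balanced accuracy,
MCC, AUC) and ≥60%-of-residues region-level detection mirror the
community disorder-assessment protocol.

## Worked example

Train on a synthetic TMP corpus and predict a protein end to end:

```bash
tmidr generate --seed 11 --n-proteins 60 --out corpus/
tmidr train --corpus corpus/ --seed 11 --out model/
tmidr predict --model model/ \
    --fasta query.fasta --topology query.topo --out pred/
```

With `query.fasta` holding an 80-residue protein whose N-terminal tail has
a disorder-promoting composition (PESQKG repeats) and `query.topo` its
topology string (`I`×40 `M`×20 `O`×20), `pred/q1.tsv` starts:

```
position  residue  topology  category  raw       smoothed  display   call_specific  call_sensitive
1         P        I         2         0.573056  0.928711  0.898159  1              1
2         E        I         2         0.740086  0.936384  0.909119  1              1
3         S        I         2         0.894343  0.942519  0.917884  1              1
...
41        I        M         4         0.0       0.0       0.0       0              0
```

`category` is the compartment index (2 = intracellular-distant, 4 =
membrane), `raw` the compartment-CNN score, `smoothed` the sensitive-mode
track after the ±7 average, and `display` its rescaled value — here well
above 0.5, so both modes call these disorder-biased tail residues
disordered. Membrane rows (positions 41–60) carry `raw = 0` and are never
called.

Evaluation against per-residue labels:

```bash
tmidr evaluate --predictions pred/ --labels corpus/labels.tsv --out report.json
```

The same machinery is available as a library; the central classes are
`MembraneDisorderEnsemble`, `CompartmentConvNet` and `BiRNNSmoother`
(scikit-learn-style `fit`/`predict`).

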