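# pagvocal

Analysis pipeline for pulsatile fish vocalisations and the midbrain
circuitry that patterns them. The plainfin midshipman (*Porichthys
notatus*) produces a small repertoire of pulse-train calls — brief
broadband **grunts** (often repeated in trains with a characteristic
inter-grunt interval, IGI), long variable **growls**, long stable
multi-harmonic courtship **hums**, and **buzzes** — and the same temporal
statistics can be read out of "fictive calls": vocal motor volleys
recorded from the occipital nerve after pharmacological activation of
midbrain (periaqueductal gray, PAG) or hindbrain vocal nuclei. This
package implements the complete quantitative chain for such data:

1. **Signal processing** — 1 kHz zero-phase lowpass, moving-average
   smoothing, normalisation to the maximum, peak detection above 25% of
   the segment maximum, and response-latency measurement from an
   injection-artifact marker (`pagvocal.signal`).
2. **Call analysis** — segmentation of pulse series into calls and bouts,
   the six per-call features used for embedding
   (duration; CV of amplitude; mean pulse repetition rate, PRR = 1/IPI;
   CV of PRR; percent change in amplitude from lowest to highest peak;
   percent change in PRR from slowest to fastest gap), bout IGI profiles
   (stable vs rise-then-fall), rule-based call-type labels, and calls per
   minute (`pagvocal.calls`).
3. **Embedding and statistics** — z-scored UMAP of the six features, a
   k-nearest-neighbour overlap score between call groups, log(1+x)
   transform, Benjamini–Hochberg adjustment, and mixed-model group
   contrasts with animal identity as a random effect
   (`pagvocal.embedding`).
4. **catFISH quantification** — two-period neuronal activation from
   per-cell nuclear (intronic, recent period) and cytoplasmic (coding,
   earlier period) label states: zone counts and the **reactivation
   index**, the percentage of nuclear-labelled cells that also carry
   cytoplasmic label, with exact binomial recovery of the underlying
   conditional activation probability (`pagvocal.catfish`).
5. **Synthetic data** — seeded generators for all call classes, bouts
   with stable or rise-then-fall IGI profiles, noise at a requested SNR,
   stimulus artifacts, and bivariate-Bernoulli two-period cell
   populations, each with exact ground truth (`pagvocal.synth`). Every
   downstream stage is validated against this ground truth.

The numbered scripts under `analysis/` run the study end to end on
synthetic data (simulate → detect/featurise → embed/overlap → bout IGI →
catFISH → group contrasts), writing tables under `results/`.

## Worked example

```sh
$ pagvocal simulate --call-type grunt --n-calls 6 --igi-mean 0.5 \
      --igi-sd 0.02 --snr-db 20 --seed 11 --out demo/bout.wav
wrote demo/bout.wav (6 calls, 123 pulses)
$ pagvocal detect demo/bout.wav --out demo/pulses.csv
123 pulses -> demo/pulses.csv
$ pagvocal features demo/pulses.csv --out demo/features.csv
6 analysable calls (0 single-pulse) -> demo/features.csv
```

The simulated grunt train carries 123 ground-truth pulses; at 20 dB SNR
the detector recovers all 123 and segmentation returns the 6 generated
calls. The first feature rows:

```
call_id,...,n_pulses,duration,cv_amp,mean_prr,cv_prr,...
0,...,21,0.1978,0.0948,101.31,0.0461,...
1,...,21,0.1989,0.1233,100.65,0.0312,...
```

Each call lasts ~0.2 s with a mean PRR near the generating 100 Hz and a
PRR CV near the generating 0.05 — the detector's read-back of the known
simulation parameters. The same library calls are available in Python
(`pv.synth_bout`, `pv.preprocess`, `pv.detect_pulses`,
`pv.segment_calls`, `pv.extract_features`, ...).

Running `python analysis/05_catfish_quant.py` after `01_simulate.py`
prints, for the two simulated reactivation regimes:

```
cross_type: reactivation index 68.0 +/- 1.3% (mean +/- SEM, n=5 animals;
            generating conditional 65%; CI covered truth in 4/5 animals)
same_type:  reactivation index 89.9 +/- 0.4% (mean +/- SEM, n=5 animals;
            generating conditional 90%; CI covered truth in 5/5 animals)
```

i.e. the per-animal reactivation index recovers the conditional
activation probability used to generate each population.

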