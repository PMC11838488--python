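# kinfp — single-molecule kinetic fingerprinting

`kinfp` analyzes single-molecule kinetic fingerprinting experiments: a
surface-captured biomarker (miRNA, protein, or mutant DNA) is transiently
and repeatedly visited by a fluorescent probe under TIRF microscopy, and
the *temporal pattern* of those visits — not a static spot intensity —
identifies and counts individual molecules. The package takes raw
per-channel TIFF movie stacks (or per-ROI intensity traces), and produces
digital molecule counts, demultiplexed target identities, ensemble kinetic
parameters and concentrations. A built-in ground-truth simulator generates
traces, fields of view and rendered movies with the statistical structure
the analysis assumes, so the whole pipeline is testable without
experimental data.

It is intended for researchers building or evaluating kinetic-
fingerprinting assays (SiMREPS-style detection, DNA-PAINT-adjacent
kinetics) and for method development on trace idealization and kinetic
demultiplexing.

## Model

Each molecule is an alternating renewal process: probe-bound dwells are
exponential with mean τ_on, unbound dwells exponential with mean τ_off.
The camera integrates the path at 100 ms/frame; traces are idealized with
a two-state Gaussian-emission hidden Markov model (Baum–Welch EM, Viterbi
decoding), yielding per-molecule fingerprints

> N_b+d (number of binding + dissociation events), τ_on,med, τ_off,med,
> τ_off,max, and S/N,

which kinetic filtering compares against target-specific thresholds to
reject nonspecific binding. Accepted molecules are demultiplexed by color
channel (C1 = Cy3, C2 = Cy5, C12 = both colors colocalized) and by
position in log dwell-time space relative to pretrained axis-aligned
Gaussian clusters (χ², 2 dof confidence ellipses; 95% ⇒ d² ≤ 5.991).
Ensemble kinetics come from fitting the cumulative dwell-time frequency to
y = −e^(−x/τ) + c (accepted iff SSE < 0.05 and R² > 0.99); counts are
quantified through linear standard curves with LOD = 3s/m and optional
spike-in normalization.

## Worked example

Simulate a three-target mixture (the miR-29 / miR-16 / let-7a kinetic
profiles: τ_on/τ_off = 0.49/10.35, 2.29/2.69, 6.25/16.47 s) at a 5-minute
acquisition, pretrain clusters on an independent simulation, and
demultiplex:

```python
from kinfp.simulate import THREE_PLEX_KINETICS, simulate_clustering_dataset
from kinfp.demux import train_cluster_model, assign_molecules, unassigned_fraction

train = simulate_clustering_dataset(THREE_PLEX_KINETICS, 100, 300.0, seed=1)
model = train_cluster_model(train)          # simulate -> HMM -> fingerprints -> fit
test = simulate_clustering_dataset(THREE_PLEX_KINETICS, 100, 300.0, seed=2)
res = assign_molecules(test, model, confidence=0.95, rule="confidence",
                       undefined="unassign")
print(res["label"].value_counts())
print(f"unassigned fraction: {unassigned_fraction(res):.3f}")
```

```
label
let-7a        99
miR-29        98
miR-16        98
unassigned     5
unassigned fraction: 0.017
```

Of 300 simulated molecules, 295 are returned to their generating target
and 5 (1.7%) fall outside every 95% confidence cluster — molecules whose
traces showed too few complete binding events to place, or whose dwell
medians landed between clusters. The fitted cluster centers sit at the
log10 of the generating dwell times (e.g. miR-16: mean (0.243, 0.305) ≈
log10(2.29), log10(2.69) — the small offsets are frame quantization).

Ensemble kinetics of one target, from pooled simulated dwells:

```python
from kinfp.quantify import cumulative_dwell_hist, fit_exponential_cdf
fit = fit_exponential_cdf(cumulative_dwell_hist(dwells, frame_time=0.1))
```

```
tau=0.515 s  c=1.004  sse=0.0014  r2=0.9991  accepted=True
```

The fitted τ estimates the 0.49-s mean bound dwell of the fastest target
(binning at the 0.1-s frame time contributes the small upward offset), and
the fit passes the SSE/R² acceptance rules.

The same stages are available from the shell:

```sh
kinfp simulate -c sim.yaml -o fixtures/
kinfp analyze -c analyze.yaml -o results/    # idealize -> filter -> assign
kinfp fit-dwell --dwells dwells.tsv
```

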