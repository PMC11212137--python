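# enantiopore

Single-molecule nanopore sensing can tell apart peptide enantiomers —
molecules that differ only in the chirality of one amino acid, such as
vasopressin with an l- or d-arginine at position 8 (l-AVP / d-AVP) — from
the statistics of the ionic-current blockades they produce in a wild-type
aerolysin pore. `enantiopore` implements that analysis as a tested Python
pipeline for people who work with (or want to prototype against)
single-channel resistive-pulse recordings:

* **trace simulation** (`trace_sim`): synthetic recordings with an open-pore
  baseline around I₀ ≈ 250 pA (110 mV, 4 M KCl), Poisson event arrivals,
  exponential dwell times, per-population Gaussian normalized blockade
  depths, 250 kHz sampling and a 5 kHz Gaussian low-pass — with a
  ground-truth event ledger for validation;
* **event detection** (`eventio`): robust I₀/σ estimation, threshold
  detection at I₀ − 7σ, the five event parameters
  (T_t, ΔI_bmin, ΔI_bmax, ΔI_b, I_bs with ΔI_b = I₀ − I_b), and the standard
  event filters (dwell ≥ 200 µs, I_bs ≥ 1 pA, ΔI_b/I₀ ≥ 0.2);
* **distribution fits** (`fitting`): blockade histograms binned at 0.005
  fitted with Gaussian/bi-Gaussian peaks inside population windows
  (Type I 0.7–0.8, Type II 0.35–0.55, reduced/TCEP 0.4–0.8), semilog
  dwell-time histograms (30 bins/decade) and interevent-time histograms
  (2 ms bins) fitted with single exponentials, each fit repeated 3× from
  randomized starts and reported as mean ± sd;
* **enantiomer classification** (`chiral_classify`): correlation-matrix PCA
  of the five standardized parameters using a fixed reference (d-peptide)
  model, Gaussian fits of each peptide's PC2 peak (μ, σ), event attribution
  inside [μ − 3σ, μ + 3σ] bands, Monte Carlo label assignment where the
  bands overlap (probability proportional to the two Gaussian densities),
  confusion-matrix evaluation, mixture-ratio estimation with binomial
  confidence intervals, and a logistic-regression baseline;
* **orchestration** (`pipeline` + the `enantiopore` CLI): YAML-configured
  end-to-end runs with per-stage seeds and JSON reports.

## Worked example

Simulate one minute of a native l-peptide recording, detect and filter
events, and fit the population statistics:

```python
from enantiopore import *

config = SimConfig(duration_s=60.0,
                   populations=study_conditions()["l_native"],
                   condition="l_native", seed=7)
trace = simulate_trace(config)
baseline = estimate_baseline(trace)
events = extract_features(trace, detect_events(trace, baseline))
kept = filter_events(events)
fit = fit_blockade_peaks(blockade_histogram(kept), "bigaussian",
                         WINDOWS["typeII"], seed=1)
```

This prints (via the snippet in `scripts/` or your own formatting):

```
I0 = 250.00 pA, sigma = 1.83 pA, threshold = 237.18 pA
1074 events detected, 839 retained after filters
Type II component: blockade 0.431 (sd 0.017, amplitude 53)
Type II component: blockade 0.482 (sd 0.014, amplitude 33)
Type I blockade = 0.718
event frequency = 20.7 Hz
Type II dwell tau = 820 us
```

The bi-Gaussian resolves the two Type II conformational populations
(generator truth 0.43 and 0.48 of I₀; the dominant-amplitude component is
Type IIa), the Type I window recovers its 0.72 population, the
interevent-time fit returns the nominal ≈19 Hz capture rate, and the
dwell-time tail decay matches the 820 µs time constant. The same chain run
on the d-peptide and reduced (TCEP) conditions recovers 0.71/0.39/0.43 and
0.53/0.49 respectively.

For classification, each peptide's PC2 population is summarized by a
Gaussian band; `monte_carlo_classify` labels mixture events deterministically
where only one band applies and by a density-proportional draw in the
overlap, and `evaluate_confusion` / `estimate_mixture_ratio` quantify the
result.

## Scope

The package analyzes (simulated or user-supplied) current traces; it does
not model pore–peptide physics, voltage/salt dependence, conformational
kinetics, or multi-level event substructure. External traces can be
supplied as raw float32 + JSON sidecar or as (time_s, current_pA) CSV.
See `docs/methods.md` for the model conventions, parameter defaults and
known limitations.
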