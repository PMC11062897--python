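# tundratrack

Seasonal habitat selection and fall-relocation analysis for Arctic tundra
telemetry, exercised end-to-end on synthetic landscapes and ground-truthed
trajectories.

Arctic hares (*Lepus arcticus*) in the High Arctic polar desert hold a
summer range, and most individuals then travel on the order of 100 km in
fall — alternating multi-day stopovers with directional traveling bouts —
before settling on a winter range. `tundratrack` re-implements the full
computational chain used to study this system from Argos satellite
telemetry:

1. **Telemetry cleaning** — a forward-sweep speed filter (5 km/h cruising,
   10 km/h bursts under 10 min), best fix per day by Argos error class
   (3 > 2 > 1 > A, nominal radii 250/500/1500 m), movement-rate phase
   segmentation (summer / relocation / winter), and daily regularization
   by interpolation.
2. **Home ranges and the availability null model** — 100% adaptive local
   convex hulls (a-LoCoH) for individuals with stable area-observation
   curves (n > 50), seasonal availability domains (pooled 100% MCP
   dilated by the mean-individual-MCP radius, minus water), and random
   home ranges obtained by rigidly translating and rotating each observed
   range across the domain (used:available 1:5 in summer, 1:10 in
   winter).
3. **Habitat-selection functions (HSF)** — logistic regression of used vs
   available ranges on standardized terrain covariates (mean/sd SAVI,
   elevation, slope, arc-chord-ratio rugosity, aspect-class proportions),
   Spearman pruning at |ρ| > 0.7, all-subsets AICc ranking with evidence
   weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2), the ΔAICc < 2 support rule,
   the 85%-CI uninformative-parameter screen, VIF ≤ 5 checks, and log
   relative selection strength (log-RSS) effect curves.
4. **Path segmentation** — a two-state hidden Markov model with gamma
   step lengths and wrapped Cauchy turning angles, fitted by direct
   numerical likelihood maximization from ten random starts, compared
   against a one-state control by AIC, checked with one-step-ahead
   pseudo-residuals, and decoded with the Viterbi algorithm
   (stopover vs travel).
5. **Latent selection difference (LSD)** — mixed-effect logistic
   regression (random intercept per individual, adaptive Gauss–Hermite
   quadrature with 15 nodes) contrasting stopover (1) against traveling
   (0) locations through error-radius buffers, including the
   SAVI × elevation interaction, with bootstrap ROC AUC (999 resamples
   within individuals) as goodness of fit.

The synthetic-data module is first-class: it generates landscapes
(vegetation index with patch-mosaic heterogeneity, correlated relief,
lakes) and trajectories with known behavioral states and known selection
effects, so every stage of the chain is testable against ground truth
without any download.

## Worked example

```python
from tundratrack.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=1), "runs/demo")
r = summary["residency"]["summer"]
print(f"stable summer ranges: {r['n_used']}, "
      f"area {r['used_area_km2_mean']:.1f} ± {r['used_area_km2_sd']:.1f} km²")
print("summer retained model:", r["retained_model"])
h, l = summary["hmm"], summary["lsd"]
print(f"HMM AIC 2-state {h['aic_2state']:.1f} vs 1-state {h['aic_1state']:.1f}")
print(f"stopover share {h['stopover_fraction']:.2f}, "
      f"LSD AUC {l['auc_mean']:.2f} ± {l['auc_sd']:.2f}")
```

prints, for seed 1:

```
stable summer ranges: 15, area 9.3 ± 3.1 km²
summer retained model: Elevation_mean
HMM AIC 2-state 6350.8 vs 1-state 6948.1
stopover share 0.64, LSD AUC 0.58 ± 0.02
```

Summer ranges average ~9 km² and selection is driven by (low) elevation —
the effect designed into the generator; the two-state movement model
clearly beats the one-state control; about two thirds of decoded
relocation locations are stopovers; and the retained LSD model carries a
positive vegetation-heterogeneity effect on stopping (odds ratio
1.22, 95% CI 1.05–1.42 in this run). The same pipeline is available from
the shell:

```bash
tundratrack run --seed 1 --out runs/demo
tundratrack report runs/demo
```

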