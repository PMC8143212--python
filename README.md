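# atgdyn

Kinetic modeling and time-course analysis of ATG13 punctum dynamics during
autophagy initiation.

When autophagy is induced, the ULK kinase complex (read out here through its
ATG13 subunit) translocates to the forming autophagosomal structure and then
leaves it. In live imaging this appears as a punctum whose fluorescence
rises and falls. `atgdyn` implements and analyzes two regimes of this
process:

* **Nonselective (starvation-induced) autophagy** — a single pulse of ATG13
  accumulation. Six ODE variants of the minimal model

  ```
  dA/dt = kprodATG13 * A^m  -  kremATG13 * A
  ```

  differ in whether a discrete event at time `t` switches the punctum from
  pure accumulation to pure removal (variants 1–3) or both reactions run
  simultaneously (variants 4–6), and in which reaction the PI3K inhibitor
  wortmannin down-regulates by a factor `kwrtm` (accumulation / removal /
  both). The partial order `m` captures cooperativity of aggregation on the
  already aggregated complex.

* **Ivermectin-induced mitophagy** — repeated ATG13 translocations to one
  mitochondrial fragment. A hybrid stochastic model runs aggregation cycles
  (per-cycle time-to-peak `t ~ Normal`), accumulates LC3 at `kprodLC3 * A`
  as a proxy for engulfment coverage, waits `kpeak * k^p` after cycle `k`,
  and terminates once cumulative LC3 reaches `engulf_coeff * MT_diam` for
  the sampled fragment diameter. The model predicts that the number of
  ATG13 peaks grows linearly with the diameter of the engulfed fragment.

Around the models sit the supporting analyses a study of this kind needs:
a trace-processing pipeline (peak synchronization, spline-assisted
alignment, irregularity filtering, ≥3-repeat trimming, photobleaching
regularization, peak/trough trains), normal-vs-log-normal classification of
peak times (Shapiro–Wilk, Q–Q, skewness/kurtosis), multi-start global
estimation with best-75% retention, AIC ranking of the six variants,
profile-likelihood identifiability at 66/95/99%, the two-stage mitophagy
calibration, and a synthetic-data generator that emulates the imaging data
(which are not publicly deposited) with known ground truth.

## Worked example

Simulate a 17-event mitophagy population at the fitted kinetic parameters
and check the predicted count–diameter relation:

```python
from atgdyn import (MitophagyParams, simulate_mitophagy_population,
                    correlate_counts_diameters)

params = MitophagyParams()          # fitted kinetics + delay law
events = simulate_mitophagy_population(17, params, seed=1)
counts = [e.n_peaks(910.0) for e in events]   # peaks by the 910 s endpoint
diams  = [e.mt_diam for e in events]
corr = correlate_counts_diameters(counts, diams)
print(counts)
print(f"Pearson r = {corr.r:.2f} (p = {corr.p_value:.1e}); "
      f"slope = {corr.slope:.2f} peaks/um")
```

prints

```
[6, 7, 7, 2, 5, 6, 5, 5, 7, 5, 6, 5, 3, 6, 5, 7, 6]
Pearson r = 0.85 (p = 1.4e-05); slope = 3.32 peaks/um
```

Larger fragments need more aggregation cycles before the LC3 budget covers
them, so the peak count tracks the sampled diameter — the model's headline
prediction.

The same functionality is exposed as a command-line tool:

```sh
atgdyn synth             --outdir fx  --seed 1      # synthetic fixtures
atgdyn fit-nonselective  --input fx/nonselective_traces.csv \
                         --outdir fit --seed 1      # 6 variants + AIC table
atgdyn fit-mitophagy     --input fx/mitophagy_traces.csv \
                         --diameters fx/diameters.csv --outdir mfit --seed 1
atgdyn simulate-mitophagy --outdir sim --seed 1 --n 17
atgdyn analyze-traces    --input fx/nonselective_traces.csv --outdir rep
```

Every run writes a `manifest.json` so it can be reproduced bit-identically.

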