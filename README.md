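# dropqs

Quantitative analysis of cytokine secretion by macrophages in droplet
microfluidics: Poisson cell-encapsulation statistics, a multi-cell droplet
IL-10-sharing model, titration-curve-based absolute cytokine quantification,
and density/time-course secretion kinetics — with a synthetic-data generator
so the whole pipeline runs and is testable without biological material.

## The problem

Only a minority (~10%) of LPS-stimulated human macrophages secrete the
anti-inflammatory cytokine IL-10, while essentially all secrete TNFα. When
several cells are co-encapsulated in a droplet, IL-10 from a producer is
captured by its neighbours, so the fraction of IL-10-*positive* cells grows
with droplet occupancy. `dropqs` implements the statistics of that
experiment for people analysing droplet secretion assays:

* **Occupancy.** Cells load into droplets at random, so the number of cells
  per droplet is Poisson with mean *a* = concentration × droplet volume
  (e.g. 2.5×10⁶ cells/mL in ~0.8 nL droplets → *a* ≈ 2). The package
  computes the truncated Poisson terms, simulates encapsulation, and
  chi-square-tests an observed occupancy histogram against the expectation.

* **Sharing model.** With producer fraction *b*, the quadratic-weight
  prediction of the percent of IL-10⁺ cells is

  ```
                Σₖ₌₁³⁰ (aᵏ e⁻ᵃ / k!) · b · k²
  %IL-10⁺ = ───────────────────────────────── × 100
                Σₖ₌₁³⁰ (aᵏ e⁻ᵃ / k!) · k
  ```

  which collapses (untruncated) to 100·*b*·(1+*a*) and can exceed 100% —
  each of the *b·k* expected producers is credited with converting all *k*
  cells, double-counting droplets with two or more producers. The package
  evaluates this formula verbatim (capped at 100% by default), alongside
  the exact expectation under the same mechanism,
  100·Σₖ p(k)·k·(1−(1−b)ᵏ) / Σₖ p(k)·k (a droplet is fully positive iff it
  holds ≥1 producer), and a Monte-Carlo droplet simulator. The quadratic
  formula upper-bounds the exact model; the gap vanishes as b → 0.

* **Quantification.** A titration curve (monotone MFI ↔ concentration
  mapping, log-log interpolating or four-parameter logistic) converts
  per-cell fluorescence to absolute cytokine amounts; ELISA concentrations
  are normalized by sample volume and cell count to pg per 10⁵ cells.

* **Kinetics.** Finite-difference production rates per time interval, with
  negative rates flagged as clearance; per-donor maximum normalization; and
  a shutoff time (earliest time the course reaches 95% of its final amount)
  that quantifies how higher cell density shortens the production window.

## Worked example

```python
import dropqs as dq

for a in (2, 4, 8, 12):
    q = dq.fraction_positive_quadratic(dq.SharingParams(a=a, b=0.10))
    e = dq.fraction_positive_exact(dq.SharingParams(a=a, b=0.10))
    sim = dq.simulate_sharing(dq.SharingParams(a=a, b=0.10), 100_000, seed=1)
    print(f"a={a:>2}  model {q.fraction_positive:6.1f}% "
          f"(uncapped {q.uncapped_value:6.1f}%)   exact {e.fraction_positive:5.1f}%   "
          f"simulated {sim.fraction_positive:5.1f}% ± {sim.standard_error:.2f}")
```

prints

```
a= 2  model   30.0% (uncapped   30.0%)   exact  26.3%   simulated  26.5% ± 0.18
a= 4  model   50.0% (uncapped   50.0%)   exact  39.7%   simulated  39.6% ± 0.18
a= 8  model   90.0% (uncapped   90.0%)   exact  59.6%   simulated  59.6% ± 0.16
a=12  model  100.0% (uncapped  130.0%)   exact  72.9%   simulated  72.9% ± 0.14
```

At ~2 cells/droplet the formula and the exact mechanism nearly agree
(30% vs 26%); by ~8–12 cells/droplet the formula predicts (near-)saturation
while the exact expectation — and any data generated under the actual
sharing mechanism — sits far below it. That widening gap is the
double-counting of multi-producer droplets, and it mirrors how measured
positivity plateaus while the model runs to 100%.

The same API drives the command line:

```bash
dropqs predict-fraction --a 2 --a 8 --b 0.1 --model quadratic
dropqs generate --what timecourse --seed 1 --out synth/
dropqs rates --in synth/timecourse.csv --out synth/rates.csv
dropqs run --seed 1 --out pipeline_out/   # full synthetic pipeline + manifest
```

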