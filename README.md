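# nephrops-growth

Growth estimation for the Norway lobster, *Nephrops norvegicus*, from
tag-recapture and catch length-frequency data.

Nephrops cannot be aged directly: the exoskeleton is shed at each moult, so
there are no verified age structures, and growth is episodic — carapace
length (CL) is constant between moults and jumps at ecdysis. Stock
assessment nevertheless needs the von Bertalanffy growth function (VBGF)
parameters

    L(t) = L∞ · (1 − e^(−k (t − t₀)))

where `L∞` is the asymptotic carapace length (mm) and `k` (yr⁻¹) the rate at
which it is approached. Because `L∞` and `k` are strongly confounded when
fitted jointly, this package estimates them from independent data sources,
the approach used in tag-recapture studies of lightly exploited inshore
populations:

* **Powell–Wetherall plot** (`powell_wetherall`): for cutoff lengths `L′`
  over the fully recruited range of a catch length-frequency sample, the
  mean length above the cutoff satisfies `L̄ − L′ = a + b·L′` under steady
  state (constant recruitment, exponential total mortality `Z`, VBGF
  growth). OLS gives `L∞ = −a/b` and, as a by-product, `Z/k = −(1+b)/b`.
* **Forced Gulland–Holt plot** (`forced_gulland_holt`): each tag return
  contributes an annualized increment rate `ΔL/Δt` at mean length
  `L̄ = (L₁+L₂)/2`; with `L∞` fixed from the previous step, least squares
  through the point `(L∞, 0)` gives `k = Σ rᵢxᵢ / Σ xᵢ²` with
  `x = L∞ − L̄`. Returns from different liberty periods can be pooled
  (`pool_and_estimate`).
* **Moult-frequency inference** (`increment_analysis`): increment
  histograms, classification of increments into moult-count modes,
  one- vs two-moulter starting-size comparison (t test), wild vs captive
  growth (Mann–Whitney), starting size vs increment (Spearman), and moult
  detection in captive monthly CL series (a sustained increase > 0.5 mm).
* **Conversions** (`conversions`): CL→total-length (linear) and CL→weight
  (allometric) for biomass and economic summaries.
* **Individual-based simulator** (`growth_sim`): a synthetic population
  with stepped (moult-quantized) growth under a sex-specific VBGF envelope,
  seasonal moult timing, size-dependent male double-moulting, truncated-
  normal liberty periods and 0.1-mm measurement rounding, plus steady-state
  catch sampling — so the whole pipeline can be exercised and validated
  with no external data.

## Worked example

Simulate a population with male envelope (L∞ = 70.8 mm, k = 0.161 yr⁻¹) and
female envelope (55.2 mm, 0.077 yr⁻¹), then run the full estimation
pipeline:

```python
import nephrops_growth as ng
from nephrops_growth.io_interface import RunConfig, run_pipeline, format_report

cfg = RunConfig(sim=ng.SimConfig(seed=1), n_tags=2000, n_catch=20000, seed=1)
print(format_report(run_pipeline(cfg)))
```

```
Nephrops growth estimation report
seed: 1
records: 2000 (kept 1827)
dropped: {'non-positive growth': 173}
-- sex M (n=966)
   Powell-Wetherall: L_inf = 70.53 mm (a=23.795, b=-0.3374, Z/k=1.96, r^2=0.9997, 16 points)
   forced Gulland-Holt: k = 0.1683 yr^-1 (n=966)
   overall mean increment: 5.43 mm CL
   moult modes: {'1 moult': 502, '2 moults': 433, '>=3 moults': 20, 'unclassified': 11}
-- sex F (n=861)
   Powell-Wetherall: L_inf = 55.30 mm (a=18.089, b=-0.3271, Z/k=2.06, r^2=0.9996, 9 points)
   forced Gulland-Holt: k = 0.0744 yr^-1 (n=861)
   overall mean increment: 1.56 mm CL
   moult modes: {'1 moult': 861, '2 moults': 0, '>=3 moults': 0, 'unclassified': 0}
```

Reading the output: animals recaptured before their next moult show no
growth and are dropped (the `non-positive growth` audit). The
Powell–Wetherall regression on the steady-state catch sample recovers each
sex's asymptotic length to well under 1%; the forced Gulland–Holt fit on
the tagging increments recovers `k` within a few percent. About half of the
males fall in the two-moult increment mode (5.50–8.49 mm) while females
moult once a year, which is why the male mean annual increment (~5.4 mm CL)
is several times the female one (~1.6 mm CL).

The same operations are available from the shell:

```sh
nephrops-growth simulate --seed 1 --n-tags 2000 --n-catch 20000 --out-dir out/
nephrops-growth estimate linf --lf out/length_frequency.csv --sex M --recruit-length 38
nephrops-growth estimate k --tags out/tag_records.csv --linf 70.8 --sex M --pool-years
nephrops-growth tables --tags out/tag_records.csv --sex M --year 1
```

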