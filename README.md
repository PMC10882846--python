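# stpanel

Spatial-temporal panel analysis of disease prevalence for epidemiologists
working with administrative-unit panels (e.g. provincial chronic-disease
comorbidity prevalence observed at a few survey waves). The package covers
the standard workflow end to end:

1. **Spatial autocorrelation** — global Moran's I and Getis-Ord General G
   with analytic (randomization) or seeded permutation inference; local
   Moran (LISA) with Anselin HH/LL/HL/LH classification; Getis-Ord Gi\*
   hot/cold-spot z-scores binned at the 90/95/99% levels.
2. **Spatial weights** — queen/rook contiguity from polygons, k-nearest
   neighbours and inverse-distance weights on great-circle distances, row
   standardization, islands handled explicitly.
3. **Varying-coefficient regression** — OLS with VIF/tolerance collinearity
   screening, and the local family GWR / TWR / GTWR sharing one weighted
   least-squares engine, with adaptive bandwidths selected by corrected AIC
   (AICc) and a searched space-time metric ratio τ.
4. **Synthetic panels** — lattice study areas, SAR-clustered fields,
   varying-coefficient panels with known β surfaces, and individual-level
   comorbidity records, so every stage is verifiable without restricted
   survey microdata.

## The model

At each observation *i* with planar coordinates (*u_i*, *v_i*) and time
*t_i*, the local model is

    y_i = β₀(u_i, v_i, t_i) + Σ_k β_k(u_i, v_i, t_i) · x_ik + ε_i,  ε_i ~ N(0, σ²)

estimated by weighted least squares, β̂(i) = (XᵀW_iX)⁻¹XᵀW_i y, with kernel
weights decaying in the space-time metric d²_ST = Δu² + Δv² + τ·Δt²
(τ in km²/yr²; τ = 0 gives GWR, a purely temporal metric gives TWR). The
adaptive bandwidth at *i* is the distance to its q-th nearest observation;
q and τ are chosen by minimising

    AICc = 2n·ln(σ̂) + n·ln(2π) + n·(n + tr S)/(n − 2 − tr S),   σ̂² = RSS/n,

where tr S, the hat-matrix trace, is the effective number of parameters.
The same AICc definition (tr S = k+1) is applied to OLS so all four models
are ranked on one scale; a gap above 3 is treated as meaningful.

## Worked example

```bash
python examples/04_model_comparison_gtwr.py
```

```
collinearity screen: max VIF = 1.116, min tolerance = 0.896

 model        R2     AdjR2       AICc       RSS
   OLS    0.4251    0.3891    -235.60    0.8375
   GWR    0.8915    0.8516    -359.24    0.1580
   TWR    0.6444    0.5759    -260.82    0.5180
  GTWR    0.9550    0.9305    -420.40    0.0656
best by AICc: GTWR (margin 61.2)

GTWR vs true PM2.5 coefficient surface: corr = 0.987
mean |error|: GTWR 0.00059  OLS 0.00142
```

The VIF screen passes (all VIF < 5, tolerances > 0.3), so the regressors
can be used together. On the reference synthetic panel — whose true PM2.5
coefficient varies across space and time — GTWR attains the highest R² and
the lowest AICc by far more than the meaningful margin of 3, and its local
coefficient estimates correlate 0.99 with the generating surface while the
single OLS coefficient has 2.4× the mean absolute error. The other
examples (`examples/0*.py`) demonstrate panel simulation, global and local
autocorrelation, and individual-record aggregation.

A config-driven pipeline is also available from the shell:

```bash
stpanel simulate --seed 20240222 --out examples/data
stpanel run-all --config examples/config.yaml
```

producing per-year autocorrelation tables, LISA/Gi\* exports (CSV +
GeoJSON), the VIF table, the model comparison and local-coefficient
exports, all reproducible byte-for-byte from the config and seed.

## Layout

- `src/stpanel/` — library modules: `panel` (data model and I/O),
  `weights`, `autocorr`, `regression`, `synthetic`, `pipeline`, `cli`
- `examples/` — one short narrative script per capability
- `tests/` — pytest suite including brute-force formula oracles,
  enumeration-based moment checks and simulation-based recovery tests
- `docs/methods.md` — modelling assumptions, parameter choices and
  limitations
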