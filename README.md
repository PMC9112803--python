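# foldkin

Chevron-plot global fitting and Φ-value analysis for proteins that fold
through a **high-energy on-pathway intermediate** — the three-state scenario
in which the rate-limiting step switches from an early (TS1) to a late (TS2)
transition state as denaturant increases, producing a kink in the unfolding
arm of the chevron plot. The package was built around the folding study of
the C-terminal SH2 domain of the phosphatase SHP2 (wild type plus 29
conservative point mutants) and ships that study's per-variant parameter
table as a packaged verification dataset.

It is aimed at experimental folding groups who collect stopped-flow
fluorescence kinetics and want a scriptable, tested replacement for
spreadsheet/GraphPad workflows: from raw single-exponential traces to
Φ-values, Tanford β values, LFER α slopes and Hammond plots, with a
synthetic-data generator so every stage can be validated against known
ground truth.

## The model

Each mixing experiment relaxes as a single exponential,
F(t) = F∞ + A·exp(−k_obs·t). The observed rate versus urea follows

```
            k_f⁰ exp(−m_f[urea]/RT) + k_u⁰ exp(m_u[urea]/RT)
k_obs =    ─────────────────────────────────────────────────
                 1 + K_part exp(m_part[urea]/RT)
```

where `K_part` is the partitioning constant between TS1 and TS2 and
`m_part` its denaturant dependence; `K_part = 0` recovers the classical
two-state chevron. Chevrons of all variants are fitted **jointly** in
log₁₀ k_obs, sharing m-values across variants (fully shared for the main
analysis; per-variant m_f/m_u with shared m_part for Hammond analysis).

From the fitted constants, for each mutant relative to wild type:

* ΔΔG_D-TS1 = RT·ln(k_f^wt/k_f^mut), ΔΔG_TS1-N = RT·ln(k_u^mut/k_u^wt),
  ΔΔG_TS2-N = RT·ln[(k_u/K_part)^mut/(k_u/K_part)^wt],
  ΔΔG_eq = RT·ln[(k_f/k_u)^wt/(k_f/k_u)^mut]
* Φ_TS1 = ΔΔG_D-TS1/ΔΔG_eq and Φ_TS2 = 1 − ΔΔG_TS2-N/ΔΔG_eq, with mutants
  below |ΔΔG_eq| = 0.4 kcal/mol excluded
* β_TS1 = m_f/(m_f+m_u) and β_TS2 = 1 − (m_u−m_part)/(m_f+m_u)

RT defaults to 0.5925 kcal/mol (25 °C). See `docs/methods.md` for the
assumptions, defaults and numerical choices.

## Worked example

```python
import numpy as np
import foldkin as fk

# packaged reference table: wild type + 29 mutants
fixture = fk.load_table1()
rec = fk.recompute_table1(fixture).set_index("variant")
print("L117A: ddG_TS1-N = %.2f kcal/mol, Phi_TS1 = %.2f, Phi_TS2 = %.2f"
      % (rec.loc["L117A", "ddG_TS1N_rec"],
         rec.loc["L117A", "phi_ts1_rec"],
         rec.loc["L117A", "phi_ts2_rec"]))

# synthetic ensemble with known truth -> global fit -> Phi recovery
spec = fk.EnsembleSpec(n_variants=10, urea_grid=np.linspace(0, 9, 25),
                       noise_sd_log=0.02, seed=1)
datasets, truth = fk.simulate_ensemble(spec)
result = fk.global_fit(datasets, "shared_all_m", seed=0)
print("shared m-values:", {k: round(v, 3) for k, v in result.shared.items()})
```

prints

```
L117A: ddG_TS1-N = 1.64 kcal/mol, Phi_TS1 = 0.30, Phi_TS2 = 0.51
shared m-values: {'mf': 0.812, 'mu': 0.519, 'mpart': 0.445}
```

The L117A line reproduces the published values (1.65 ± 0.15 kcal/mol,
Φ_TS1 = 0.31 ± 0.13, Φ_TS2 = 0.50 ± 0.12) from the printed rate constants
alone. The second line shows the joint fit recovering the generator's true
shared m-values (0.81, 0.52, 0.45 kcal/mol/M) from 2%-noise chevrons.

The same pipeline is available from the shell:

```bash
foldkin simulate --seed 1 --n-variants 29 --out-chevrons chev.csv --out-truth truth.csv
foldkin global-fit --input chev.csv --scheme shared_all_m --seed 0 --out fit.json
foldkin phi --input fit.json --out phi.csv
foldkin lfer --input phi.csv --out lfer.json
foldkin validate-table1
```

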