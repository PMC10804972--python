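# ricegas

Farm-scale greenhouse-gas accounting for four fates of rice straw — open
**burning**, in-situ **incorporation**, **livestock fodder** with partial
manure return, and **biochar** — across dry, median and wet field-hydrology
categories, for rice–wheat rotation systems of the kind found in the
Eastern Indo-Gangetic Plain.

## Who this is for

Agroecosystem modellers and LCA practitioners who need to (a) turn daily
field water-tube observations into hydrology categories and long-run
water-table input files for a process-based soil model (DNDC-style "water
table mode"), and (b) combine the model's annual soil CH4 / N2O / SOC
outputs with IPCC Tier-1/2 non-soil accounting into net CO2-equivalent
results per hectare-year. The soil biogeochemistry model itself is external;
a seeded synthetic generator stands in for both its outputs and the field
observations so the whole pipeline is testable offline.

## The accounting

The functional unit is the residue from 1 ha of rice (grain yield
*Y* = 3.77 t/ha, straw ratio *R* = 1.5, dry-matter fraction *D* = 0.86).
Non-soil fluxes per pathway:

- **Livestock**: enteric CH4 = *Y*m · GE / *E*CH4 with the herd-weighted
  conversion factor *Y*m = 4.74 % of gross energy GE = straw DM × 14.08
  MJ/kg; volatile solids VS = [GE(1−DE) + UE·GE]·(1−ASH)/18.45; storage
  CH4 = VS·*B*o·0.67·MCF and storage N2O = *N*f·VS·EF·44/28 on the full
  stored VS; half the VS fuels cookstoves (Tier-1 EFs 281 / 27 kg per TJ),
  half returns to the field five days before the rice season.
- **Biochar**: C yield fraction *F*by = 0.126 + 0.273·*L*f +
  0.539·e^(−0.004·T) at T = 798.15 K; soil C mass *M*bc = *F*by·*Y*rs·*D*;
  avoided GHG = *M*bc·*F*perm·44/12 with 100-year permanence
  *F*perm = 0.71 (a credit, negative in the tables).
- **Burning**: combusted mass = *Y*·*R*·*D*·*B* with burn efficiency
  *B* = 0.89; CH4 / N2O via 9.59 / 0.48 g/kg; the surviving pyrogenic
  carbon (*P*f = 0.11, on-site fraction *P*r = 0.9895) earns the same
  permanence credit.
- **Incorporation** has no non-soil term.

Gas masses convert to CO2-e with 100-year GWPs (CH4 27.9, N2O 273); the
net soil flux per category is the horizon-mean CH4 + N2O CO2-e minus the
mean annual SOC change × 44/12. Totals are soil + non-soil per pathway ×
category, compared against burning as the reference.

## Worked example

```python
>>> from ricegas import load_params, livestock_pathway, biochar_pathway
>>> p = load_params()                      # study defaults
>>> inv = livestock_pathway(p)
>>> round(inv.co2e_Mg, 3)                  # Mg CO2-e per ha-year, non-soil
2.215
>>> {k: round(v, 3) for k, v in inv.component_co2e().items()}
{'enteric_ch4': 1.627, 'storage_ch4': 0.203, 'storage_n2o': 0.158,
 'cookstove_ch4': 0.117, 'cookstove_n2o': 0.11}
>>> bc = biochar_pathway(p)
>>> round(bc.fby, 4), round(bc.avoided_MgCO2e, 3)
(0.197, 2.494)
```

Enteric fermentation dominates the livestock pathway's 2.2 Mg CO2-e/ha/yr;
the biochar pathway's 2.5 Mg credit is what makes it the lowest-emission
fate in every hydrology category. From the shell:

```bash
ricegas livestock                 # per-component non-soil fluxes, CSV
ricegas biochar --set pyrolysis_T_K=723.15
ricegas synth flux --category wet --residue --out wet.csv
ricegas soil summarize --in wet.csv
ricegas water-input --observations obs.csv --n-years 100 --seed 1 --out wt/
```

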