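# ocuperm

Ocular permeability route prediction and carbonic anhydrase selectivity
profiling for topical drug candidates.

## The problem

Topically applied anti-glaucoma drugs reach the ciliary body by two main
absorption routes: across the cornea, which favours lipophilic solutes, or
across the conjunctiva and sclera, which admit relatively hydrophilic ones.
Hydrophilic carbonic anhydrase II (hCA II) inhibitors are attractive — they
achieve higher tear-fluid concentrations and clear more slowly from
intraocular spaces — but only if the conjunctival route can carry them.
`ocuperm` answers that question quantitatively for a compound series, and
summarises each compound's isoform-selectivity profile from an inhibition
panel.

## The models

Apparent permeability Papp (cm/s) across each barrier is predicted by a
published linear QSPR model on molecular descriptors:

| barrier | model |
|---|---|
| rabbit cornea | log10 Papp = −3.885 − 0.183·HBtot + 0.277·logD(7.4) |
| porcine cornea | log10 Papp = −4.6823 − 0.7670·logPSA − 0.1346·HBd + 3.0024·HR |
| porcine conjunctiva | log10 Papp = −4.1594 − 0.6121·logPSA − 0.0792·HBd + 3.2914·HR |

where HBd/HBtot are hydrogen-bond donor / total hydrogen-bond-former counts,
logD(7.4) the pH 7.4 distribution coefficient, logPSA = log10 of the polar
surface area (Å²), and HR the halogen ratio (halogens over heavy atoms).
Each compound's Papp is divided by a reference drug's (dorzolamide by
default) to give a percent-of-reference per tissue; the **route-shift
index** — conjunctival % over rabbit-corneal % — classifies the dominant
route (index > 1: conjunctival shift relative to the reference).

Selectivity over a Ki panel uses the standard ratio
Ki(off-target)/Ki(target); comparing a compound's ratio with a reference
inhibitor's (ratio of ratios) shows whether selectivity improved.

## Worked example

The packaged fixture tables cover a published series of five hydrophilic
thienyl-oxazole sulfonamide hCA II inhibitors (7a–7e) referenced against
dorzolamide ("1"):

```sh
ocuperm predict --fixture --output profiles.csv
```

prints `wrote 6 profiles to profiles.csv`, and `profiles.csv` reads:

```
compound,rabbit_cornea_Papp_cm_s,rabbit_cornea_pct_of_ref,porcine_cornea_Papp_cm_s,porcine_cornea_pct_of_ref,porcine_conjunctiva_Papp_cm_s,porcine_conjunctiva_pct_of_ref
1,7.79E-06,100,1.75E-07,100,1.86E-06,100
7a,9.68E-07,12,1.71E-07,98,1.83E-06,98
7b,3.27E-07,4,1.20E-07,69,1.47E-06,79
7c,3.76E-07,5,1.18E-07,67,1.45E-06,78
7d,2.68E-07,3,8.29E-08,47,1.17E-06,63
7e,1.68E-07,2,8.29E-08,47,1.17E-06,63
```

Reading: compound 7a keeps only 12% of dorzolamide's rabbit corneal
permeability but 98% of its conjunctival permeability — a route-shift index
of ≈7.9, classified conjunctival. The whole hydrophilic series shifts to the
conjunctival route. The same analysis from the library:

```python
import ocuperm as op

bundle = op.published_fixtures()
profiles = op.build_profiles(
    bundle.molecule_records(), op.builtin_models(),
    reference_id=bundle.reference_id, reference_papp=bundle.reference_papp,
)
lead = profiles[1]            # compound 7a
print(lead.route_shift_index)  # 7.914169527853874
print(lead.dominant_route)     # Route.CONJUNCTIVAL
```

Selectivity on the packaged Ki panel (target hCA II, reference
acetazolamide "3"):

```sh
ocuperm selectivity --fixture --output selectivity.csv
```

The first data row shows the lead compound: Ki(hCA II) = 0.069 nM, hCA I/II
selectivity 58.0 versus acetazolamide's 20.8 (ratio-of-ratios 2.8).

Synthetic inputs for scale or property testing come from the seeded
generators: `ocuperm simulate --kind descriptors --n 100 --seed 1729
--output table.csv`.

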