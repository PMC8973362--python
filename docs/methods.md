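# Methods

## Permeability models

Each tissue model is an affine function of molecular descriptors returning
log10 of the apparent permeability coefficient Papp in cm/s. The three
built-in models (rabbit cornea; porcine cornea; porcine conjunctiva) carry
their published regression coefficients as exact decimal literals; they are
never refit, and no uncertainty is attached because none is published. The
model registry is open: user models load from a JSON config (name,
intercept, descriptor→coefficient map) and may override built-ins, so new
tissues need no code change.

The coefficient signs encode the physical picture the analysis rests on:
permeability falls with hydrogen-bonding capacity (HBd, HBtot) and polar
surface area, rises with lipophilicity (logD) and halogenation, and the
cornea penalises polarity more steeply than the conjunctiva. Monotonicity in
each sign is asserted by tests.

## Descriptors and the supplied/computed merge

Descriptor vectors may be supplied externally (the reproduction path for
published tables, whose values typically come from proprietary calculators)
or computed from structure with deliberately simple, documented definitions:
donors = hydrogens on N or O; acceptors = N and O atoms (S and halogens
excluded by default, overridable); PSA = topological PSA; halogen ratio =
halogens over heavy atoms, hydrogen-invariant by construction. These
computed counts are not expected to match any particular commercial
calculator, which is why supplied values always take precedence in the
merge.

Two rules are canonical:

* **logPSA is always log10(PSA) at full floating precision** whenever PSA is
  present, replacing any supplied (typically 3-decimal) logPSA. Using a
  rounded logPSA of 2.250 instead of log10(177.93) moves a porcine-cornea
  prediction from 8.29E−08 to 8.30E−08 cm/s — a visible error at the 3
  significant figures reports use. A supplied logPSA inconsistent with PSA
  beyond 5·10⁻⁴ is rejected as corrupt input.
* **logP/logD are never estimated internally.** Ionisation-aware
  lipophilicity needs a pKa model, which is out of scope; values come from
  the input table or an injected provider (a `(smiles, pH) → value or None`
  callable). A compound lacking a model's required descriptor gets no value
  imputed: that model's entry is absent, a warning is logged, and the run
  continues — models fail loudly, silently wrong numbers are worse than
  missing ones.

A supplied HBd or HBa invalidates a structure-computed HBtot, which is then
recomputed as the sum; a supplied HBtot that contradicts supplied HBd + HBa
is rejected at construction.

## Route analysis

Percent-of-reference is computed from unrounded Papp values and rounded
half-up only for display. The order matters: display rounding reproduces
published integer percentage columns (e.g. 4.83 → 5 and 3.44 → 3
simultaneously), while the route-shift index — conjunctival
percent-of-reference over rabbit-corneal percent-of-reference — always uses
the unrounded values. Classification uses a multiplicative tie guard of
10⁻⁹ around the threshold (default 1), so a compound exactly as
route-balanced as the reference is indeterminate, not arbitrarily assigned.
Dominance is defined relative to the reference drug rather than as an
absolute conjunctiva/cornea ratio because the scientific question is
comparative: does this compound rely on the conjunctival route more than
the clinical comparator does?

The reference drug's own descriptors are often unpublished; its per-tissue
Papp may therefore be supplied as constants (the packaged fixtures carry
dorzolamide's printed 7.79E−06 / 1.75E−07 / 1.86E−06 cm/s). A reference with
descriptors is recomputed like any other compound. One known divergence is
preserved rather than forced: two porcine-cornea percentage cells of the
packaged expected table print 48 where recomputation from the printed
inputs gives 47.39 → 47, plausibly because the original used an unrounded
reference permeability internally. The fixture flags these two cells as
known-divergent and tests assert the recomputed 47, not the printed 48.

## Selectivity profiling

Selectivity ratio = Ki(off-target)/Ki(target), with the reciprocal identity
ratio(a,b)·ratio(b,a) = 1 as a tested invariant. Ranking by potency is
ascending in Ki with lexicographic tie-break on compound id, and is
invariant under uniform Ki rescaling. The report adds a ratio-of-ratios
column against a reference inhibitor. Assay error bands quoted with Ki
panels (typically ±5–10%) are not propagated into ratio uncertainty: no
error model is published for the ratios, and inventing one would imply
precision the data do not support.

## Synthetic data

The generators emulate the statistical shape of the inputs, not chemistry:
descriptor rows are drawn with HBd ∈ {0..6} and HBa ∈ {0..10} uniform,
PSA ~ U(40, 200) Å², logD(7.4) ~ U(−3, 2), and 0–3 halogens over 10–40 heavy
atoms — an envelope bracketing the packaged hydrophilic series (PSA 155–178,
HBd 3–5, logD −1.84…−0.42) with margin. MW is a crude 13.5 g/mol-per-heavy-
atom proxy, adequate for a field no model consumes. Ki panels are
log-uniform on [0.01, 1000] nM per isoform, with the target isoform divided
by a boost factor so the median off-target/target ratio approaches the
boost. No valid structures are synthesised for generated rows; generated
tables therefore exercise the descriptor-table path, not the SMILES path,
and passing tests on them say nothing about calculator agreement on real
structures. A single integer seed (default 1729) governs all generation;
identical seeds give identical tables.

Problem sizes used in tests: the fixture series (5 compounds + reference)
for all exact reproduction checks; n = 1000 rows for generator invariants;
n = 10⁴ for the median-selectivity calibration check (tolerance ±20%, the
sampling noise of a median over a log-uniform ratio at that n is well
inside it); n = 40 for pipeline closure.

## Numerical choices

* Internal values are never rounded; reports format Papp to 3 significant
  figures in scientific notation (`9.68E-07`) and percentages as half-up
  integers.
* Report CSVs are byte-stable across runs on identical input (no
  timestamps in data files; logs go to stderr).
* Parsing accepts both `1.83E-06` and `1.83e-06` and the typographic minus
  sign `−`; decimal points only, no locale-dependent separators.
* Compound ids are opaque, case-sensitive strings.

## Known limitations

* Computed HBd/HBa/PSA follow the simple definitions above and will differ
  from other calculators; exact reproduction of published tables requires
  supplying the original descriptor values.
* The QSPR models are linear and were fit on small drug-like datasets;
  extrapolation far outside descriptor ranges typical of topical ocular
  drugs (e.g. very high halogen ratios) is unvalidated.
* No pharmacokinetics: tear clearance, melanin binding, dose — out of
  scope. The route classification is a permeability-ratio statement, not an
  absorbed-fraction prediction.
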