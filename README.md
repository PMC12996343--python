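# pepsim

Pepsin activity prediction and in vitro gastric digestion modelling.

Pepsin (EC 3.4.23.1), the stomach's aspartic endopeptidase, has its activity
optimum near pH 2 and 37 °C, but gastric pH and temperature swing widely
after a meal — and in vitro digestion protocols (INFOGEST static and
semi-dynamic) substitute commercial porcine pepsin for the human enzyme.
`pepsim` is a toolkit for researchers running such digestion studies: it
predicts how much proteolytic capacity pepsin actually has under the
pH/temperature conditions of an experiment, compares human versus porcine
enzyme or static versus semi-dynamic protocols by area under the
activity–time curve, simulates total pepsin activity in the stomach over a
meal, and answers the practical question of the minimal heat treatment that
irreversibly inactivates pepsin in collected digesta samples.

## The model

Activity (as a percentage of the pH 2 / 37 °C optimum) is described by a
reduced-cubic response-surface polynomial on the log scale, with
A = pH and B = temperature (°C):

```
log10(activity %) = β0 + βA·A + βB·B + βAB·AB + βAA·A² + βBB·B² + βABB·AB²   [+ βAAA·A³ + βBBB·B³]
```

Two published coefficient sets are built in — a 7-term human surface and a
9-term porcine surface, both fitted over pH 1–7 and 4–60 °C from 37
pH/temperature combinations. Each exists in two variants, because the
published human equation carries an obvious transcription error (its
temperature-linear coefficient, 0.88912, puts the optimum prediction at
10³¹·⁶ %): `as_printed` is faithful to the publication, `corrected` applies
the single documented amendment (0.88912 → 0.088912, restoring ≈100 % at
the optimum). The porcine surface has no defensible single-coefficient fix
(it prints ≈59.5 % at its own optimum), so its recommended output is
`predict_relative` — activity renormalised by the surface's own value at
pH 2 / 37 °C, which is exactly 100 at the optimum by construction.

The package also re-implements the machinery that produces such surfaces
(`pepsim.fitting`): OLS of log10 activity on the monomial basis, the ANOVA
model F-value, adjusted R², Design-Expert-style predicted R²
(1 − PRESS/SS_total via the hat-matrix identity), externally studentized
residual diagnostics, and D-optimal (Fedorov exchange) design selection —
so a user can refit surfaces from their own measurement tables rather than
trust printed coefficients.

The remaining modules: `assay` (INFOGEST unit arithmetic — one unit gives a
ΔA280 of 0.001/min at pH 2, 37 °C), `profiles` (digestion time series →
activity profiles and trapezoidal AUC), `simulator` (well-mixed gastric
compartment: secretion, emptying, pepsin mass balance, with a 40 %
reduced-output older-adult scenario), `thermal` (heat-inactivation retention
table and the 75 °C / 5 min minimal-treatment rule), and `synthetic`
(seeded generators for every input, so everything runs offline).

## Worked example

```python
>>> import pepsim as pp
>>> porcine = pp.builtin_model("porcine", "as_printed")
>>> pp.predict_relative(porcine, 3.0, 37.0)
47.13136306748825
```

At pH 3 and body temperature, porcine pepsin is predicted to retain about
47 % of its optimum activity; the human surface retains 81 % under the same
conditions (`pp.predict_relative(pp.builtin_model("human", "corrected"), 3, 37)`
→ `81.135…`) — the human enzyme keeps its activity over a much broader pH
range. The same queries from the shell:

```
$ pepsim predict --species porcine --variant as-printed --ph 3 --temp 37 --relative
47.1314
$ pepsim predict --species human --ph 3 --temp 37 --relative
note: using the 'corrected' human surface (documented editorial coefficient
amendment applied; pass --variant as-printed for the coefficients exactly as published)
81.1353
```

Simulating a 75 min gastric digestion of a 50 mL / 50 kcal liquid meal with
the default adult parameters (33 mL basal volume, 0.4 mg/mL basal pepsin,
46.8 mg/h pepsin secretion, 1 mL/min fluid secretion, 2 mL/min emptying,
2,000 U/mg) against a semi-dynamic pH descent from 6 to 2:

```python
>>> from pepsim import GastricParams, simulate
>>> from pepsim.synthetic import GeneratorSpec, generate_ph_curve
>>> curve = generate_ph_curve(GeneratorSpec(seed=11), duration=75, start_ph=6, end_ph=2)
>>> adult = simulate(GastricParams(), curve, porcine)
>>> older = simulate(GastricParams(output_reduction=0.4), curve, porcine)
>>> round(adult.peak_units), adult.peak_time, round(adult.auc_units / older.auc_units, 3)
(28111, 52.0, 1.667)
```

Total activity rises to a single peak (here ≈28,000 U at 52 min) as acid
secretion drives pH toward the optimum, then falls as emptying outpaces
secretion; the 40 % reduced-output older-adult run is exactly 0.6× the
adult trajectory, so the adult cumulative activity (AUC) is 1/0.6 ≈ 1.67×
larger.

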