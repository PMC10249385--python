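# gcretention

Temperature-independent retention parameters for gas chromatography:
determination from isothermal measurements, conversion between the three
standard parameterizations, quality validation, database storage, and
prediction/simulation of temperature-programmed separations.

## Who this is for

Method developers and analytical chemists who want to predict retention
times, elution orders, and resolution on capillary GC columns without
running every candidate temperature program. Once the substance- and
phase-specific retention parameters of the analytes are known, a separation
on any column geometry, carrier-gas condition, and oven program can be
simulated in milliseconds.

## The models

The partition of a solute between the stationary (liquid) and mobile (gas)
phase is captured by the distribution coefficient *K* = *k*·β, where *k* is
the retention factor measured from the chromatogram, *k* = (t_R − t_M)/t_M,
and β = d/(4·d_f) is the phase ratio of the column. Three equivalent
three-parameter models describe ln *k*(T):

**Clarke–Glew (ABC) model.** With T₁ = 1 K,

    ln K(T) = A + B/T + C·ln(T/T₁),      ln k = ln K − ln β

(the *A* coefficient parameterizes the distribution coefficient; the nominal
phase ratio β₀ converts to the retention factor).

**K-centric model (Blumberg).** Parameters with direct chromatographic
meaning: the characteristic temperature T_char where ln k = 0 (solute evenly
split between the phases), the characteristic thermal constant θ_char (a
θ_char rise in temperature near T_char cuts *k* by a factor of *e*), and the
heat-capacity change ΔC_p:

    ln k(T) = (ΔC_p/R + T_char/θ_char)·(T_char/T − 1) + (ΔC_p/R)·ln(T/T_char)

**Thermodynamic model.** Transfer enthalpy ΔH_ref and entropy ΔS_ref at a
reference temperature T_ref (90 °C by convention) with ΔC_p compensating
their temperature dependence.

All pairwise conversions are exact algebra except ABC → K-centric, which
locates T_char in closed form on the real −1 branch of the Lambert W
function,

    x = −(B/C)·exp((A − ln β₀)/C),   T_char = −(B/C) / W₋₁(x),

valid exactly when −1/e < x < 0 — one of the validation criteria applied to
every database entry (alongside A < 0, C > 0, 0 < θ_char < 100 K, a minimum
of three fitted points, and the fitted ln k range −2.0…3.5).

Void times follow from compressible laminar flow,
t_M = (128 η L²/3d²)·(p_i³ − p_o³)/(p_i² − p_o²)², and temperature-programmed
retention times from integrating the solute migration
dz/dt = u(z,t)/(1 + k(T(t))) along the column.

## Worked example

```python
from gcretention import *
from gcretention.constants import celsius_to_kelvin
from gcretention.dbio import read_db, complete_entry, example_db_path

entries = {e.name: e for e in read_db(example_db_path())}
abc = entries["cinnamaldehyde"].abc           # A=-82.062, B=10505 K, C=10.503, beta0=250

th = abc_to_thermo(abc, celsius_to_kelvin(90.0))
kc, lam = abc_to_kcentric(abc)
print(f"dHref = {th.dHref:.1f} J/mol, dSref = {th.dSref:.3f} J/(mol K)")
print(f"Tchar = {kc.Tchar - 273.15:.2f} C, thetachar = {kc.thetachar:.2f} K")
```

prints

```
dHref = -55630.7 J/mol, dSref = -80.199 J/(mol K)
Tchar = 174.29 C, thetachar = 34.49 K
```

i.e. cinnamaldehyde's evaporation from this 75%-phenyl phase costs
55.6 kJ/mol at 90 °C, and at 174.3 °C the compound is evenly distributed
between the phases. Simulating a three-ramp program (70 °C, 20 °C/min to
150 °C hold 5 min, 12 °C/min to 250 °C hold 2 min, 15 °C/min to 360 °C) on a
30 m × 0.25 mm × 0.25 µm column at 1 mL/min helium:

```python
col  = ColumnSpec(L=30.0, d=0.25e-3, df=0.25e-6)
flow = FlowConditions(gas="helium", mode="flow", flow=1e-6/60, p_o=101325.0)
prog = TemperatureProgram(T_init_C=70.0,
                          segments=((20.0, 150.0, 5.0), (12.0, 250.0, 2.0), (15.0, 360.0, 5.0)))
sel = ["limonene", "linalool", "cinnamaldehyde", "geraniol"]
params = {n: complete_entry(entries[n]).kcentric for n in sel}
for p in simulate_retention(params, col, prog, flow).peaks:
    print(f"{p.name:16s} tR = {p.tR_min:7.3f} min   Telu = {p.Telu_C:6.1f} C")
```

```
limonene         tR =   3.640 min   Telu =  142.8 C
linalool         tR =   4.194 min   Telu =  150.0 C
geraniol         tR =   5.792 min   Telu =  150.0 C
cinnamaldehyde   tR =   7.960 min   Telu =  150.0 C
```

— the four fragrance compounds elute in order of their characteristic
temperatures, three of them during the 150 °C hold.

Fitting works statsmodels-style: build an `IsothermalRetentionModel` from a
dataframe or an `IsothermalSeries`, call `.fit()` (or `.fit_robust()` for
trimmed fitting with outlier identification), and read estimates, standard
errors, and residuals off the returned `RetentionFitResults`
(`results.summary()` prints a table).

The same workflow is scriptable from the shell:

```sh
gcretention synth --mode isothermal --n 3 --sigma 0.02 --out iso.csv
gcretention fit iso.csv --out fitted.csv
gcretention validate fitted.csv
gcretention holdup --length-m 30 --diameter-mm 0.25 --film-um 0.25 --temp-c 50 --flow-ml-min 1
```

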