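# cardioprofile

In-silico profiling of drug-induced arrhythmogenic risk in single cardiac
cells.

hERG-block assays alone misclassify torsadogenic risk: QT/APD prolongation
is neither necessary nor sufficient for the cellular arrhythmia trigger
(early afterdepolarizations, EADs), and multichannel block can mask or
unmask it. `cardioprofile` simulates a family of cardiac action-potential
models — Purkinje (P), endocardial (Endo), mid-myocardial (M) and epicardial
(Epi) — under multichannel Hill pore block at therapeutic concentration
(EFTPC), across physiological pacing rates, and extracts the biomarkers that
discriminate risk:

* APD90 rate adaptation and drug-induced ΔAPD% = 100·(APD90,drug −
  APD90,control)/APD90,control,
* EAD occurrence and onset cycle length (CL),
* AP alternans at fast pacing,
* the dominant depolarizing current of each EAD (I_NaL vs I_CaL).

Drug block is conductance scaling, g → g / (1 + (C/IC50)^h), over the CiPA
channel panel (Nav1.5 peak/late, Cav1.2, hERG, Kv4.3, KCNQ1/KCNE1, Kir2.1);
the integrator is forward Euler with a two-level adaptive step; pacing runs
to a steady-state convergence rule bounded by the 60-minute schedule. The
cell family, the 12-compound CiPA training library and every constant are
shipped as plain-text parameter files. See `docs/methods.md` for the model,
numerics and limitations.

Intended for safety-pharmacology modellers and cardiac-electrophysiology
students who want a fast, fully inspectable single-cell profiling pipeline —
not a replacement for biophysically detailed models.

## Worked example

Profile two compounds in M cells at two cycle lengths:

```python
from cardioprofile import CellType, run_profile, shipped_library
from cardioprofile.pharmacology import get_drug
from cardioprofile.profiling import ProfileConfig

lib = shipped_library()
table = run_profile(
    [get_drug("terfenadine", lib), get_drug("verapamil", lib)],
    [CellType.M], [1000.0, 2000.0],
    ProfileConfig(max_beats=240),
)
print(table.df[["drug", "cl", "apd90_control", "apd90_drug",
                "delta_apd_pct", "ead_flag", "dominant_ead_current"]]
      .to_string(index=False))
```

prints (APDs in ms):

```
       drug     cl  apd90_control  apd90_drug  delta_apd_pct  ead_flag dominant_ead_current
terfenadine 1000.0     395.634057  449.030451      13.496410     False                 None
  verapamil 1000.0     395.634057  414.346329       4.729692     False                 None
terfenadine 2000.0     437.582992  675.821507      54.444190      True                I_CaL
  verapamil 2000.0     437.582992  482.272186      10.212736     False                 None
```

Terfenadine (hERG-dominant block) prolongs the M-cell AP at CL = 1000 ms and
triggers I_CaL-driven EADs at slow pacing, while verapamil — whose Cav1.2
block offsets its hERG block — prolongs the AP without ever triggering an
EAD: APD prolongation alone does not predict the arrhythmia trigger.

The same pipeline is available from the shell:

```bash
cardioprofile profile --drug terfenadine --cell M --grid 300:2000:50 \
    --max-beats 240 --out terfenadine_m.tsv
cardioprofile simulate --cell Purkinje --drug quinidine --cl 2000 \
    --max-beats 240 --out quinidine_p.tsv
cardioprofile analyze quinidine_p.tsv
cardioprofile fixtures drugs --n 12 --seed 1 --out synthetic_library.yaml
```

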