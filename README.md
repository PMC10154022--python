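# crc-disrupt

Microsimulation of **colorectal-cancer (CRC) screening disruptions** and their
long-term cost in life-years, for modellers and screening-policy analysts who
want to quantify how delays, regimen switches, or discontinuation of screening
after a system-wide shock (such as the COVID-19 pandemic) erode the benefit of
an established screening programme.

## What it models

Each simulated person carries an adenoma–carcinoma natural history in
continuous age: adenomas arise from a non-homogeneous Poisson process with a
person-level frailty, grow through the size classes 1–5 mm / 6–9 mm / ≥10 mm,
may transform into preclinical cancer with a size-dependent annual
probability, and surface clinically after a random sojourn time. Other-cause
mortality comes from a bundled Gompertz–Makeham cohort life table. Screening
(decennial colonoscopy ages 50–70, or annual FIT ages 50–75 with diagnostic
colonoscopy after a positive test) detects and removes lesions according to
per-size-class sensitivities; adenoma findings put a person on Multi-Society
Task Force surveillance, with intervals determined by the findings at the two
most recent colonoscopies and a stopping age of 85.

Scenarios follow a `[cohort] | [disruption]` grammar — for example
`C60 | F18m` is a colonoscopy-adherent 60-year-old cohort that permanently
switches to annual FIT with an 18-month delay, and `F70 | U` is a
FIT-adherent 70-year-old cohort that stops screening entirely. Every person's
natural history is drawn once and replayed under each scenario (common random
numbers), so contrasts isolate the disruption effect.

Outcomes are expected life-years per 1000 persons from the beginning of 2020:

- `LY` under the disrupted scenario, `LYNS` under no screening, `LYND` under
  no disruption;
- **life-years lost** `LYL = LYND − LY`, **life-years gained**
  `LYG = LYND − LYNS`, and `%LYLost = 100·LYL/LYG`,

with CRC cases and deaths per 1000, life-days lost per person, Monte-Carlo
standard errors, and min–max ranges across two bundled natural-history
parameterizations (`preset-A`, `preset-B`) that stand in for structurally
different models.

## Worked example

```bash
cat > experiment.yaml <<EOF
scenarios: ["C60 | C18m", "C60 | F18m", "C60 | U"]
n: 20000
seed: 42
sensitivity_scenarios: [high]
presets: [preset-A, preset-B]
output_dir: out
EOF
crc-disrupt run --config experiment.yaml
crc-disrupt report --in out/outcomes.csv --out reports
cat reports/summary_table.csv
```

prints (LY columns per 1000 persons, rounded at report time):

```
scenario,model,sensitivity,LY_ns,LY_nd,LYG,LY,LYG_disrupted,LYL,pct_LY_lost
C60 | C18m,preset-A,high,23914,24241,327,24242,328,-1,0
C60 | F18m,preset-A,high,23914,24241,327,24230,317,11,3
C60 | U,preset-A,high,23914,24241,327,24091,177,150,46
C60 | C18m,preset-B,high,24063,24324,262,24321,259,3,1
C60 | F18m,preset-B,high,24063,24324,262,24301,238,24,9
C60 | U,preset-B,high,24063,24324,262,24194,132,130,50
```

Reading the `preset-A` rows: undisrupted screening gains this cohort 327
life-years per 1000 persons over no screening. An 18-month colonoscopy delay
costs essentially nothing (−1, i.e. zero within Monte-Carlo noise at
n=20,000), switching permanently to FIT costs 11 LY per 1000 (3% of the
screening benefit), and discontinuing screening forfeits 150 LY per 1000 —
46% of the benefit. Across both presets the discontinuation loss spans
130–150 LY per 1000 persons. `out/outcomes.csv` holds the unrounded values
with standard errors; `reports/dotplot_data.csv` holds the loss-per-scenario
dot-plot data (scenarios under 2 life-days lost per person are omitted,
remaining rows sorted by descending loss).

Scenario codes are listed by `crc-disrupt scenarios`; the bundled life table,
presets and sensitivity tables can be written out with
`crc-disrupt fixtures export --dir fixtures/`.

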