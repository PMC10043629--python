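# Preparing the real input tables

The pipeline reads two plain CSV files.  This note records how to derive
them from the published German sources; the package itself never downloads
or parses the published spreadsheet layouts.

## Prevalence CSV

Schema: `year,sex,age_lo,age_hi,n_care,n_pop[,prevalence]`, UTF-8, one row
per (year, sex, age group); blank `age_hi` marks the open-ended top group;
`sex` is `female` or `male`.

Source: the biennial long-term-care statistics ("Pflegestatistik — Pflege im
Rahmen der Pflegeversicherung, Deutschlandergebnisse"), reports 2011, 2013,
2015, 2017, 2019.  The age layout is <15, 15–59, then 5-year steps 60–64 …
85–89, and 90+.  Map the printed labels to half-open intervals:
"60–64" → `age_lo=60, age_hi=65`; "90+" → `age_lo=90, age_hi=` (blank).

The published table (Tab. 1.2 of the reports) gives totals and the values
for women.  Counts for men are not printed and must be reconstructed; the
natural reconstruction — also the one assumed here — is

    n_care(men) = n_care(total) − n_care(women)
    n_pop(men)  = n_pop(total)  − n_pop(women)

Record in your own provenance notes which reconstruction you applied; the
reader recomputes prevalence from the counts in any case and warns when a
stated prevalence column disagrees beyond rounding (0.5/n_pop).

## Mortality CSV

Schema: `year,sex,age,m`, one row per (year, sex, single age), `m` the
all-cause mortality rate per person-year of the total population.

Source: period life tables / population projection data of the Federal
Statistical Office (destatis.de; the interactive population pyramid exposes
the rates of the moderate assumption variant G2L2W2).  Export the rates for
the same calendar years as the prevalence table (or for every year — the
reader accepts any rectangular year × age grid per sex, and the estimator
interpolates bilinearly between tabulated years and ages; it refuses to
extrapolate outside the grid).  Ages must be contiguous single years
covering at least the evaluation range (50–90 by default).

## Running the estimation

```sh
ltc-incidence estimate \
    --prevalence pflegestatistik_2011_2019.csv \
    --mortality destatis_mortality.csv \
    --year 2015 --R 3.2 --R 1.17 --remission 0 \
    --ages 50:90 --out incidence_2015.csv
```

The output CSV (`year,sex,age,R,r,incidence_per_1000py,flag`) has one row
per (sex, age, scenario); rows with negative estimates are flagged
`negative_estimate`, never clipped.  A JSON manifest with the fitted
coefficients and the full configuration is written next to the output.

Because the published method leaves the regression details open (group
inclusion, weights, representative ages), small deviations from printed
reference values are expected under the defaults; `--min-fit-age`,
`--weights` and `FitOptions.age_assignment` are the knobs to explore them.
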