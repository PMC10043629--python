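"""Fit the logit-linear prevalence surface per sex.

Reads the synthetic tables written by 01_generate_tables.py, regresses
logit(prevalence) on calendar year (centred at 2015) and representative age
separately for women and men, and serialises the fitted models to
results/logit_model_<sex>.txt.
"""

from pathlib import Path

from ltcincidence import FitOptions, fit_logit_linear, read_prevalence_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    prev = read_prevalence_csv(OUT / "synthetic_prevalence.csv")
    # regression restricted to the 5-year groups inside the reporting range;
    # the broad <15 / 15-59 groups and the open-ended 90+ group are far from
    # logit-linear (see docs/methods.md)
    options = FitOptions(include_groups=lambda g: g.lower >= 40 and not g.is_open)
    for sex in ("female", "male"):
        model = fit_logit_linear(prev, sex, options)
        model.to_text(OUT / f"logit_model_{sex}.txt")
        print(
            f"{sex}: logit p = {model.beta0:+.4f} {model.beta_t:+.5f}*(t-{model.t_ref:.0f}) "
            f"{model.beta_a:+.5f}*age   ({model.fit_points} points, "
            f"residual SS {model.residual_ss:.3g})"
        )
        print(f"  predicted prevalence 2015: age 70 = {100*model.predict_prevalence(2015, 70):.2f}%, "
              f"age 90 = {100*model.predict_prevalence(2015, 90):.2f}%")


if __name__ == "__main__":
    main()
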