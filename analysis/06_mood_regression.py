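#!/usr/bin/env python
"""Stage 6 — between-user mood regression.

Fits the logistic model posted_in_MH ~ age + gender + active_days +
activity + posemo + anxiety + anger + sadness + i, where the five mood
scores come exclusively from non-MH posts, compares it against the
controls-only model with a likelihood-ratio test, and refits on a
gender-balanced subsample as a robustness check.
"""

import json
from pathlib import Path

import numpy as np

from bdforum.aggregate import read_records_tsv, regression_frame, select_rq3
from bdforum.pipeline import CONTROLS, _fit_summary, _write_coefficients_tsv
from bdforum.stats import (
    fit_logistic,
    gender_balanced_rerun,
    likelihood_ratio,
    mean_profile,
    relative_probability,
)

OUT = Path("results/analysis")
SEED = 11


def main() -> None:
    records = read_records_tsv(OUT / "user_records.tsv")
    sample = select_rq3(records)
    X, y = regression_frame(sample)
    print(f"regression sample: {len(y)} users, "
          f"{int((y == 0).sum())} never posted in MH communities "
          f"({100 * float((y == 0).mean()):.1f}%)")

    controls_est, controls_fit = fit_logistic(X[CONTROLS], y)
    full_est, full_fit = fit_logistic(X, y)
    lrt = likelihood_ratio(controls_fit, full_fit)
    _write_coefficients_tsv(full_est, OUT / "rq3_coefficients.tsv")

    print(f"controls-only: LL {controls_fit.ll:.1f}, AIC {controls_fit.aic:.0f}, "
          f"BIC {controls_fit.bic:.0f}")
    print(f"with mood:     LL {full_fit.ll:.1f}, AIC {full_fit.aic:.0f}, "
          f"BIC {full_fit.bic:.0f}")
    print(f"LRT: X2({lrt.df}) = {lrt.x2:.2f}, p = {lrt.p:.3g}")
    hl, cs, nk = full_fit.pseudo_r2
    print(f"pseudo-R2: Hosmer-Lemeshow {hl:.3f}, Cox-Snell {cs:.3f}, Nagelkerke {nk:.3f}")

    rel = relative_probability(full_est, mean_profile(X))
    print(f"feminine vs masculine gender at the mean profile: {rel:+.1f}% "
          f"change in predicted probability of posting in MH communities")

    Xb, yb, bal_est, bal_fit = gender_balanced_rerun(X, y, np.random.default_rng(SEED + 2))
    _write_coefficients_tsv(bal_est, OUT / "rq3_coefficients_gender_balanced.tsv")
    print(f"gender-balanced robustness refit: n = {bal_fit.n}")

    modelfit = {
        "n": int(full_fit.n),
        "outcome_prevalence": float(np.mean(y)),
        "controls": _fit_summary(controls_fit),
        "full": _fit_summary(full_fit),
        "lrt": {"x2": lrt.x2, "df": lrt.df, "p": lrt.p},
        "relative_probability_gender_pct": rel,
        "gender_balanced": {"n": int(bal_fit.n), **_fit_summary(bal_fit)},
    }
    with open(OUT / "rq3_modelfit.json", "w", encoding="utf-8") as handle:
        json.dump(modelfit, handle, indent=2, sort_keys=True)
        handle.write("\n")


if __name__ == "__main__":
    main()
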