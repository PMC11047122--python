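"""Eight-gene Cox risk score, median split and log-rank comparison.

Simulates tumor expression for eight signature genes and survival times
whose hazard follows a known linear score, fits the Cox model, scores each
sample as sum(C_i * E_i), splits at the median and compares the groups.
"""

import numpy as np
import pandas as pd

from crconset.simulate import SimulationSpec, simulate_survival
from crconset.survivalrisk import (
    classify_age_days,
    compute_risk_score,
    fit_cox,
    logrank_test,
    median_split,
)

spec = SimulationSpec(seed=1)
rng = np.random.default_rng(spec.seed)
genes = [f"SIG{i + 1}" for i in range(8)]
expr = pd.DataFrame(rng.normal(size=(8, 500)), index=genes,
                    columns=[f"s{i}" for i in range(500)])
beta = np.asarray(spec.true_coefficients)
true_scores = pd.Series(beta @ expr.to_numpy(), index=expr.columns)
surv = simulate_survival(spec, true_scores)

model = fit_cox(expr, surv)
print("true coefficients:     ", np.round(beta, 2))
print("recovered coefficients:", np.round(model.coefficients, 2))
# At n=500 the partial-likelihood fit recovers each coefficient within ~0.2.

scores = compute_risk_score(model, expr)
groups = median_split(scores)
stat, p = logrank_test(groups, surv)
print(f"high-risk group: {(groups == 'high').sum()} samples "
      f"(score >= median {scores.median():.2f})")
print(f"log-rank chi2 = {stat:.1f}, p = {p:.3g}")
# A tiny p confirms the score separates survival, as planted.

print("age 17,900 days ->", classify_age_days(17_900))
print("age 18,251 days ->", classify_age_days(18_251))
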