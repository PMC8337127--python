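"""Agreement between predicted and measured Kt/V (Bland-Altman).

Out-of-fold CV predictions stand in for "the new method"; the generator's
Kt/V targets are "the clinical method".  Differences are expressed as
percent of the pair mean; the 95% limits of agreement are mean +/- 1.96 SD,
and the disagreement count is the number of patients falling outside them.
"""

from gtskfs import (
    CohortSpec, Hyperparams, bland_altman, cross_validate, generate_cohort,
)
from gtskfs.cohort import from_dataframe

data = from_dataframe(generate_cohort(CohortSpec(n=250, seed=4)))
report = cross_validate(data, Hyperparams(seed=4), variant="gtsk", folds=10, seed=4)
ba = bland_altman(data.y, report.predictions)

print(f"mean percent difference: {ba.mean_diff_pct:+.4f}%")
print(f"95% limits of agreement: ({ba.lower_limit:.4f}%, {ba.upper_limit:.4f}%)")
print(f"outside the limits: {ba.n_outside}/{ba.n_total}")
# A mean difference near zero means no systematic bias; for roughly
# Gaussian errors about 5% of patients fall outside the limits.
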