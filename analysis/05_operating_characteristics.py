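#!/usr/bin/env python
"""Validate the pipeline's statistical behaviour on known ground truth.

Measures (a) the type-I error of the end-to-end log-rank comparison
when the generator encodes no marker-outcome association, and (b)
power and HIGH/LOW label recovery when a hazard ratio of 2.5 is
configured on KRT19 in a 200-patient cohort. Writes
results/operating_characteristics.csv.
"""

import pandas as pd

from ctcpanel.validation import null_type_one_error, power_and_recovery

SEED = 1


def main() -> None:
    type1 = null_type_one_error(n_seeds=200, base_seed=SEED)
    power, recovery = power_and_recovery(n_seeds=100, base_seed=SEED)
    out = pd.DataFrame([
        {"metric": "null_logrank_type1_error", "value": type1, "n_seeds": 200},
        {"metric": "power_logrank_p_lt_0.01", "value": power, "n_seeds": 100},
        {"metric": "high_low_label_recovery", "value": recovery, "n_seeds": 100},
    ])
    out.to_csv("results/operating_characteristics.csv", index=False)
    print(f"null scenario: log-rank rejects at alpha=0.05 in {type1:.1%} of 200 seeds")
    print(f"power scenario (n=200, HR 2.5 on KRT19): p < 0.01 in {power:.0%} of 100 seeds")
    print(f"mean HIGH/LOW label recovery vs ground truth: {recovery:.1%}")


if __name__ == "__main__":
    main()
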