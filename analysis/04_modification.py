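#!/usr/bin/env python
"""Effect modification by particulate matter.

For each pollutant model set: the extreme-cold OR at the 10th/50th/90th
percentile centering levels and the percent change per 10 ug/m3 from
the interaction coefficients.
"""

import pandas as pd

from _common import RESULTS, get_study
from coldpm.pipeline import AnalysisConfig, format_est, run_analysis


def main():
    rows = []
    for pollutant in ("pm1", "pm25"):
        study = get_study(pollutant=pollutant)
        b = run_analysis(study.deaths, study.exposures,
                         AnalysisConfig(pollutant=pollutant))
        m = b.modification
        rows.append({
            "pollutant": pollutant,
            "or_low": format_est(*m.or_at_level["p10"], digits=2),
            "or_median": format_est(*m.or_at_level["p50"], digits=2),
            "or_high": format_est(*m.or_at_level["p90"], digits=2),
            "pct_per_10": format_est(*m.pct_per_10),
            "true_pct_per_10": round(study.truth.pct_per_10, 1),
        })
        print(f"{pollutant}: extreme-cold OR {rows[-1]['or_low']} at low, "
              f"{rows[-1]['or_high']} at high level; "
              f"+{m.pct_per_10[0]:.1f}% per 10 ug/m3 "
              f"(truth +{rows[-1]['true_pct_per_10']}%)")
    pd.DataFrame(rows).to_csv(RESULTS / "table_modification.csv", index=False)


if __name__ == "__main__":
    main()
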