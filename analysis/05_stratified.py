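#!/usr/bin/env python
"""Subgroup analyses (Table-2 analogue).

Independent fits by sex, age group, educational level and cause class;
the generator gives the elderly a stronger true interaction (scale 1.5
vs 0.5), so the recovered ordering is the check of interest.
"""

from dataclasses import replace

from _common import RESULTS, STUDY_SEED
from coldpm.pipeline import AnalysisConfig, run_stratified
from coldpm.scenarios import pct_recovery_config
from coldpm.synthetic import simulate_study


def main():
    cfg = pct_recovery_config(STUDY_SEED, pollutant="pm1")
    cfg = replace(cfg, subgroup_gamma_scale={"age_group": {"<75": 0.5, ">=75": 1.5}})
    study = simulate_study(cfg)
    table = run_stratified(study.deaths, study.exposures,
                           AnalysisConfig(pollutant="pm1"))
    table.to_csv(RESULTS / "table2_stratified_pm1.csv", index=False)
    t = table.set_index(["factor", "level"])
    print(table.to_string(index=False))
    print(f"\nelderly vs younger pct per 10 ug/m3: "
          f"{t.loc[('age_group', '>=75'), 'pct_per_10']} vs "
          f"{t.loc[('age_group', '<75'), 'pct_per_10']} "
          f"(true scales 1.5 vs 0.5 on the overall +7.6%)")


if __name__ == "__main__":
    main()
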