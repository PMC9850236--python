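"""Shared plumbing for the numbered analysis scripts.

The scripts analyse one synthetic six-season study whose truth is
calibrated to the headline estimates (overall extreme-cold OR 1.83,
+7.6% per 10 ug/m3 PM1).  Intermediate data live under scratch/ (not
part of the deliverable); tables go to results/.
"""

from pathlib import Path

from coldpm.scenarios import pct_recovery_config
from coldpm.synthetic import simulate_study, write_deaths, write_exposures

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis_data"

STUDY_SEED = 1


def get_study(pollutant="pm1"):
    """Simulate (or re-simulate: generation is deterministic) the
    study analysed by the scripts, and cache the CSVs under scratch/."""
    study = simulate_study(pct_recovery_config(STUDY_SEED, pollutant=pollutant))
    SCRATCH.mkdir(parents=True, exist_ok=True)
    exp_path = SCRATCH / f"exposures_{pollutant}.csv"
    if not exp_path.exists():
        write_exposures(study.exposures, exp_path)
        write_deaths(study.deaths, SCRATCH / f"deaths_{pollutant}.csv")
    RESULTS.mkdir(exist_ok=True)
    return study
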