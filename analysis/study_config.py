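"""Shared study configuration for the numbered analysis scripts.

One night per participant, 480 minutes in bed, moderate fragmentation,
with sleep-problem subgroups assigned at their cohort prevalences.  All
scripts derive every number from this config and the seed, so the whole
analysis is reproducible end to end.
"""

from pathlib import Path

from actisleep.synthetic import NightConfig

SEED = 42
STUDY_CONFIG = NightConfig(n_participants=100, in_bed_minutes=480, seed=SEED, subgroups=True)

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"
SCRATCH = REPO / "scratch"
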