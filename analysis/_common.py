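"""Shared configuration for the numbered analysis scripts.

Every script re-creates the same synthetic reference from one seed, so no
intermediate matrices need to be stored on disk.
"""

from pathlib import Path

from striacell.synthetic_data import CountSimConfig, GradientSpec, simulate_counts

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20240501


def reference_config() -> CountSimConfig:
    return CountSimConfig(
        seed=SEED,
        n_plates=2,
        plate_effect_sd=0.1,
        gradient=GradientSpec(cluster="C1"),
    )


def get_reference():
    return simulate_counts(reference_config())
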