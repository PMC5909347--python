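"""Shared run configuration for the numbered analysis scripts.

All scripts operate on the same on-disk run directory so they can be
executed in order (01 -> 05) or individually once their inputs exist.
"""

from pathlib import Path

from vascquant.pipeline import RunConfig


def default_config(seed: int = 1) -> RunConfig:
    return RunConfig(out_dir=Path("results/analysis"), seed=seed,
                     n_per_group=6)
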