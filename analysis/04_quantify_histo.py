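"""Quantify histology: microvessel density and bead counts per animal.

Segments CD-31-like stained structures (connected components above the
minimum area) to compute MVD in structures/mm^2, and counts fluorescent
beads per field of view, into ``results/analysis/quantify_histo.csv``.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
config_mod = importlib.import_module("00_config")

from vascquant.pipeline import quantify_histo  # noqa: E402


def main() -> None:
    config = config_mod.default_config()
    csv = quantify_histo(config)
    df = pd.read_csv(csv)
    print(f"wrote {csv} ({len(df)} animals)")
    print(df.groupby("group")[["mvd", "beads_per_fov"]]
          .median().round(1).to_string())


if __name__ == "__main__":
    main()
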