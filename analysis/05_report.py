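"""Assemble the cohort statistics report.

Merges the three quantification tables, builds the stratified two-group
comparison table (normality-gated t / Mann-Whitney U per variable,
chi-square for the ordinal TOF scores), the four Spearman correlations
between imaging and reference readouts (with the exclusion rerun if a
total-necrosis flag fired), and scatter figures, under
``results/analysis/``.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
config_mod = importlib.import_module("00_config")

from vascquant.pipeline import report  # noqa: E402


def main() -> None:
    config = config_mod.default_config()
    res = report(config)
    table = res["comparison_table"]
    merged = table[table["cell_line"] == "merged"]
    print("merged-cohort comparisons (co vs non-co):")
    print(merged[["variable", "test", "p_value", "significant"]]
          .to_string(index=False))
    print("\ncorrelation analyses:")
    print(res["correlations"][["analysis", "r", "p_value", "n"]]
          .to_string(index=False))
    print(f"\ntables and figures under {res['out_dir']}")


if __name__ == "__main__":
    main()
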