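"""Call differentially regulated proteins per dose group.

Replicate ratios are tested on the log2 scale (mean imputed as third
value, one-sample t, BH adjustment) and called at fold change >= 1.2 /
<= 0.83 with adjusted P <= 0.1.  Prints the per-group up/down counts and
the Venn partition of the three differential sets.
"""

import json

from common import CONFIG, RUN_DIR
from radprot import pipeline

calls = pipeline.stage_differential(CONFIG, RUN_DIR)
sig = calls[calls["status"] != "unchanged"]
for group, sub in sig.groupby("group"):
    up, down = (sub["status"] == "up").sum(), (sub["status"] == "down").sum()
    print(f"group {group}: {up} up, {down} down "
          f"({len(sub)} differential of {CONFIG.n_proteins})")
venn = json.loads((RUN_DIR / "venn.json").read_text())
print("Venn partition:", venn)
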