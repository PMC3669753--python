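"""Generate the synthetic study: a 3-replicate -Fe/+Fe RPKM table with
planted up/down genes, a 300-array log2 compendium with three planted
co-expression modules (30/20/10 genes at within-correlation 0.85), and a
toy GO world with one planted enriched leaf term.

The planted up-regulated genes are relabelled onto the compendium's
module members, so differential expression and co-expression structure
coincide the way the downstream network analysis assumes.
"""

import json

import pandas as pd

from _common import RESULTS, SEED, ensure_world, WORLD

world = ensure_world()
truth = json.loads((world / "truth.json").read_text())

summary = pd.DataFrame(
    [
        ("seed", SEED),
        ("planted_up_genes", len(truth["de_up"])),
        ("planted_down_genes", len(truth["de_down"])),
        ("planted_module_genes", len(truth["module_assignment"])),
        ("planted_modules", len(set(truth["module_assignment"].values()))),
        ("planted_enriched_terms", len(truth["enriched_terms"])),
        ("bait_genes", len(truth["baits"])),
    ],
    columns=["quantity", "value"],
)
summary.to_csv(RESULTS / "01_world_summary.tsv", sep="\t", index=False)
print(f"synthetic world written to {WORLD}")
print(summary.to_string(index=False))
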