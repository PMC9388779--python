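#!/usr/bin/env python
"""Regional attribution of the seed-FC classifier.

Computes exact linear-model Shapley values for the CV test predictions,
selects the top 10% of voxels by mean |attribution| and tallies the
percentage each atlas region contributes — the tabular counterpart of a
region-importance figure.
"""

from pathlib import Path

from tdcsfc.pipeline import (
    PipelineConfig,
    attribute_dataset,
    build_fc_dataset,
    evaluate_dataset,
)
from tdcsfc.synthetic import SimConfig, resolve_discriminative_regions

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

config = PipelineConfig(sim=SimConfig(seed=0), n_responders=17, n_nonresponders=17)
ds = build_fc_dataset(config)
result = evaluate_dataset(config, ds)
table = attribute_dataset(config, ds, result)
table.to_csv(OUT / "region_contributions.tsv", sep="\t", index=False)

planted = resolve_discriminative_regions(ds.atlas, config.sim)
print(table.to_string(index=False))
print(f"\nplanted discriminative regions: {planted}")
print(f"top-2 recovered: {set(table['region_label'].head(2))}")
print(f"wrote {OUT / 'region_contributions.tsv'}")
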