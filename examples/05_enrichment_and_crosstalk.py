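"""Gene-set enrichment of a query list, and ligand-receptor crosstalk.

Enrichment is a one-sided hypergeometric test with BH correction; an
interaction is recorded whenever >= 1 source-type cell expresses the
ligand and >= 1 target-type cell expresses the receptor.
"""

import pandas as pd

from sctme import (
    SyntheticSpec, generate_dataset, run_qc, normalize_log,
    LRDatabase, infer_interactions, ligand_source_summary, hypergeom_enrich,
)
from sctme.genesets import GeneSetCollection

matrix, truth = generate_dataset(SyntheticSpec(seed=0))
matrix, _ = run_qc(matrix)
normalize_log(matrix)
truth.cells = truth.cells[~truth.cells["lowq"]].reset_index(drop=True)

# enrichment: the planted up-regulated transition program against a toy collection
universe = list(matrix.gene_meta["symbol"])
collection = GeneSetCollection(
    sets={
        "M2_POLARIZATION_UP": truth.transition_up,
        "RANDOM_SET": universe[100:160],
    },
    descriptions={"M2_POLARIZATION_UP": "", "RANDOM_SET": ""},
)
res = hypergeom_enrich(truth.transition_up, collection, universe)
print("enrichment of the up-regulated transition genes:")
print(res[["set", "k", "K", "pvalue", "padj", "significant"]].to_string(index=False))

# crosstalk: planted epithelial -> myeloid channels
db = LRDatabase(pd.DataFrame(
    [{"ligand": c.ligand, "receptor": c.receptor} for c in truth.lr_channels]
))
table = infer_interactions(matrix, truth.cells["cell_type"].to_numpy(), db)
print(f"\n{len(table)} potential ligand-receptor interactions")
summary = ligand_source_summary(
    table,
    sorted({c.receptor for c in truth.lr_channels}),
    ["CD14+ monocyte", "M2 macrophage"],
)
print("ligand sources for receptors on monocytes/M2 macrophages:")
print(summary.to_string(index=False))
# epithelial cells should dominate the sourcing, as the channels are planted there
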