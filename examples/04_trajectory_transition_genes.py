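"""Order myeloid cells along the monocyte-to-M2 axis and find the genes
that change smoothly along it.

The root anchors at CD14+ monocytes from normal tissue; pseudotime is arc
length along the principal curve of a 2-D embedding of per-cluster
differential genes. Transition-state genes pass a spline NB likelihood-
ratio test at P < 0.005 and FDR < 0.05 and carry an up/down direction.
"""

from scipy.stats import spearmanr

from sctme import (
    SyntheticSpec, generate_dataset, run_qc, normalize_log,
    ordering_genes, learn_trajectory, transition_genes, assign_fates,
)

spec = SyntheticSpec(
    n_cells_per_type={
        "CD14+ monocyte": {"tumor": 100, "normal": 150},
        "M2 macrophage": {"tumor": 150, "normal": 30},
    },
    lowq_cells={"count": 0}, lr_channels=[], grn=None,
    cnv={"regions": [], "malignant_fraction": 0.0},
    trajectory={"types": ("CD14+ monocyte", "M2 macrophage"), "n_branches": 1},
    seed=0,
)
matrix, truth = generate_dataset(spec)
matrix, _ = run_qc(matrix)
normalize_log(matrix)

labels = truth.cells["cell_type"].astype("category").cat.codes.to_numpy()
genes = ordering_genes(matrix, labels)
root = ((truth.cells["cell_type"] == "CD14+ monocyte")
        & (truth.cells["tissue"] == "normal")).to_numpy()
traj = learn_trajectory(matrix, genes, root_mask=root, seed=0)

rho = spearmanr(traj.pseudotime, truth.cells["pseudotime"]).statistic
print(f"{len(genes)} ordering genes; pseudotime vs planted ordering: "
      f"Spearman rho = {rho:.3f}")

fates = assign_fates(traj, truth.cells["cell_type"].to_numpy(), "M2 macrophage")
results = transition_genes(matrix, traj, fates["AT1"])
up = [r.gene for r in results if r.direction == "up"]
down = [r.gene for r in results if r.direction == "down"]
print(f"{len(results)} transition-state genes ({len(up)} up, {len(down)} down "
      f"along root -> M2 fate)")
print("strongest:", [(r.gene, r.direction) for r in results[:5]])
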