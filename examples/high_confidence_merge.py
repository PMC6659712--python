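"""High-confidence hits: the intersection of ANC and network-module evidence.

Simulates one study at the event level, runs both independent statistical
routes on it — ANC hit calling on bead distributions, and correlation
network analysis on the replicate-averaged MFI matrix — and keeps only
interactions significant by both.  The merged set is exported as a
Cytoscape-style node-edge diagram (SIF + attribute table).
"""

import numpy as np

from qminet import cna
from qminet.integrate import (
    NetworkDiagram,
    collapse_epitopes,
    detection_mask,
    export_network,
    merge_anc_cna,
)
from qminet.preprocess import average_replicates, mfi_matrix_from_distributions
from qminet.synthdata import PlantedEffect, SimulationDesign, make_panel
from qminet.workflows import anc_pipeline, event_pipeline

panel = make_panel(5, 6, seed=3)  # 30 interactions
design = SimulationDesign(
    n_experiments=4, n_replicates=2, beads_per_interaction_per_well=300, seed=4
)
planted = [
    PlantedEffect("IP1_Probe1", "treated", 0.5),
    PlantedEffect("IP2_Probe3", "treated", 0.5),
    PlantedEffect("IP3_Probe5", "treated", 0.5),
]

# route 1: bead-level ANC
anc_result = anc_pipeline(panel, design, planted)
print(f"ANC hits: {sorted(anc_result.hit_interactions)}")

# route 2: matrix-level network analysis on the same simulated events
dists = event_pipeline(panel, design, planted)
matrix = average_replicates(mfi_matrix_from_distributions(dists))
trait = (matrix.samples["condition"] == "treated").to_numpy().astype(float)
modules, net, expr = cna.run_cna(matrix, trait, min_module_size=5)
assoc = modules.module_trait[modules.module_trait["significant"]]
print(f"trait-associated modules: {list(assoc.index)}")

merged = merge_anc_cna(anc_result.hits, modules)
print(f"high-confidence set {merged.interactions} (counts: {merged.counts})")

# one edge per protein pair, largest |log2 FC| epitope measurement wins
edges = collapse_epitopes(
    {
        (tuple(name.split("_")), name): lfc
        for name, lfc in merged.log2_fc.items()
    }
)
masked = detection_mask([e.log2_fc for e in edges])
for edge, below in zip(edges, masked):
    note = " (below 10% detection limit)" if below else ""
    print(f"edge {edge.protein_a}--{edge.protein_b}: log2 FC {edge.log2_fc:+.2f}{note}")

path = export_network(NetworkDiagram(edges), "scratch_network.sif", "sif")
print(f"wrote {path} and {path.with_suffix('.attrs.csv')}")
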