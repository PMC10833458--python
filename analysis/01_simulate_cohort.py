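#!/usr/bin/env python
"""Generate the synthetic study inputs every later step consumes.

Emits, under results/data/: a two-condition log2 expression matrix
(500 genes x 40 samples; "autonomous" vs "control"), the planted 29-up /
3-down ground-truth signature, per-sample annotations, and a PPI edge list
with 5 planted hub nodes on a 200-node background.
"""

from pathlib import Path

from autonomy.io import write_edge_list, write_expression, write_signature
from autonomy.simulate import SimConfig, simulate_expression, simulate_graph

SEED = 2024
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    matrix, signature, groups = simulate_expression(cfg)
    write_expression(matrix, OUT / "matrix.tsv")
    matrix.annotations.to_csv(OUT / "annotations.tsv", sep="\t",
                              index_label="sample_id")
    write_signature(signature, OUT / "signature_truth.tsv")
    graph, hubs = simulate_graph(cfg)
    write_edge_list(sorted(graph.edges), OUT / "edges.tsv")
    (OUT / "hubs_truth.tsv").write_text("".join(f"{h}\n" for h in hubs))

    print(f"expression: {matrix.n_genes} genes x {matrix.n_samples} samples "
          f"({(groups == 'autonomous').sum()} autonomous / "
          f"{(groups == 'control').sum()} control)")
    print(f"planted signature: {len(signature.up_genes)} up / "
          f"{len(signature.down_genes)} down, effect {cfg.effect} log2 units")
    print(f"graph: {graph.number_of_nodes()} nodes, "
          f"{graph.number_of_edges()} edges, {len(hubs)} planted hubs")
    print(f"wrote inputs to {OUT}/")


if __name__ == "__main__":
    main()
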