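"""Fitness-landscape genotype network and activity quintiles.

Builds the Hamming-distance-1 genotype network over the combinatorial
(variable-position) library — the desk-scale analogue of the
phylogenetically derived landscape — and bins genotypes into activity
quintiles.
"""

import json

import numpy as np

import ribofit as rf
from ribofit.landscape import annotate_quintiles, export_bin_summary, export_network

from _common import BASE_SEED, REF69, outdir


def main() -> None:
    out = outdir("04_network")
    rng = np.random.default_rng(BASE_SEED + 10)
    ref = rf.ReferenceSequence(REF69)
    # a 12-position biallelic variable-position scheme (2^12 = 4096 genotypes)
    positions = sorted(rng.choice(np.arange(1, 70), 12, replace=False))
    entries = []
    for pos in positions:
        r = ref.base_at(int(pos))
        entries.append((int(pos), (str(rng.choice([a for a in "ACGU" if a != r])),)))
    scheme = rf.VariablePositionScheme(tuple(entries))
    model = rf.sample_landscape_model(
        ref, n_compensatory_pairs=2, epistasis_scale=1.0, seed=BASE_SEED + 11
    )
    genotypes = rf.enumerate_combinatorial_variants(ref, scheme)
    table = rf.simulate_activity_table(model, genotypes, depth=1000, seed=BASE_SEED + 12)
    graph = rf.build_genotype_network(table)
    assignment, counts = rf.quintile_bins(table)
    annotate_quintiles(graph, assignment)
    export_network(graph, out / "edges.tsv", out / "nodes.tsv")
    export_bin_summary(counts, out / "quintiles.json")
    (out / "scheme.json").write_text(
        json.dumps({str(p): list(a) for p, a in scheme.entries}, indent=2)
    )

    print(
        f"Network: {graph.number_of_nodes()} genotypes, {graph.number_of_edges()} "
        f"single-mutation edges (hypercube expectation {12 * 2**11})."
    )
    print("Genotypes per activity quintile (1 = lowest fifth of activity):")
    for k in range(1, 6):
        print(f"  quintile {k}: {counts[k]}")
    print(f"Outputs in {out}")


if __name__ == "__main__":
    main()
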