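"""Simulate the doped mutant library and its cleavage-sequencing reads.

Draws a ground-truth activity landscape over a 69-nt reference (logistic
link, wild-type activity 0.8, mixture of near-neutral and deleterious
effects, compensatory base pairs, background negative epistasis), samples a
3%-doped library, and writes FASTQ reads whose cleaved/uncleaved state is
encoded by the absence/presence of the 5' upstream segment.
"""

import json

import ribofit as rf

from _common import BASE_SEED, REF69, outdir


def main() -> None:
    out = outdir("01_simulate")
    ref = rf.ReferenceSequence(REF69)
    model = rf.sample_landscape_model(
        ref, n_compensatory_pairs=2, epistasis_scale=1.0, seed=BASE_SEED
    )
    model.to_json(out / "landscape_model.json")

    library = rf.sample_doped_library(
        ref, rf.DopedLibraryConfig(0.03, 20_000, seed=BASE_SEED + 1)
    )
    genotypes = sorted(set(library), key=lambda g: (g.order, str(g)))
    rf.true_activity_table(model, genotypes).to_tsv(out / "true_activity.tsv")

    cfg = rf.ReadSimulationConfig(
        mean_depth=150, depth_dispersion=0.5, seed=BASE_SEED + 2
    )
    n_reads = sum(
        1 for _ in rf.simulate_reads(model, genotypes, cfg, fastq_path=out / "reads.fastq")
    )
    orders = [g.order for g in library]
    summary = {
        "n_molecules": len(library),
        "n_unique_genotypes": len(genotypes),
        "mean_order_per_molecule": sum(orders) / len(orders),
        "n_reads": n_reads,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"Simulated {len(library)} molecules -> {len(genotypes)} unique genotypes "
        f"(mean mutations per molecule {summary['mean_order_per_molecule']:.2f}), "
        f"{n_reads} reads."
    )
    print(f"Outputs in {out}")


if __name__ == "__main__":
    main()
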