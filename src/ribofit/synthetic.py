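"""Synthetic ground-truth landscapes and simulated cleavage-sequencing reads.

Everything here is a labeled fixture generator: the real experiment measures
fraction cleaved by sequencing, and no generative model for it is implied by
the data. The generator exists so the full pipeline (read classification,
epistasis, genotype networks, regression models, evaluation harness) can be
exercised and validated end to end against a known truth.

The generative model is

    latent(g)   = baseline + sum additive(m) + sum pairwise(m, m') [+ 3-way]
    activity(g) = link(latent(g))                        in [0, 1]

with a logistic link by default (activities span the full range, wild-type
near 0.8). An "exponential" link (min(1, exp(latent))) is also provided: in
that regime activity is multiplicative across mutations, so the pairwise
epistasis statistic is exactly zero for a purely additive model — the clean
null for epistasis-recovery tests.

Compensatory base pairs are planted structurally: both designated single
mutations get strongly deleterious additive effects and the designated double
gets a positive pairwise term that lifts it above both singles, emulating the
base-pair-restoration pattern seen in double-mutant heatmaps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .genotypes import (
    ALPHABET,
    Genotype,
    Mutation,
    ReferenceSequence,
)
from .reads import ActivityTable, ReadRecord

PairKey = tuple[Mutation, Mutation]
TripleKey = tuple[Mutation, Mutation, Mutation]


def _pair_key(a: Mutation, b: Mutation) -> PairKey:
    if a.position == b.position:
        raise ValueError("pairwise terms require distinct positions")
    return (a, b) if a.position < b.position else (b, a)


def _triple_key(ms: Sequence[Mutation]) -> TripleKey:
    ms = tuple(sorted(ms, key=lambda m: m.position))
    if len({m.position for m in ms}) != 3:
        raise ValueError("three-way terms require three distinct positions")
    return ms  # type: ignore[return-value]


@dataclass
class LandscapeModel:
    """Ground-truth activity surface: additive + pairwise (+ optional 3-way) latent terms."""

    reference: ReferenceSequence
    baseline: float
    additive_effects: dict[Mutation, float]
    pairwise_terms: dict[PairKey, float] = field(default_factory=dict)
    threeway_terms: dict[TripleKey, float] = field(default_factory=dict)
    link: str = "logistic"
    compensatory_pairs: list[tuple[int, int]] = field(default_factory=list)
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.link not in ("logistic", "exponential"):
            raise ValueError(f"unknown link {self.link!r}")

    def apply_link(self, latent: float) -> float:
        if self.link == "logistic":
            return 1.0 / (1.0 + math.exp(-latent))
        return min(1.0, math.exp(latent))

    def latent(self, g: Genotype) -> float:
        x = self.baseline
        muts = g.mutations
        for m in muts:
            x += self.additive_effects.get(m, 0.0)
        if self.pairwise_terms:
            for i in range(len(muts)):
                for j in range(i + 1, len(muts)):
                    x += self.pairwise_terms.get(_pair_key(muts[i], muts[j]), 0.0)
        if self.threeway_terms and len(muts) >= 3:
            import itertools

            for trio in itertools.combinations(muts, 3):
                x += self.threeway_terms.get(_triple_key(trio), 0.0)
        return x

    # -- serialization (JSON model dump for independent recomputation) -----

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "reference": self.reference.bases,
            "baseline": self.baseline,
            "link": self.link,
            "seed": self.seed,
            "config": self.config,
            "compensatory_pairs": [list(p) for p in self.compensatory_pairs],
            "additive_effects": {str(m): v for m, v in self.additive_effects.items()},
            "pairwise_terms": {
                f"{a};{b}": v for (a, b), v in self.pairwise_terms.items()
            },
            "threeway_terms": {
                ";".join(str(m) for m in trio): v
                for trio, v in self.threeway_terms.items()
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "LandscapeModel":
        s = str(text_or_path)
        text = s if s.lstrip().startswith("{") else Path(s).read_text()
        d = json.loads(text)
        ref = ReferenceSequence(d["reference"])

        def mut(s: str) -> Mutation:
            return Genotype.from_string(s).mutations[0]

        return cls(
            reference=ref,
            baseline=d["baseline"],
            additive_effects={mut(k): v for k, v in d["additive_effects"].items()},
            pairwise_terms={
                _pair_key(*(mut(t) for t in k.split(";"))): v
                for k, v in d["pairwise_terms"].items()
            },
            threeway_terms={
                _triple_key([mut(t) for t in k.split(";")]): v
                for k, v in d.get("threeway_terms", {}).items()
            },
            link=d["link"],
            compensatory_pairs=[tuple(p) for p in d["compensatory_pairs"]],
            seed=d.get("seed"),
            config=d.get("config", {}),
        )


def true_activity(model: LandscapeModel, g: Genotype) -> float:
    """Ground-truth activity in [0, 1] for a genotype under the model."""
    return model.apply_link(model.latent(g))


# ---------------------------------------------------------------------------
# Model sampling


def sample_landscape_model(
    ref: ReferenceSequence,
    n_compensatory_pairs: int = 2,
    epistasis_scale: float = 1.0,
    seed: int = 0,
    link: str = "logistic",
    wildtype_activity: float = 0.8,
    neutral_prob: float = 0.35,
    neutral_sd: float = 0.15,
    deleterious_mean: float = -3.0,
    deleterious_sd: float = 1.0,
    background_pair_fraction: float = 0.05,
    n_threeway_terms: int = 0,
    threeway_scale: float = 0.0,
    mutation_pool: Sequence[Mutation] | None = None,
) -> LandscapeModel:
    """Draw a random but fully reproducible ground-truth landscape.

    Additive latent effects are a mixture of near-neutral (prob
    ``neutral_prob``, N(0, neutral_sd)) and deleterious (N(deleterious_mean,
    deleterious_sd)) draws, so single-mutant activities span the full range.
    A random ``background_pair_fraction`` of mutation pairs at distinct
    positions get negative pairwise terms of magnitude ~ Exp(epistasis_scale/2),
    reflecting the predominance of negative epistasis in RNA landscapes.
    ``n_compensatory_pairs`` position pairs are planted as described in the
    module docstring. Optional three-way terms (triples drawn from
    ``mutation_pool``, default all single mutations) plant higher-order
    structure that no amount of double-mutant data can reveal.
    """
    L = len(ref)
    if 2 * n_compensatory_pairs > L:
        raise ValueError("too many compensatory pairs for the reference length")
    rng = np.random.default_rng(seed)
    if link == "logistic":
        baseline = math.log(wildtype_activity / (1.0 - wildtype_activity))
    else:
        baseline = math.log(wildtype_activity)

    singles = []
    for pos in range(1, L + 1):
        r = ref.base_at(pos)
        for alt in ALPHABET:
            if alt != r:
                singles.append(Mutation(pos, r, alt))

    additive: dict[Mutation, float] = {}
    for m in singles:
        if rng.random() < neutral_prob:
            additive[m] = float(rng.normal(0.0, neutral_sd))
        else:
            additive[m] = float(rng.normal(deleterious_mean, deleterious_sd))

    pairwise: dict[PairKey, float] = {}
    if epistasis_scale != 0.0 and background_pair_fraction > 0.0:
        n_singles = len(singles)
        for i in range(n_singles):
            mi = singles[i]
            for j in range(i + 1, n_singles):
                mj = singles[j]
                if mi.position == mj.position:
                    continue
                if rng.random() < background_pair_fraction:
                    pairwise[_pair_key(mi, mj)] = float(
                        -epistasis_scale * rng.exponential(0.5)
                    )

    # Compensatory base pairs: break = deleterious, designated double restores.
    positions = rng.permutation(np.arange(1, L + 1))
    comp_pairs: list[tuple[int, int]] = []
    for k in range(n_compensatory_pairs):
        i, j = int(positions[2 * k]), int(positions[2 * k + 1])
        if i > j:
            i, j = j, i
        comp_pairs.append((i, j))
        mi = Mutation(i, ref.base_at(i), str(rng.choice([a for a in ALPHABET if a != ref.base_at(i)])))
        mj = Mutation(j, ref.base_at(j), str(rng.choice([a for a in ALPHABET if a != ref.base_at(j)])))
        ai = -4.0 - float(abs(rng.normal(0.0, 0.5)))
        aj = -4.0 - float(abs(rng.normal(0.0, 0.5)))
        additive[mi] = ai
        additive[mj] = aj
        # double's latent = baseline - 1 > each single's latent (baseline + a)
        pairwise[_pair_key(mi, mj)] = -(ai + aj) - 1.0

    threeway: dict[TripleKey, float] = {}
    if n_threeway_terms > 0:
        pool = list(mutation_pool) if mutation_pool is not None else singles
        attempts = 0
        while len(threeway) < n_threeway_terms and attempts < 1000 * n_threeway_terms:
            attempts += 1
            idx = rng.choice(len(pool), size=3, replace=False)
            trio = [pool[int(i)] for i in idx]
            if len({m.position for m in trio}) != 3:
                continue
            key = _triple_key(trio)
            if key in threeway:
                continue
            threeway[key] = float(-threeway_scale * (0.5 + rng.exponential(1.0)))

    return LandscapeModel(
        reference=ref,
        baseline=baseline,
        additive_effects=additive,
        pairwise_terms=pairwise,
        threeway_terms=threeway,
        link=link,
        compensatory_pairs=comp_pairs,
        seed=seed,
        config={
            "n_compensatory_pairs": n_compensatory_pairs,
            "epistasis_scale": epistasis_scale,
            "wildtype_activity": wildtype_activity,
            "neutral_prob": neutral_prob,
            "neutral_sd": neutral_sd,
            "deleterious_mean": deleterious_mean,
            "deleterious_sd": deleterious_sd,
            "background_pair_fraction": background_pair_fraction,
            "n_threeway_terms": n_threeway_terms,
            "threeway_scale": threeway_scale,
        },
    )


# ---------------------------------------------------------------------------
# Doped-synthesis library


@dataclass(frozen=True)
class DopedLibraryConfig:
    """Doped chemical synthesis: each position mutates independently.

    The default 3% per-position rate models synthesis from phosphoramidite
    mixes of 97% wild-type base and 1% each of the other three.
    """

    per_position_mutation_rate: float = 0.03
    n_molecules: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_position_mutation_rate < 1.0:
            raise ValueError("rate must be in [0, 1)")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be positive")


def sample_doped_library(
    ref: ReferenceSequence, cfg: DopedLibraryConfig
) -> list[Genotype]:
    """Draw molecules from the doped library (with multiplicity).

    Each position mutates independently with the configured rate; the
    alternative base is uniform over the three non-reference bases.
    """
    rng = np.random.default_rng(cfg.seed)
    L = len(ref)
    mask = rng.random((cfg.n_molecules, L)) < cfg.per_position_mutation_rate
    alt_choice = rng.integers(0, 3, size=(cfg.n_molecules, L))
    alts_by_pos = [
        [a for a in ALPHABET if a != ref.base_at(pos)] for pos in range(1, L + 1)
    ]
    out = []
    for row in range(cfg.n_molecules):
        muts = tuple(
            Mutation(pos + 1, ref.base_at(pos + 1), alts_by_pos[pos][alt_choice[row, pos]])
            for pos in np.nonzero(mask[row])[0]
        )
        out.append(Genotype(muts))
    return out


# ---------------------------------------------------------------------------
# Read simulation

DEFAULT_UPSTREAM = "GGAAACAGCUAUGACCAUG"
DEFAULT_PRIMER_SITE = "AGAUCGGAAGAGCGUCGUG"


@dataclass(frozen=True)
class ReadSimulationConfig:
    """Desk-scale emulation of the cleavage-sequencing library structure.

    A cleaved molecule's read is ribozyme + primer site; an uncleaved one
    additionally carries the 5' upstream segment. Depth per genotype is
    negative-binomial around ``mean_depth`` (``depth_dispersion`` = 0 gives a
    fixed depth), mirroring the large spread in per-variant coverage between
    single and double mutants in real libraries.
    """

    mean_depth: float = 100.0
    depth_dispersion: float = 0.0
    upstream_seq: str = DEFAULT_UPSTREAM
    primer_site: str = DEFAULT_PRIMER_SITE
    sequencing_error_rate: float = 0.0
    seed: int = 0
    as_dna: bool = True

    def __post_init__(self) -> None:
        if not self.upstream_seq or not self.primer_site:
            raise ValueError("upstream_seq and primer_site must be nonempty")
        if self.upstream_seq in self.primer_site or self.primer_site in self.upstream_seq:
            raise ValueError("upstream_seq and primer_site must be disjoint")
        if not 0.0 <= self.sequencing_error_rate < 1.0:
            raise ValueError("sequencing_error_rate must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


_DNA = str.maketrans("U", "T")


def _sample_depth(rng: np.random.Generator, cfg: ReadSimulationConfig) -> int:
    if cfg.depth_dispersion <= 0:
        return max(1, int(round(cfg.mean_depth)))
    # NB parameterized by mean m and dispersion k: var = m + m^2/k
    k = 1.0 / cfg.depth_dispersion
    p = k / (k + cfg.mean_depth)
    return max(1, int(rng.negative_binomial(k, p)))


def simulate_reads(
    model: LandscapeModel,
    genotypes: Sequence[Genotype],
    cfg: ReadSimulationConfig,
    fastq_path: str | Path | None = None,
) -> Iterator[ReadRecord]:
    """Yield simulated reads for the given genotypes; optionally write FASTQ.

    Each read of genotype g is cleaved with probability true_activity(model, g).
    Substitution errors are applied uniformly at ``sequencing_error_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    handle = open(fastq_path, "w") if fastq_path is not None else None
    err = cfg.sequencing_error_rate
    try:
        read_idx = 0
        for g in genotypes:
            ribo = g.sequence(model.reference)
            p = true_activity(model, g)
            depth = _sample_depth(rng, cfg)
            n_cleaved = int(rng.binomial(depth, p))
            cleaved_seq = ribo + cfg.primer_site
            uncleaved_seq = cfg.upstream_seq + ribo + cfg.primer_site
            for i in range(depth):
                seq = cleaved_seq if i < n_cleaved else uncleaved_seq
                if err > 0.0:
                    n_err = rng.binomial(len(seq), err)
                    if n_err:
                        chars = list(seq)
                        for pos in rng.choice(len(seq), size=n_err, replace=False):
                            old = chars[pos]
                            chars[pos] = str(
                                rng.choice([a for a in ALPHABET if a != old])
                            )
                        seq = "".join(chars)
                if cfg.as_dna:
                    seq = seq.translate(_DNA)
                rec = ReadRecord(
                    identifier=f"sim_{read_idx}", sequence=seq, quality="I" * len(seq)
                )
                read_idx += 1
                if handle is not None:
                    handle.write(f"@{rec.identifier}\n{rec.sequence}\n+\n{rec.quality}\n")
                yield rec
    finally:
        if handle is not None:
            handle.close()


def simulate_activity_table(
    model: LandscapeModel,
    genotypes: Sequence[Genotype],
    depth: int,
    seed: int = 0,
    min_reads: int = 1,
) -> ActivityTable:
    """Binomial cleaved counts at true activity, bypassing read simulation.

    Fast path for model-level tests: same estimator contract as the read
    pipeline (cleaved / total) without generating sequences.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = {}
    for g in genotypes:
        p = true_activity(model, g)
        c = int(rng.binomial(depth, p))
        counts[g] = (c, depth - c)
    return ActivityTable.from_counts(
        counts,
        model.reference,
        min_reads=min_reads,
        provenance={"simulated": True, "depth": depth, "seed": seed},
    )


def true_activity_table(
    model: LandscapeModel, genotypes: Sequence[Genotype]
) -> ActivityTable:
    """Noise-free table: fraction_cleaved equals true activity exactly.

    The depth-to-infinity limit of :func:`simulate_activity_table`; counts
    columns are filled with a nominal depth of 1 and are not meaningful.
    """
    import pandas as pd

    rows = []
    for g in sorted(set(genotypes), key=lambda g: (g.order, str(g))):
        rows.append(
            {
                "genotype": str(g),
                "order": g.order,
                "cleaved": 1,
                "uncleaved": 0,
                "total": 1,
                "fraction_cleaved": true_activity(model, g),
            }
        )
    df = pd.DataFrame(rows, columns=list(ActivityTable.COLUMNS))
    return ActivityTable(df, model.reference, {"simulated": True, "noise_free": True})
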