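"""Pairwise epistasis from double-mutant activity data.

For a double mutant AB with constituent singles A and B,

    epsilon = log10( W_AB * W_wt / (W_A * W_B) )

where W is fraction cleaved. epsilon = 0 is the multiplicative null;
negative epsilon means the combination is worse than expected from the
singles. The statistic is undefined when any of the four activities is zero
or missing; such pairs are excluded and tallied rather than floored, so no
magnitudes are invented (an optional activity floor is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import Genotype, Mutation
from .reads import ActivityTable


@dataclass(frozen=True)
class EpistasisRecord:
    mutation_a: Mutation
    mutation_b: Mutation
    W_wt: float
    W_A: float
    W_B: float
    W_AB: float
    epsilon: float


def pairwise_epistasis(W_wt: float, W_A: float, W_B: float, W_AB: float) -> float:
    """log10(W_AB * W_wt / (W_A * W_B)); all four activities must be positive."""
    for name, w in (("W_wt", W_wt), ("W_A", W_A), ("W_B", W_B), ("W_AB", W_AB)):
        if not w > 0 or math.isnan(w):
            raise ValueError(f"{name} must be positive for epsilon to be defined")
    return math.log10((W_AB * W_wt) / (W_A * W_B))


#: Exclusion reason codes for epistasis_distribution.
EXCL_MISSING_SINGLE = "missing_single"
EXCL_NONPOSITIVE = "nonpositive_activity"


def epistasis_distribution(
    table: ActivityTable, activity_floor: float | None = None
) -> tuple[list[EpistasisRecord], dict]:
    """One epistasis record per usable double mutant in the table.

    A double is usable when both constituent singles and the wild-type are
    present with positive activity. Excluded doubles are tallied by reason.
    The summary includes count, mean, and quartiles of epsilon.
    """
    df = table.data
    by_label = dict(zip(df["genotype"], df["fraction_cleaved"]))
    if "WT" not in by_label:
        raise ValueError("activity table must contain the wild-type row")

    def floored(w: float) -> float:
        if activity_floor is not None and not math.isnan(w):
            return max(w, activity_floor)
        return w

    W_wt = floored(float(by_label["WT"]))
    records: list[EpistasisRecord] = []
    exclusions: dict[str, int] = {}
    doubles = df.loc[df["order"] == 2, "genotype"]
    for label in doubles:
        g = Genotype.from_string(label)
        ma, mb = g.mutations
        la, lb = str(Genotype((ma,))), str(Genotype((mb,)))
        if la not in by_label or lb not in by_label:
            exclusions[EXCL_MISSING_SINGLE] = exclusions.get(EXCL_MISSING_SINGLE, 0) + 1
            continue
        W_A = floored(float(by_label[la]))
        W_B = floored(float(by_label[lb]))
        W_AB = floored(float(by_label[label]))
        ws = (W_wt, W_A, W_B, W_AB)
        if any(math.isnan(w) or w <= 0 for w in ws):
            exclusions[EXCL_NONPOSITIVE] = exclusions.get(EXCL_NONPOSITIVE, 0) + 1
            continue
        records.append(
            EpistasisRecord(ma, mb, W_wt, W_A, W_B, W_AB, pairwise_epistasis(*ws))
        )
    eps = np.array([r.epsilon for r in records])
    summary = {
        "n_records": len(records),
        "n_excluded": int(sum(exclusions.values())),
        "exclusions": exclusions,
        "mean": float(eps.mean()) if len(eps) else float("nan"),
        "quantiles": {
            q: float(np.quantile(eps, q)) if len(eps) else float("nan")
            for q in (0.05, 0.25, 0.5, 0.75, 0.95)
        },
    }
    return records, summary


def records_to_frame(records: list[EpistasisRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mutation_a": str(r.mutation_a),
                "mutation_b": str(r.mutation_b),
                "W_wt": r.W_wt,
                "W_A": r.W_A,
                "W_B": r.W_B,
                "W_AB": r.W_AB,
                "epsilon": r.epsilon,
            }
            for r in records
        ],
        columns=["mutation_a", "mutation_b", "W_wt", "W_A", "W_B", "W_AB", "epsilon"],
    )


def epsilon_histogram(records: list[EpistasisRecord], n_bins: int = 50) -> dict:
    """Histogram summary of the epsilon distribution (plot-ready JSON)."""
    eps = np.array([r.epsilon for r in records])
    if len(eps) == 0:
        return {"bin_edges": [], "counts": []}
    counts, edges = np.histogram(eps, bins=n_bins)
    return {"bin_edges": edges.tolist(), "counts": counts.tolist()}


def double_mutant_matrix(
    table: ActivityTable, normalize_to_wildtype: bool = False
) -> pd.DataFrame:
    """Square (position, alt-base)-indexed matrix of double-mutant activities.

    Axis labels are mutation strings ("G1A", ...). Cell [a, b] holds the
    activity of the double mutant {a, b}; it equals cell [b, a] by
    construction, the diagonal block (same position) is NaN, and doubles
    absent from the table stay NaN (missing). With
    ``normalize_to_wildtype``, values are divided by the wild-type activity.
    """
    df = table.data
    doubles = df.loc[df["order"] == 2]
    singles = sorted(
        {
            str(Genotype((m,)))
            for label in doubles["genotype"]
            for m in Genotype.from_string(label).mutations
        }
    )
    mat = pd.DataFrame(np.nan, index=singles, columns=singles)
    wt = None
    if normalize_to_wildtype:
        wt = float(table.data.loc[table.data["genotype"] == "WT", "fraction_cleaved"].iloc[0])
        if not wt > 0:
            raise ValueError("wild-type activity must be positive to normalize")
    for label, fc in zip(doubles["genotype"], doubles["fraction_cleaved"]):
        g = Genotype.from_string(label)
        ma, mb = (str(Genotype((m,))) for m in g.mutations)
        val = fc / wt if wt is not None else fc
        mat.loc[ma, mb] = val
        mat.loc[mb, ma] = val
    return mat
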