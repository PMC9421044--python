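"""Turn cleavage-sequencing reads into a per-genotype activity table.

Each read carries the ribozyme sequence anchored by an exact 3' reverse
transcription primer-binding site. Co-transcriptional self-cleavage removes
the 5' upstream segment, so a read is classified *cleaved* when that segment
is absent and *uncleaved* when it is present. Per-genotype activity is

    fraction cleaved = cleaved / (cleaved + uncleaved)

Reads with unexpected mutations in the primer-binding site, the uncleaved
portion, or the ribozyme sequence are discarded and tallied by reason.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genotypes import (
    Genotype,
    ReferenceSequence,
    VariablePositionScheme,
    normalize_bases,
)

#: Rejection reason codes emitted by classify_read.
REASON_NO_PRIMER = "primer_site_not_found"
REASON_AMBIGUOUS_PRIMER = "primer_site_ambiguous"
REASON_BAD_LENGTH = "ribozyme_region_truncated"
REASON_UNEXPECTED_RIBOZYME = "unexpected_ribozyme_sequence"
REASON_BAD_UPSTREAM = "unexpected_uncleaved_portion"


@dataclass(frozen=True)
class ReadRecord:
    identifier: str
    sequence: str
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be nonempty")


class Rejected:
    """Sentinel returned by classify_read for discarded reads."""

    __slots__ = ("reason",)

    def __init__(self, reason: str):
        self.reason = reason

    def __repr__(self) -> str:
        return f"Rejected({self.reason!r})"


MISSING = float("nan")


@dataclass
class ActivityTable:
    """Per-genotype cleaved/uncleaved counts and fraction cleaved.

    ``data`` has one row per genotype with columns
    ``genotype`` (string syntax, "WT" for order 0), ``order``, ``cleaved``,
    ``uncleaved``, ``total``, ``fraction_cleaved``. Rows whose total is below
    ``min_reads`` carry NaN (missing), never an invented 0.
    """

    data: pd.DataFrame
    reference: ReferenceSequence
    provenance: dict = field(default_factory=dict)

    COLUMNS = ("genotype", "order", "cleaved", "uncleaved", "total", "fraction_cleaved")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"activity table missing columns: {sorted(missing)}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def genotypes(self) -> list[Genotype]:
        return [Genotype.from_string(s) for s in self.data["genotype"]]

    def lookup(self, g: Genotype) -> pd.Series:
        rows = self.data.loc[self.data["genotype"] == str(g)]
        if rows.empty:
            raise KeyError(f"genotype {g} not in table")
        return rows.iloc[0]

    def activity_of(self, g: Genotype) -> float:
        return float(self.lookup(g)["fraction_cleaved"])

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[Genotype, tuple[int, int]],
        reference: ReferenceSequence,
        min_reads: int = 1,
        provenance: dict | None = None,
    ) -> "ActivityTable":
        rows = []
        for g in sorted(counts, key=lambda g: (g.order, str(g))):
            c, u = counts[g]
            rows.append(
                {
                    "genotype": str(g),
                    "order": g.order,
                    "cleaved": int(c),
                    "uncleaved": int(u),
                    "total": int(c + u),
                    "fraction_cleaved": fraction_cleaved(c, u, min_reads=min_reads),
                }
            )
        prov = dict(provenance or {})
        prov.setdefault("min_reads", min_reads)
        prov.setdefault("position_convention", "1-based")
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df, reference, prov)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False, na_rep="NA")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(
            json.dumps(
                {"reference": self.reference.bases, **self.provenance},
                indent=2,
                default=str,
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path, reference: ReferenceSequence | None = None) -> "ActivityTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        prov: dict = {}
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        if sidecar.exists():
            prov = json.loads(sidecar.read_text())
            if reference is None and "reference" in prov:
                reference = ReferenceSequence(prov.pop("reference"))
            else:
                prov.pop("reference", None)
        if reference is None:
            raise ValueError("reference sequence required (no provenance sidecar found)")
        if "order" not in df.columns:
            df["order"] = [Genotype.from_string(s).order for s in df["genotype"]]
        if "total" not in df.columns:
            df["total"] = df["cleaved"] + df["uncleaved"]
        return cls(df, reference, prov)


# ---------------------------------------------------------------------------
# Estimators


def fraction_cleaved(cleaved: int, uncleaved: int, min_reads: int = 1) -> float:
    """c / (c + u), or NaN (missing) when the total is below ``min_reads``."""
    if cleaved < 0 or uncleaved < 0:
        raise ValueError("counts must be non-negative")
    total = cleaved + uncleaved
    if total < max(min_reads, 1):
        return MISSING
    return cleaved / total


def relative_activity(fc: float, fc_wildtype: float) -> float:
    """Fraction cleaved normalized to the wild-type's (display only)."""
    if not fc_wildtype > 0:
        raise ValueError("wild-type fraction cleaved must be positive")
    return fc / fc_wildtype


# ---------------------------------------------------------------------------
# Read classification


class ReadClassifier:
    """Classify reads into (genotype, cleaved-flag) or reject them.

    The 3' primer-binding site is located by exact substring match (no
    mismatch tolerance); the ribozyme region is the L bases immediately 5' of
    it, and the cleavage state is read from the presence/absence of the
    upstream segment before that.

    Modes
    -----
    match_list
        The ribozyme region must exactly equal one of the expected variant
        sequences (e.g. all single and double mutants); anything else is
        discarded as an unexpected mutation.
    variable_positions
        Bases are read off at the scheme's variable positions; any deviation
        from the reference outside them, or a disallowed base at one of them,
        discards the read.
    """

    def __init__(
        self,
        ref: ReferenceSequence,
        upstream_seq: str,
        primer_site: str,
        mode: str = "match_list",
        expected_genotypes: Iterable[Genotype] | None = None,
        scheme: VariablePositionScheme | None = None,
    ):
        if mode not in ("match_list", "variable_positions"):
            raise ValueError(f"unknown mode {mode!r}")
        self.ref = ref
        self.upstream_seq = normalize_bases(upstream_seq)
        self.primer_site = normalize_bases(primer_site)
        if not self.upstream_seq or not self.primer_site:
            raise ValueError("upstream_seq and primer_site must be nonempty")
        self.mode = mode
        self._expected: dict[str, Genotype] | None = None
        self.scheme = scheme
        if mode == "match_list":
            if expected_genotypes is None:
                raise ValueError("match_list mode requires expected_genotypes")
            self._expected = {g.sequence(ref): g for g in expected_genotypes}
        else:
            if scheme is None:
                raise ValueError("variable_positions mode requires a scheme")
            scheme.validate_against(ref)
            self._allowed = {
                pos: set(alts) | {ref.base_at(pos)} for pos, alts in scheme.entries
            }

    def classify(self, read: ReadRecord) -> tuple[Genotype, bool] | Rejected:
        """Return (genotype, cleaved) or a Rejected sentinel with a reason code."""
        seq = normalize_bases(read.sequence)
        first = seq.find(self.primer_site)
        if first == -1:
            return Rejected(REASON_NO_PRIMER)
        if seq.find(self.primer_site, first + 1) != -1:
            return Rejected(REASON_AMBIGUOUS_PRIMER)
        L = len(self.ref)
        start = first - L
        if start < 0:
            return Rejected(REASON_BAD_LENGTH)
        ribo = seq[start:first]
        prefix = seq[:start]
        if prefix == "":
            cleaved = True
        elif prefix == self.upstream_seq:
            cleaved = False
        else:
            return Rejected(REASON_BAD_UPSTREAM)
        if self.mode == "match_list":
            g = self._expected.get(ribo)
            if g is None:
                return Rejected(REASON_UNEXPECTED_RIBOZYME)
            return g, cleaved
        # variable_positions: everything outside the scheme must match reference
        muts = []
        for i, (r, s) in enumerate(zip(self.ref.bases, ribo)):
            if r == s:
                continue
            pos = i + 1
            allowed = self._allowed.get(pos)
            if allowed is None or s not in allowed:
                return Rejected(REASON_UNEXPECTED_RIBOZYME)
            muts.append((pos, r, s))
        from .genotypes import Mutation

        return Genotype(tuple(Mutation(*m) for m in muts)), cleaved


def classify_read(
    read: ReadRecord,
    ref: ReferenceSequence,
    upstream_seq: str,
    primer_site: str,
    mode: str = "match_list",
    expected_genotypes: Iterable[Genotype] | None = None,
    scheme: VariablePositionScheme | None = None,
) -> tuple[Genotype, bool] | Rejected:
    """One-shot wrapper around :class:`ReadClassifier` for a single read."""
    return ReadClassifier(
        ref, upstream_seq, primer_site, mode, expected_genotypes, scheme
    ).classify(read)


# ---------------------------------------------------------------------------
# Counting


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a plain or gzipped FASTQ file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
            try:
                yield ReadRecord(
                    identifier=rec.id,
                    sequence=str(rec.seq),
                    quality="",
                )
            except ValueError as exc:
                raise ValueError(f"unreadable FASTQ record index {i}: {exc}") from exc


def count_genotypes(
    reads: Iterable[ReadRecord],
    ref: ReferenceSequence,
    upstream_seq: str,
    primer_site: str,
    mode: str = "match_list",
    expected_genotypes: Iterable[Genotype] | None = None,
    scheme: VariablePositionScheme | None = None,
    min_reads: int = 1,
    provenance: dict | None = None,
) -> tuple[ActivityTable, dict]:
    """Single-pass tally of cleaved/uncleaved reads per genotype.

    Returns the activity table and a rejection summary mapping reason code to
    count (plus ``total_reads``, ``classified``, ``rejected``), satisfying
    cleaved + uncleaved + rejected = total.
    """
    classifier = ReadClassifier(
        ref, upstream_seq, primer_site, mode, expected_genotypes, scheme
    )
    counts: dict[Genotype, list[int]] = {}
    rejections: dict[str, int] = {}
    total = 0
    for read in reads:
        total += 1
        result = classifier.classify(read)
        if isinstance(result, Rejected):
            rejections[result.reason] = rejections.get(result.reason, 0) + 1
            continue
        g, cleaved = result
        slot = counts.setdefault(g, [0, 0])
        slot[0 if cleaved else 1] += 1
    n_rejected = sum(rejections.values())
    summary = {
        "total_reads": total,
        "classified": total - n_rejected,
        "rejected": n_rejected,
        "by_reason": rejections,
    }
    prov = dict(provenance or {})
    prov.update(
        {
            "mode": mode,
            "upstream_seq": normalize_bases(upstream_seq),
            "primer_site": normalize_bases(primer_site),
            "rejection_summary": summary,
        }
    )
    table = ActivityTable.from_counts(
        {g: (c, u) for g, (c, u) in counts.items()},
        ref,
        min_reads=min_reads,
        provenance=prov,
    )
    return table, summary


def count_fastq_files(
    paths: Iterable[str | Path],
    ref: ReferenceSequence,
    pooled: bool = True,
    **kwargs,
) -> tuple[ActivityTable, dict] | list[tuple[ActivityTable, dict]]:
    """Count genotypes across one or more FASTQ files.

    With ``pooled=True`` (default) counts are pooled across files into one
    table, mirroring pooled sequencing replicates; otherwise one table per
    file is returned.
    """
    paths = [Path(p) for p in paths]
    if pooled:

        def chain() -> Iterator[ReadRecord]:
            for p in paths:
                yield from read_fastq(p)

        table, summary = count_genotypes(chain(), ref, **kwargs)
        table.provenance["source_files"] = [str(p) for p in paths]
        return table, summary
    results = []
    for p in paths:
        table, summary = count_genotypes(read_fastq(p), ref, **kwargs)
        table.provenance["source_files"] = [str(p)]
        results.append((table, summary))
    return results
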