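"""Shared constants for the analysis drivers."""

from pathlib import Path

#: Synthetic 69-nt reference used by the desk-scale study (the experimental
#: reference sequence is not redistributed here; any 69-nt sequence exercises
#: the identical pipeline).
REF69 = "GCAUCGGAUCCGGAAACGGUUAAGGGCUAUGGACUCAUAAGGUCCAGGCAAUGCCUCGAUCCAAGGCAU"

BASE_SEED = 20260920

RESULTS = Path(__file__).resolve().parent.parent / "results"


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
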