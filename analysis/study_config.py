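"""Shared desk-scale study configuration for the analysis drivers.

One discovery cohort (40 gout-like cases / 40 controls) and one smaller
validation cohort (15/15) are generated from the same catalog and planted
design, mirroring a two-cohort case-control study with longitudinal
follow-up of the cases.  All drivers read and write under results/.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"

SEED = 20260101
N_GENES = 2000
N_SPECIES = 50
N_KOS = 200
DEPTH = 20_000
EQUAL_DEPTH = 15_000  # matched-read downsampling target across samples

DISCOVERY = dict(n_case=40, n_control=40)
VALIDATION = dict(n_case=15, n_control=15)
RECOVERY = {"2W": 0.1, "4W": 0.3, "24W": 0.8}
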