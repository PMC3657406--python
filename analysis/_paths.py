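"""Shared locations for the analysis drivers."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
DATA = SCRATCH / "data"
RESULTS = ROOT / "results"

for _p in (SCRATCH, RESULTS):
    _p.mkdir(exist_ok=True)
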