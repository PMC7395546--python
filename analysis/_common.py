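"""Shared settings for the analysis drivers."""

from pathlib import Path

SEED = 20240101
_ROOT = Path(__file__).resolve().parent.parent
RESULTS = _ROOT / "results"
RESULTS.mkdir(exist_ok=True)
# simulated track tables are bulky regenerable intermediates; keep them out
# of results/ so that directory holds only the small summary tables
SCRATCH = _ROOT / "scratch" / "sim"
SCRATCH.mkdir(parents=True, exist_ok=True)
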