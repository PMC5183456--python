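"""Substitution patterns in transferred genes: dN/dS per event and the paired
autolog comparison (dS vs dN, prophage-copy vs genomic-copy CAI)."""

import json
from pathlib import Path

from phagelgt.io import load_dataset
from phagelgt.pipeline import PipelineConfig, stage_donors, stage_selection

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = load_dataset(ROOT / "data")
    config = PipelineConfig(outdir=str(ROOT / "run"), seed=1)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls = stage_donors(dataset, config, outdir)
    report = stage_selection(dataset, calls, config, outdir)
    print(json.dumps(report, sort_keys=True, indent=2))


if __name__ == "__main__":
    main()
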