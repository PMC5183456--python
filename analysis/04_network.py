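"""Assemble the dLGT network and report its structure and autolog census."""

import json
from pathlib import Path

from phagelgt.io import load_dataset
from phagelgt.pipeline import (
    PipelineConfig, events_from_calls, stage_clustering, stage_donors, stage_network,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = load_dataset(ROOT / "data")
    config = PipelineConfig(outdir=str(ROOT / "run"), seed=1)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mapping = stage_clustering(dataset, config, outdir)
    calls = stage_donors(dataset, config, outdir)
    events = events_from_calls(dataset, calls, mapping)
    result = stage_network(dataset, events, outdir)
    print(json.dumps(result["report"]["stats_full"], sort_keys=True, indent=2))
    print(json.dumps(result["report"]["autologs"], sort_keys=True, indent=2))
    print("host range (donor-recipient ranks):",
          result["report"]["host_range"]["donor_recipient_rank_counts"])


if __name__ == "__main__":
    main()
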