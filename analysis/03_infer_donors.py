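"""Infer the donor genome of every bacterial-flagged prophage gene and
compare the calls against the planted ledger."""

from pathlib import Path

from phagelgt.io import load_dataset
from phagelgt.pipeline import PipelineConfig, stage_donors

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = load_dataset(ROOT / "data")
    config = PipelineConfig(outdir=str(ROOT / "run"), seed=1)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls = stage_donors(dataset, config, outdir)
    resolved = [c for c in calls if not c.excluded]
    print(f"queries: {len(calls)}, resolved: {len(resolved)}")
    by_reason: dict[str, int] = {}
    for c in calls:
        if c.excluded:
            by_reason[c.exclusion_reason] = by_reason.get(c.exclusion_reason, 0) + 1
    for reason, n in sorted(by_reason.items()):
        print(f"excluded ({reason}): {n}")

    if dataset.ledger is not None:
        truth = dataset.ledger.by_gene()
        correct = sum(1 for c in resolved if truth[c.gene_id].donor == c.donor)
        print(f"precision vs ledger: {correct}/{len(resolved)} = "
              f"{correct / len(resolved):.3f}")


if __name__ == "__main__":
    main()
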