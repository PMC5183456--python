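"""Cluster prophage proteins into families and prophages into phage entities."""

from pathlib import Path

from phagelgt.io import load_dataset
from phagelgt.pipeline import PipelineConfig, stage_clustering

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = load_dataset(ROOT / "data")
    config = PipelineConfig(outdir=str(ROOT / "run"), seed=1)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mapping = stage_clustering(dataset, config, outdir)
    entities = set(mapping.values())
    singletons = sum(
        1 for e in entities
        if sum(1 for v in mapping.values() if v == e) == 1
    )
    print(f"prophages clustered: {len(mapping)}")
    print(f"phage entities: {len(entities)} ({singletons} singletons)")


if __name__ == "__main__":
    main()
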