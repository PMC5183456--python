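"""Generate the study dataset: 50 genomes, 200 planted transduction events.

Defaults are the study conditions: similarity-kernel placement (strength 10),
9% autologs, omega 0.12, 5 expected post-transfer substitutions per gene.
Writes the dataset directory under results/data/.
"""

from pathlib import Path

from phagelgt.io import save_dataset
from phagelgt.simulate import SimConfig, simulate_dataset

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    config = SimConfig(seed=SEED, n_subs_per_event=5.0)
    dataset, ledger = simulate_dataset(config)
    save_dataset(dataset, OUT)
    n_auto = sum(ev.is_autolog for ev in ledger.events)
    print(f"genomes: {len(dataset.genomes)}")
    print(f"planted events: {len(ledger.events)} ({n_auto} autologs)")
    print(f"dataset written to {OUT}")


if __name__ == "__main__":
    main()
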