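#!/usr/bin/env python
"""Generate the miniature two-hemisphere synthetic brain.

Three neuroblast lineages (an EB ring-neuron lineage, a tuberculo-bulbar
lineage and an FB large-field lineage) are planted with 50-150 fibers
per tract, 8 nm skeleton node spacing, connector-free twig artifacts and
block-structured connectivity.  The dataset (SWC skeletons, synapse
table, compartment and bundle annotations, ground truth) is written to
scratch/brain/ for the downstream analysis steps; a summary of the
planted composition goes to results/.
"""

from pathlib import Path

from cxlineage.synth import default_config, generate_brain, write_dataset

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "brain"
RESULTS = ROOT / "results"

def main():
    ds = generate_brain(default_config(seed=7, mirror=True))
    write_dataset(ds, OUT)
    RESULTS.mkdir(exist_ok=True)
    comp = ds.neurons.groupby(["lineage", "hemisphere"])["neuron_id"].count()
    comp.rename("n_neurons").to_csv(RESULTS / "planted_composition.csv")
    print(f"wrote {len(ds.skeletons)} skeletons and "
          f"{len(ds.connectors)} synapses to {OUT}")
    print(comp)


if __name__ == "__main__":
    main()
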