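#!/usr/bin/env python
"""Generate the matched wild-type-like and mutant-like synthetic datasets.

The two systems differ only in their planted contrasts: basin width (one
dominant large-amplitude mode in the mutant-like arm), approaching vs
departing interface drift, interface interaction occupancies, and the hub
residue's contacts. Writes structure, multi-model trajectory, parameter table
and the planted-truth file for each arm under results/data/.
"""

from common import SEED, dataset_paths, DATA

from ppidyn.structio import write_parameter_table, write_structure, write_trajectory_pdb
from ppidyn.synthetic import make_scenario_pair


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    pair = make_scenario_pair(seed=SEED)
    for tag in ("wt", "mut"):
        d = pair[tag]
        p = dataset_paths(tag)
        write_structure(d["model"], p["structure"])
        write_trajectory_pdb(d["trajectory"], p["trajectory"])
        write_parameter_table(d["params"], p["parameters"])
        p["truth"].write_text(d["truth"].to_text())
        print(f"[{tag}] {d['model'].n_atoms} atoms, {d['trajectory'].n_frames} frames "
              f"-> {p['structure'].parent}")
    print("planted contrasts: occupancies, basin width, drift sign, hub contacts")


if __name__ == "__main__":
    main()
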