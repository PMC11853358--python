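"""Shared plumbing for the numbered analysis scripts.

Script 01 writes the two synthetic datasets (structure, trajectory,
parameters, planted truth) under ``results/data``; later scripts load them
from disk through the package's standard readers, exactly as they would load
a deposited trajectory.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"

SEED = 20250101
HUB = "P:459"


def dataset_paths(tag: str) -> dict:
    return {
        "structure": DATA / f"{tag}_structure.pdb",
        "trajectory": DATA / f"{tag}_trajectory.pdb",
        "parameters": DATA / f"{tag}_parameters.tsv",
        "truth": DATA / f"{tag}_truth.txt",
    }


def load(tag: str):
    from ppidyn.energetics import ForceFieldParameters
    from ppidyn.structio import (
        apply_parameters,
        read_parameter_table,
        read_structure,
        read_trajectory,
    )

    p = dataset_paths(tag)
    model = apply_parameters(read_structure(p["structure"]), read_parameter_table(p["parameters"]))
    traj = read_trajectory(p["trajectory"], model)
    return {
        "model": model,
        "trajectory": traj,
        "ff": ForceFieldParameters.from_model(model),
    }


def outdir(stage: str) -> Path:
    d = RESULTS / stage
    d.mkdir(parents=True, exist_ok=True)
    return d
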