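#!/usr/bin/env python
"""Full paired comparison report: every stage for both systems, one table.

Thin driver over ppidyn.pipeline.run_compare; all numbers in the report are
traceable to per-stage files under results/compare/.
"""

from common import HUB, RESULTS, SEED, load

from ppidyn.pipeline import RunConfig, run_compare


def main() -> None:
    cfg_wt = RunConfig(name="wt", seed=SEED, output_dir=str(RESULTS / "compare" / "wt"),
                       interface_stride=10, energy_stride=10, decomposition_stride=50)
    cfg_mut = RunConfig(name="mut", seed=SEED, output_dir=str(RESULTS / "compare" / "mut"),
                        interface_stride=10, energy_stride=10, decomposition_stride=50)
    report = run_compare(cfg_wt, cfg_mut, dataset_a=load("wt"), dataset_b=load("mut"), hub=HUB)
    print(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    if report.attrs["failed"]:
        for f in report.attrs["failed"]:
            print("FAILED:", f)
        raise SystemExit(1)


if __name__ == "__main__":
    main()
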