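#!/usr/bin/env python
"""Generate the two datasets every later step analyses.

Writes (a) the deterministic reference fixture - a 512-participant cohort
whose marginal counts equal the reported week-96 trial tables - and (b) a
seeded stochastic cohort from the synthetic-trial generator with the same
visit structure, for sensitivity runs at other sample sizes.
"""

from pathlib import Path

from virosnap.io import write_trial_dataset
from virosnap.simulate import SimConfig, generate_trial, make_fixture

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fixture = make_fixture()
    write_trial_dataset(fixture, RESULTS / "data" / "reference")
    print(f"reference fixture: {len(fixture.participants)} participants "
          f"({(fixture.participants['arm'] == 'long_acting').sum()} long-acting, "
          f"{(fixture.participants['arm'] == 'oral').sum()} oral)")

    cfg = SimConfig(seed=20240901)
    simulated = generate_trial(cfg)
    write_trial_dataset(simulated, RESULTS / "data" / "simulated_seed20240901")
    cfg.to_yaml(RESULTS / "data" / "simulated_seed20240901" / "sim_config.yaml")
    print(f"simulated cohort: {len(simulated.participants)} participants, "
          f"{len(simulated.viral_loads)} viral-load rows, "
          f"{len(simulated.sequences)} baseline sequences")


if __name__ == "__main__":
    main()
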