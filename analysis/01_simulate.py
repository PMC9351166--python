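"""Generate the paper-scale synthetic study inputs.

Writes a 144-neighbourhood lattice (1 km cells) with heterogeneous
populations, 25 candidate covariates (4 truly driving the event rate),
~700 point events over 10 years, and two implanted space-time cylinders
of elevated relative risk — then prints what was implanted so later
scripts can be judged against the ground truth.
"""

import json
from pathlib import Path

from urbanscan.pipeline import make_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "fixture"

if __name__ == "__main__":
    fx = make_fixture(OUT, preset="paper-scale", seed=1)
    truth = fx["truth"]
    print(f"areas: {fx['areas'].n}, total events: {truth['total_events']}")
    print(f"active covariates: {truth['active_covariates']}")
    for i, cl in enumerate(truth["clusters"], 1):
        print(
            f"implanted cluster {i}: {len(cl['areas'])} areas, "
            f"years {cl['years'][0]}-{cl['years'][1]}, RR={cl['rr']}"
        )
    print(f"inputs written to {OUT}")
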