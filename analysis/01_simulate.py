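#!/usr/bin/env python
"""Generate the synthetic study systems used by the downstream analyses.

Writes four trajectory bundles under results/data/:

* closed      — WT-like occluded channel, no planted events;
* planted     — closed channel with 4 steered K+ crossings (ground truth
                for the permeation analysis);
* displaced   — single subunit ramped radially outward by 3 A (the
                asymmetric-gating study system);
* hydrated    — same geometry with the occluded core allowed to hydrate
                (contrast system for the water maps).

Each bundle is prefix.{pdb,xyz,topology.tsv,truth.json}.
"""

from pathlib import Path

from channelgate import SyntheticConfig, simulate
from channelgate.synthetic import write_bundle

OUT = Path("results/data")

SYSTEMS = {
    "closed": dict(planted_permeations=0),
    "planted": dict(planted_permeations=4),
    "displaced": dict(planted_permeations=0, n_waters=0, n_cations=0,
                      n_anions=0, subunit_displacement=(1, 3.0), n_frames=100),
    "hydrated": dict(planted_permeations=0, hydrate_pore=True),
}


def main(seed: int = 2024) -> None:
    for name, overrides in SYSTEMS.items():
        cfg = SyntheticConfig(**{
            "seed": seed, "n_frames": 200, "dt": 0.1, "n_cations": 20,
            "n_anions": 10, "n_waters": 400, **overrides})
        traj, truth = simulate(cfg)
        write_bundle(OUT / name, traj, truth)
        print(f"{name}: {len(traj)} frames, {traj.topology.n_atoms} atoms, "
              f"{len(truth.permeation_events)} planted events "
              f"-> results/data/{name}.*")


if __name__ == "__main__":
    main()
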