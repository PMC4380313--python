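#!/usr/bin/env python
"""Asymmetric gating signature: native-contact retention per helix pair.

Ramps a 3 A radial displacement of subunit 1 across the trajectory and
tracks the retained fraction of native inner-helix contacts for the two
interfaces of the displaced subunit (1-2, 1-5) against two undisplaced
interfaces (2-3, 4-5). The displaced interfaces lose contacts selectively,
while the others stay intact. Writes results/contact_retention.tsv.
"""

from pathlib import Path

import numpy as np

from channelgate import (SyntheticConfig, contact_retention, native_contacts,
                         rmsd_series, simulate)

PAIRS = [(1, 2), (1, 5), (2, 3), (4, 5)]


def main(seed: int = 2024) -> None:
    cfg = SyntheticConfig(seed=seed, n_frames=100, dt=0.1, n_cations=0,
                          n_anions=0, n_waters=0,
                          subunit_displacement=(1, 3.0))
    traj, truth = simulate(cfg)
    cs = native_contacts(traj.frames[0], traj.topology, PAIRS,
                         residue_range=(15, 33), cutoff=8.0)
    ret = contact_retention(traj, cs, tolerance_factor=1.2)
    cols = [traj.times] + [ret.fraction_per_frame[p] for p in PAIRS]
    Path("results").mkdir(exist_ok=True)
    np.savetxt("results/contact_retention.tsv", np.column_stack(cols),
               header="time_ns\t" + "\t".join(f"{a}-{b}" for a, b in PAIRS),
               delimiter="\t")
    print(f"displaced subunit: {truth.displaced_subunit} "
          f"(interfaces {truth.displaced_contacts})")
    for p in PAIRS:
        print(f"  TM1({p[0]})-TM1({p[1]}): native {len(cs.pairs[p]):3d} pairs,"
              f" final retention {ret.fraction_per_frame[p][-1]:.2f}")
    series = rmsd_series(traj, traj.frames[0],
                         traj.topology.calpha_indices())
    print(f"C-alpha RMSD to start rises to {series[-1]:.2f} A "
          f"as the subunit displaces")


if __name__ == "__main__":
    main()
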