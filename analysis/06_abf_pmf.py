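#!/usr/bin/env python
"""Free-energy profiles by windowed ABF on toy Langevin systems.

Runs the windowed protocol (abutting 2 A windows, 0.2 A bins, linear bias
ramp) on a harmonic well and on a 3 kcal/mol double-well, and checks the
estimates against the analytic potentials. Writes results/pmf_harmonic.tsv
and results/pmf_double_well.tsv.
"""

from pathlib import Path

import numpy as np

from channelgate import ToySystem, make_potential, run_windowed_abf


def main(seed: int = 2024) -> None:
    Path("results").mkdir(exist_ok=True)

    sys_h = ToySystem(make_potential("harmonic", k=1.0), seed=seed)
    prof = run_windowed_abf(sys_h, -2.0, 2.0, window_width=2.0,
                            steps_per_window=100_000)
    ref = 0.5 * prof.z_grid**2
    ref -= ref.min()
    k_est = 2.0 * np.polyfit(prof.z_grid, prof.free_energy, 2)[0]
    np.savetxt("results/pmf_harmonic.tsv",
               np.column_stack([prof.z_grid, prof.free_energy, ref]),
               header="z\tA_kcal_mol\tanalytic", delimiter="\t")
    print(f"harmonic: k_est = {k_est:.3f} kcal/mol/A^2 (true 1.0), "
          f"max |A - U| = {np.abs(prof.free_energy - ref).max():.3f} kcal/mol")

    pot = make_potential("double_well", barrier=3.0, half_width=1.0)
    sys_d = ToySystem(pot, seed=seed + 1)
    prof_d = run_windowed_abf(sys_d, -1.6, 1.6, window_width=1.6,
                              steps_per_window=150_000)
    ref_d = pot.u(prof_d.z_grid)
    ref_d -= ref_d.min()
    np.savetxt("results/pmf_double_well.tsv",
               np.column_stack([prof_d.z_grid, prof_d.free_energy, ref_d]),
               header="z\tA_kcal_mol\tanalytic", delimiter="\t")
    barrier = prof_d.free_energy[np.argmin(np.abs(prof_d.z_grid))]
    print(f"double well: estimated barrier {barrier:.2f} kcal/mol "
          f"(true 3.0 at z=0), max error "
          f"{np.abs(prof_d.free_energy - ref_d).max():.3f} kcal/mol")


if __name__ == "__main__":
    main()
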