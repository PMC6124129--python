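#!/usr/bin/env python
"""Navigate the tumour parameter space from steady-state oxygen profiles.

Procedure: pick a target colony radius, place a doubly occupied disc of
that radius, solve the steady oxygen problem, and read off where the
proliferation (c = kappa_prol) and survival (c = kappa_death) contours
sit.  Scanning the radius shows which colony sizes a given domain can
drive quiescent or necrotic, which is how the default tumour domain and
horizon were chosen.  Purely deterministic; no simulation is run.

Usage::

    python scripts/tumour_steady_state_scan.py [--extent 81] [--lam 0.0015]
"""

from __future__ import annotations

import argparse

import numpy as np

from dlcm import assemble_laplacian, build_structured_grid, initialize_state
from dlcm.experiments import TumourParams, circular_region, tumour_oxygen


def scan(extent: int, lam: float, params: TumourParams, radii) -> None:
    grid = build_structured_grid(
        "cartesian2d", (extent, extent), h=1.0,
        origin=(-(extent - 1) / 2.0, -(extent - 1) / 2.0))
    L = assemble_laplacian(grid)
    print(f"# domain {extent}x{extent}, lam={lam}, "
          f"kappa_prol={params.kappa_prol}, kappa_death={params.kappa_death}")
    print("# radius  n_cells  min_c   r(c<kappa_prol)  r(c<kappa_death)")
    for a in radii:
        occ = circular_region(grid, a, value=2)
        state = initialize_state(grid, occ)
        c = tumour_oxygen(state, grid, L, lam)
        r = np.linalg.norm(grid.centers, axis=1)
        quiescent = r[c < params.kappa_prol]
        necrotic = r[c < params.kappa_death]
        print(f"{a:7.1f}  {int(occ.sum()):7d}  {c.min():.3f}"
              f"  {quiescent.max() if quiescent.size else float('nan'):>15.1f}"
              f"  {necrotic.max() if necrotic.size else float('nan'):>16.1f}")


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--extent", type=int, default=81)
    parser.add_argument("--lam", type=float, default=TumourParams().lam)
    parser.add_argument("--radii", type=float, nargs="+",
                        default=[8, 10, 12, 14, 16, 18, 20])
    args = parser.parse_args(argv)
    scan(args.extent, args.lam, TumourParams(lam=args.lam), args.radii)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
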