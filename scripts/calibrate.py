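"""Calibrate the wild-type defaults against the published activation schedule.

Grid-searches the activation rate ``k_act``, the barrier bypass
probability ``p_bypass`` and the reverse-face stall/escape pair (the
parameters the timecourse constrains but the data do not fix directly) by
minimizing

    sum_G (median simulated onset_G - target_G)^2

over replicate seeds per grid point, with the published wild-type schedule
as target groups: Hoxd4 by 84 h, Hoxd8/Hoxd9 (pooled) at 108 h,
Hoxd10/Hoxd11 (pooled) at 132 h, Hoxd13 around 144 h.  The winning point
is written into ``src/hoxtimer/data/default_config.toml`` (the shipped
default); the full objective table goes to
``scratch/calibration_table.csv``.  The shipped configuration is the
argmin of this script at ``--replicates 80 --seed 0``.

Run from the repository root:

    python scripts/calibrate.py [--replicates 80] [--seed 0]
"""

import argparse
import pathlib
import re
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from hoxtimer import build_default_hoxd_locus  # noqa: E402
from hoxtimer.config import default_params  # noqa: E402
from hoxtimer.timer import calibrate_defaults  # noqa: E402

# The timecourse reports gene pairs at shared timepoints; each group is
# fitted as the pooled median of its genes' onset samples.
SCHEDULE_TARGETS = {
    "Hoxd4": 84.0,
    ("Hoxd8", "Hoxd9"): 108.0,
    ("Hoxd10", "Hoxd11"): 132.0,
    "Hoxd13": 144.0,
}

# k_act and p_bypass set the overall pace; p_stall_reverse/p_bypass_reverse
# (the weak non-motif-face hindrance) mostly shape the posterior tail of the
# schedule.  unload_prob was searched in an earlier round; its optimum
# (1e-3) is kept fixed here.
SEARCH_SPACE = {
    "k_act": [0.08, 0.09],
    "p_bypass": [1.2e-4, 1.35e-4],
    "p_stall_reverse": [0.2, 0.5, 0.6],
}
PAIRED = {  # reverse-face escape paired to capture strength
    0.2: 8e-3,
    0.5: 5e-3,
    0.6: 4e-3,
}


def main(argv=None):
    ap = argparse.ArgumentParser()
    ap.add_argument("--replicates", type=int, default=80)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--no-write", action="store_true", help="do not update the shipped config")
    args = ap.parse_args(argv)

    import dataclasses

    import pandas as pd

    locus = build_default_hoxd_locus()
    sim0, tim0 = default_params()
    result = None
    tables = []
    for psr, pbr in PAIRED.items():
        if psr not in SEARCH_SPACE["p_stall_reverse"]:
            continue
        base_sim = dataclasses.replace(sim0, p_stall_reverse=psr, p_bypass_reverse=pbr)
        space = {k: v for k, v in SEARCH_SPACE.items() if k != "p_stall_reverse"}
        res = calibrate_defaults(
            space,
            SCHEDULE_TARGETS,
            locus,
            sim_params=base_sim,
            timer_params=tim0,
            n_replicates=args.replicates,
            seed=args.seed,
        )
        res.table.insert(0, "p_stall_reverse", psr)
        res.table.insert(1, "p_bypass_reverse", pbr)
        tables.append(res.table)
        if result is None or res.objective < result.objective:
            result = res
    table = pd.concat(tables, ignore_index=True)
    result.table = table
    print(table.to_string(index=False))
    print(f"\nbest objective: {result.objective:.1f}")
    print(
        f"best k_act={result.timer_params.k_act} "
        f"p_bypass={result.sim_params.p_bypass} "
        f"p_stall_reverse={result.sim_params.p_stall_reverse} "
        f"p_bypass_reverse={result.sim_params.p_bypass_reverse}"
    )

    root = pathlib.Path(__file__).resolve().parents[1]
    scratch = root / "scratch"
    scratch.mkdir(exist_ok=True)
    result.table.to_csv(scratch / "calibration_table.csv", index=False)

    if not args.no_write:
        cfg_path = root / "src" / "hoxtimer" / "data" / "default_config.toml"
        text = cfg_path.read_text()
        for name in list(SEARCH_SPACE) + ["p_bypass_reverse"]:
            value = getattr(result.sim_params, name, None)
            if value is None:
                value = getattr(result.timer_params, name)
            text = re.sub(
                rf"(?m)^{name} = [0-9.e-]+", f"{name} = {value}", text
            )
        cfg_path.write_text(text)
        print(f"updated {cfg_path}")


if __name__ == "__main__":
    main()
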