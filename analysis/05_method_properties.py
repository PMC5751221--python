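#!/usr/bin/env python
"""Spot-check the method's statistical properties at reduced scale.

A quick, narrated version of the checks the test suite runs in full: the
reduction identity (coevolution model at equal rates equals the independent
null), the held-out exceedance of the simulated dAIC thresholds, and
detection of planted coevolving pairs.  Writes results/properties.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from melcoev import coevolution as cv
from melcoev import synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    base = sd.generate_tree(20, seed=101, height=0.5)
    tree = base.with_blen(np.where(base.parent >= 0, 0.1, 0.0))
    engine = cv.CoevEngine(tree)

    rng = np.random.default_rng(0)
    letters = np.array(list("ACGT"))
    worst = 0.0
    for _ in range(50):
        a = letters[rng.integers(0, 4, tree.n_leaves)]
        b = letters[rng.integers(0, 4, tree.n_leaves)]
        prof = cv.select_profile(a, b)
        if prof is None:
            continue
        ll16 = cv.coev_pair_loglik(a, b, tree, prof, 1 / 3, 1 / 3)
        ll_ind, _, _ = cv.fit_independent_pair(a, b, tree)
        worst = max(worst, abs(ll16 - ll_ind))
    print(f"reduction identity, max |coev(s=d) - independent|: {worst:.2e}")

    calib = cv.calibrate_null(tree, nsites=120, seed=42, n_pairs=4000,
                              engine=engine)
    print("dAIC thresholds:", {k: round(v, 2)
                               for k, v in calib.thresholds.items()})
    cols = cv.simulate_null_columns(tree, 120, seed=77)
    idx = np.random.default_rng(78).permutation(120).reshape(60, 2)
    held = cv.score_site_pairs(cols, cols, idx, tree, engine)
    exceed = float((held["delta_aic"] > calib.thresholds["95"]).mean())
    print(f"held-out exceedance of theta95: {100 * exceed:.1f}% (nominal 5%)")

    profile = cv.CoevProfile("AT", "GC")
    rng = np.random.default_rng(7)
    partials, lls = [], []
    for _ in range(30):
        a, b = sd.simulate_coev_pair(tree, profile, 10.0, 1.0, rng)
        prof = cv.select_profile(a, b)
        if prof is None:
            continue
        partials.append(cv.pair_leaf_partials(a, b, prof))
        lls.append(cv.fit_independent_pair(a, b, tree)[0])
    ll, _, _ = engine.fit_pairs(np.stack(partials))
    delta = 2 * (ll - np.array(lls)) - 4
    power = float((delta > calib.thresholds["95"]).mean())
    print(f"detection of planted s/d=10 pairs at theta95: {100 * power:.0f}%")

    with open(OUT / "properties.json", "w") as fh:
        json.dump({
            "reduction_identity_max_abs_diff": worst,
            "thresholds": calib.thresholds,
            "held_out_exceedance_theta95_pct": round(100 * exceed, 1),
            "planted_pair_detection_pct": round(100 * power, 1),
        }, fh, indent=2)
    print(f"wrote {OUT / 'properties.json'}")


if __name__ == "__main__":
    main()
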