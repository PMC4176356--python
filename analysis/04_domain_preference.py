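#!/usr/bin/env python
"""Intra- vs inter-domain enhancer-promoter preference (tethered loops).

Two chromatin loops tethered into neighbouring topological domains; one
enhancer has equal affinity (eps = 8 k_BT) to two equidistant promoters,
one in its own domain and one across the tether.  Supercoiling both
domains raises the intra-domain fraction-on and suppresses the
inter-domain one; the preference ratio grows from a few-fold at dLk = 0
to a >=20-fold (often only boundable from below at desk scale, when no
inter-domain contact is seen at all).

Writes results/domain_preference.tsv.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from twistloop.contacts import TelegraphSignal, dwell_stats, preference_ratio, telegraph
from twistloop.scenarios import make_tethered_pair


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--steps", type=int, default=500_000)
    ap.add_argument("--reps", type=int, default=2)
    ap.add_argument("--dlk", default="0,-20")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    rows = []
    for dlk in [float(x) for x in args.dlk.split(",")]:
        sigs = {"intra": [], "inter": []}
        for k in range(args.reps):
            sc = make_tethered_pair(dlk, 8.0, seed=args.seed + k,
                                    contact_start=True)
            traj = sc.simulate(args.steps, seed=args.seed + 41 * k + int(abs(dlk)))
            for name, pair in sc.contact_pairs.items():
                sigs[name].append(telegraph(traj, *pair, equilibrated=False))
        stats = {}
        for name, ss in sigs.items():
            pooled = TelegraphSignal(np.concatenate([s.samples for s in ss]),
                                     ss[0].sample_dt)
            stats[name] = dwell_stats(pooled)
        ratio, ci, is_bound = preference_ratio(
            stats["intra"], stats["inter"],
            n_samples=sum(len(s) for s in sigs["inter"]),
        )
        rows.append({
            "scenario": "tethered_pair", "dlk": dlk, "epsilon": 8.0,
            "fraction_on_intra": stats["intra"].fraction_on,
            "fraction_on_inter": stats["inter"].fraction_on,
            "preference_ratio": ratio, "ci_low": ci[0], "ci_high": ci[1],
            "is_lower_bound": is_bound, "seed": args.seed,
        })
        tag = ">=" if is_bound else "="
        print(f"dLk={dlk:+.0f}: intra={stats['intra'].fraction_on:.3f} "
              f"inter={stats['inter'].fraction_on:.4f} preference {tag} {ratio:.1f}")

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "domain_preference.tsv", sep="\t", index=False)
    print(f"wrote {out/'domain_preference.tsv'}")


if __name__ == "__main__":
    main()
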