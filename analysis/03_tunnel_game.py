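#!/usr/bin/env python
"""Tunnel-game analyses: steering-law fits and developmental contrasts.

Reads the simulated session, applies the exclusion rule and movement-time
extraction, fits MT = a + b*ID per subject and item, and contrasts global
MT, RMSE and IP between age groups and across items. Tables land in
results/tunnel_game/.
"""

from pathlib import Path

import numpy as np

from penlaws import critical_r2, read_session, render_report, run_analysis
from penlaws.steering import read_geometries

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    session = read_session(ROOT / "session.csv")
    session.trials = [t for t in session.trials if t.game == "tunnel"]
    geoms = read_geometries(ROOT / "geometries.json")
    result = run_analysis(session, geoms)
    render_report(result, ROOT / "tunnel_game")

    counts = result.counts
    print(f"{counts['tunnel']} tunnel trials: {counts['tunnel_measured']} measured, "
          f"{counts['tunnel_excluded']} excluded (>40% outside the borders)")

    fits = result.steering_fits
    sig = [f for f in fits if f.p < 0.05]
    print(f"steering law significant for {len(sig)}/{len(fits)} subject-item fits "
          f"(R2 threshold at 12 df: {critical_r2(12, 0.05):.2f})")
    for item in ("circle", "square", "word_ele"):
        for group_prefix, group in (("prim", "primary"), ("kind", "kindergarten")):
            sel = [f for f in fits if f.item == item
                   and f.subject_id.startswith(group_prefix)]
            if not sel:
                continue
            gmt = np.median([f.global_MT for f in sel])
            rmse = np.median([f.RMSE for f in sel])
            ips = [f.IP for f in sel if f.IP is not None]
            ip = np.median(ips) if ips else float("nan")
            print(f"  {item:<9} {group:<13} median global MT = {gmt:5.2f} s, "
                  f"RMSE = {rmse:.3f} s, IP = {ip:5.1f}")

    print("== group contrasts (Mann-Whitney, primary vs kindergarten) ==")
    for (metric, item), res in sorted(result.group_contrasts.items()):
        tag = "significant" if res.p < 0.05 else "n.s."
        print(f"  {metric:<9} {item:<9} p = {res.p:.2g} ({tag})")

    print("== item contrasts (Friedman over circle/square/word) ==")
    for (metric, group), res in sorted(result.item_contrasts.items()):
        tag = "significant" if res.p < 0.05 else "n.s."
        print(f"  {metric:<9} {group:<13} p = {res.p:.2g} ({tag})")
    print(f"tables written to {ROOT / 'tunnel_game'}")


if __name__ == "__main__":
    main()
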