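#!/usr/bin/env python
"""Copy-game analyses: compliance, isochrony, developmental trend, homothety.

Reads the session written by 01_simulate_cohort.py, runs the copy-game
statistical battery, reports what it found, and writes the result tables
under results/copy_game/.
"""

from pathlib import Path

from penlaws import read_session, render_report, run_analysis

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    session = read_session(ROOT / "session.csv")
    session.trials = [t for t in session.trials if t.game == "copy"]
    result = run_analysis(session)
    render_report(result, ROOT / "copy_game")

    print("== exercise compliance (big vs small traced length) ==")
    for (group, item), res in sorted(result.compliance.items()):
        print(f"  {group:<13} {item:<10} Wilcoxon p = {res.p:.2g}")

    print("== isochrony (Friedman over modalities on mean speed) ==")
    for (group, item), res in sorted(result.isochrony.items()):
        tag = "significant" if res.p < 0.05 else "n.s."
        print(f"  {group:<13} {item:<10} chi2 = {res.statistic:6.2f}  "
              f"p = {res.p:.2g}  ({tag})")
        if res.posthoc:
            for ph in res.posthoc:
                if ph["significant"]:
                    a, b = ph["pair"]
                    direction = ">" if ph["median_diff"] > 0 else "<"
                    print(f"      {a} {direction} {b}  adj. p = {ph['adjusted_p']:.2g}")

    print("== developmental trend (spontaneous speed, primary vs kindergarten) ==")
    for item, res in sorted(result.developmental.items()):
        print(f"  {item:<10} Mann-Whitney p = {res.p:.2g}")

    n_ns = sum(res.p >= 0.05 for res in result.homothety.values())
    print(f"== homothety (fraction time per element) ==")
    print(f"  {n_ns}/{len(result.homothety)} element tests non-significant "
          "(fraction times preserved across modalities)")
    for (group, item, element), res in sorted(result.homothety.items()):
        if res.p < 0.05:
            print(f"  exception: {group}/{item}/{element} p = {res.p:.2g}")
    print(f"tables written to {ROOT / 'copy_game'}")


if __name__ == "__main__":
    main()
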