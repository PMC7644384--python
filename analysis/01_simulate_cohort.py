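#!/usr/bin/env python
"""Generate the synthetic study cohort.

Builds a two-group session mirroring the validation protocol — 15
primary-school children (copy word + symbols, tunnel circle/square/word)
and 19 kindergartners (symbols only in the copy game) — and writes the
session file plus the tunnel geometry catalog for the downstream analyses.
"""

from pathlib import Path

from penlaws import write_session
from penlaws.steering import write_geometries
from penlaws.synthetic import generate_cohort

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    session, geoms = generate_cohort(seed=SEED)
    session_path = OUT / "session.csv"
    geom_path = OUT / "geometries.json"
    write_session(session, session_path)
    write_geometries(list(geoms.values()), geom_path)
    groups = {}
    for tr in session.trials:
        groups.setdefault(tr.group, set()).add(tr.subject_id)
    print(f"wrote {len(session.trials)} trials "
          f"({', '.join(f'{g}: {len(s)} subjects' for g, s in groups.items())}) "
          f"to {session_path}")
    print(f"wrote {len(geoms)} tunnel geometries to {geom_path}")


if __name__ == "__main__":
    main()
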