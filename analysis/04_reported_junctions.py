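#!/usr/bin/env python
"""Worked example: re-classify the published huntingtin junction table.

The embedded table lists 20 splice junctions (8 canonical, 12 alternative)
observed in the HTT locus of post-mortem human brain mRNA-Seq.  Using only
the table's own Canonical rows as the reference, the decision cascade is
applied to every junction, in two variants: basic (table rows only, with
the two documented reference-truncation degradations) and extended (with
synthetic stand-ins for the truncated reference entries, reproducing every
reported AS type exactly).
"""

import pathlib

from splicegaps.known_events import classify_reported

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for extended, name in ((False, "basic"), (True, "extended")):
        table = classify_reported(extended=extended)
        out = RESULTS / f"reported_events_{name}.tsv"
        table.to_csv(out, sep="\t", index=False)
        n_alt = (table.category != "Canonical").sum()
        print(f"[{name}] {n_alt}/20 junctions classify as alternative; "
              f"all rows match the reported AS type under the documented "
              f"mapping: {table.match.all()}  -> {out}")
    exact = classify_reported(extended=True)
    agree = (exact.category == exact.reported_type.str.replace(" ", "")).all()
    print(f"[extended] reported AS types reproduced exactly: {agree}")


if __name__ == "__main__":
    main()
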