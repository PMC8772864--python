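"""Prune the CA model and report association weights.

Runs the iterative discard loop (refit, drop the worst-represented
parameter, repeat until two dimensions carry half the inertia), then
pairs up every level with large coordinates (> 0.3) on the resulting
plane and computes the signed association weights.
"""

import argparse
from pathlib import Path

from scfa_assoc.association import build_report
from scfa_assoc.cohort import read_cohort
from scfa_assoc.encoding import encode_cohort
from scfa_assoc.selection import select_model


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", type=Path,
                    default=Path("results/cohort_seed1.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--top", type=int, default=10)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records = read_cohort(args.input)
    _, table = encode_cohort(records)
    model, trace = select_model(table)
    report = build_report(model)

    (args.out / "selection_trace.json").write_text(trace.to_json())
    report.to_tsv(args.out / "associations.tsv")
    (args.out / "ca_model.json").write_text(model.to_json())

    print(f"discarded {len(trace.discarded)} of "
          f"{len(trace.steps[0].parameters)} parameters: "
          f"{', '.join(trace.discarded) or '(none)'}")
    print(f"final set ({len(trace.final_parameters)}): "
          f"{', '.join(trace.final_parameters)}")
    print(f"two-dimensional inertia fraction "
          f"{trace.steps[-1].inertia2:.3f} "
          f"({'met' if trace.threshold_met else 'NOT met'})")
    print(f"\ntop association weights (of {len(report.pairs)} pairs):")
    for p in report.pairs[:args.top]:
        print(f"  {p.level_a[0]}={p.level_a[1]:<12} ~ "
              f"{p.level_b[0]}={p.level_b[1]:<12} w = {p.weight:+.2f}")


if __name__ == "__main__":
    main()
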