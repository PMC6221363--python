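#!/usr/bin/env python
"""Category algebra and removal-order inference over the amplicon tallies.

Loads the tallies recovered by 03_replay_read_categories.py (run that
first) and computes the order statistics: reads supporting the
conventional-first principle vs counterexamples, pairwise precedence
counts, single-intron-removal counts among the conventional introns, and
the aggregated partial-order report.

Writes results/order_report.json and prints the findings.
"""

import os

from intron_order.gene_model import CONVENTIONAL, NONCONVENTIONAL
from intron_order.order_inference import (
    all_of_type,
    at_least_of_type,
    category_query,
    conventional_first_consistency,
    infer_partial_order,
    load_tally,
    pairwise_precedence,
    single_removal_counts,
)

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
TALLY_DIR = os.path.join(RESULTS, "categories")


def main() -> None:
    paths = [
        os.path.join(TALLY_DIR, f"{name}.tally.tsv")
        for name in ("gapC", "i6_tubA", "i5_tubA")
    ]
    missing = [p for p in paths if not os.path.exists(p)]
    if missing:
        raise SystemExit(
            "tallies not found — run analysis/03_replay_read_categories.py first"
        )
    tallies = {os.path.basename(p).split(".")[0]: load_tally(p) for p in paths}

    i6 = tallies["i6_tubA"]
    support_i6 = category_query(
        i6,
        at_least_of_type(CONVENTIONAL, 1, present=True)
        & all_of_type(NONCONVENTIONAL, present=True),
    )
    early_nonconv = category_query(
        i6,
        at_least_of_type(NONCONVENTIONAL, 1, present=False)
        & all_of_type(CONVENTIONAL, present=False),
    )
    print("i6-tubA category algebra:")
    print(f"  >=1 conventional present with all nonconventional present: {support_i6}")
    print(f"  >=1 nonconventional absent with all conventional absent:   {early_nonconv}")
    _, n_incons, offenders = conventional_first_consistency(i6)
    print(f"  reads inconsistent with conventional-first: {n_incons} "
          f"(states {offenders})")

    i5 = tallies["i5_tubA"]
    pc = pairwise_precedence(i5, 1, 2)
    print("\ni5-tubA conventional pair (i1, i2):")
    print(f"  i1 removed first: {pc.n_i_first}, i2 removed first: {pc.n_j_first}")

    singles = single_removal_counts(i6)
    print("\ni6-tubA single-removal counts (conventional introns):")
    for o in (5, 1, 2):
        print(f"  only i{o} removed: {singles[o]}")

    report = infer_partial_order(list(tallies.values()))
    report.to_json(os.path.join(RESULTS, "order_report.json"))
    print()
    print(report.to_text())
    print(f"\nreport written to {os.path.join(os.path.normpath(RESULTS), 'order_report.json')}")


if __name__ == "__main__":
    main()
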