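"""Clinical cohort triage: panel shares and result rates.

Runs the worked-example caseload (35 panel requests from 33 patients over
one year, two of them reflex-CMP follow-ups) through the full triage path
— panel restriction, database split, rule classification, per-case result —
and summarizes request distribution and positive / VUS-only / negative
rates per panel and overall.
"""

import json
from pathlib import Path

from panelval.cohorts import example_cohort
from panelval.registry import load_panels
from panelval.triage import cohort_summary, split_by_database

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    registry = load_panels()
    reports = example_cohort(registry)
    summary = cohort_summary(reports)
    (RESULTS / "cohort_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")

    all_variants = [cv.variant for r in reports for cv in r.variants]
    in_db, novel = split_by_database(all_variants)

    print(f"requests: {summary['n_requests']} from "
          f"{summary['n_patients']} patients; variants reviewed: "
          f"{len(all_variants)} ({len(in_db)} database-known, "
          f"{len(novel)} novel)")
    for panel, entry in summary["per_panel"].items():
        print(f"  {panel}: {entry['requests']} requests "
              f"({entry['share_pct']}%), positive {entry['positive_pct']}%, "
              f"VUS-only {entry['vus_only_pct']}%, "
              f"negative {entry['negative_pct']}%")
    overall = summary["overall"]
    print(f"overall: positive {overall['positive_pct']}%, "
          f"VUS-only {overall['vus_only_pct']}%, "
          f"negative {overall['negative_pct']}%")


if __name__ == "__main__":
    main()
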