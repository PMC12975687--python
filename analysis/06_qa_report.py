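#!/usr/bin/env python
"""Full QA run for each plaque model with pass/fail verdicts.

Assembles calibration, the dual-depth ratio check, the planar region
comparison and the uncertainty budget into one report per model,
against the default tolerances (ratio +-2 pp, region mean <= 5 %,
expanded uncertainty <= 11 %).  Writes results/qa_report_<model>.json.
"""

from pathlib import Path

from plaquefilm.reporting import run_qa

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for i, name in enumerate(("CCA", "COB", "CIB")):
        report = run_qa({"model": name, "seed": 100 + i})
        report.to_json(RESULTS / f"qa_report_{name.lower()}.json")
        print(report.summary())
        print()
    print(f"wrote QA reports under {RESULTS}")


if __name__ == "__main__":
    main()
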