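#!/usr/bin/env python
"""Run the end-to-end pipeline (refine -> cohort -> MDR -> network ->
power) with default settings and write the Markdown funnel report.
"""

import json

from paima import pipeline as pl


def main() -> None:
    config = pl.RunConfig(out_dir="results/run")
    report = pl.run_pipeline(config)
    print(json.dumps(report.funnel, indent=2, default=str))
    print(f"report: {report.outputs['report']}")


if __name__ == "__main__":
    main()
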