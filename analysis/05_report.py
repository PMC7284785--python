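"""Bundle all analysis outputs into one reproducible report.

Collects the dose fits, chimera likelihood profiles, mutation-frequency
and mutation-summary tables written by the earlier steps into
results/report/ (report.json + TSVs). Exits non-zero if a section is
missing so broken upstream steps are visible.
"""

import sys
from pathlib import Path

import pandas as pd

from ionmut.report import ReportError, build_report

ROOT = Path(__file__).resolve().parents[1]

SECTIONS = {
    "dose_fits": "dose_fits.tsv",
    "chimera_profile": "chimera_profile.tsv",
    "mutation_frequencies": "mutation_frequencies.tsv",
    "mutation_summary": "mutation_summary.tsv",
    "pipeline_performance": "pipeline_performance.tsv",
    "indel_spectrum": "indel_spectrum.tsv",
    "window_density": "window_density.tsv",
}


def main() -> None:
    res = ROOT / "results"
    sections = {}
    for name, fname in SECTIONS.items():
        path = res / fname
        sections[name] = pd.read_csv(path, sep="\t") if path.exists() else None
    try:
        payload = build_report(sections, res / "report", seeds={"pipeline": "see analysis/01_simulate.py --seed"})
    except ReportError as err:
        print(f"INCOMPLETE REPORT: {err}", file=sys.stderr)
        raise SystemExit(1)
    print(f"report with {len(payload) - 1} sections -> results/report/report.json")


if __name__ == "__main__":
    main()
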