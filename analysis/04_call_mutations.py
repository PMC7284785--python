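"""Run the multi-caller consensus pipeline on the simulated cohort.

Reads the per-sample, per-caller VCFs plus the genome and gene models
written by 01_simulate.py, runs background exclusion, depth/AF
filtering, three-caller intersection and annotation, then compares the
consensus against the planted truth and writes the per-sample mutation
summary, InDel size spectrum and 500-kb window densities to results/.
"""

import json
from collections import defaultdict
from pathlib import Path

import pandas as pd

from ionmut import variant_pipeline as vp
from ionmut.genome import read_fasta, read_gff3

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    sim = ROOT / "scratch" / "sim"
    res = ROOT / "results"
    if not (sim / "genome.fa").exists():
        raise SystemExit("run analysis/01_simulate.py first (scratch/sim/ is missing)")
    genome = read_fasta(sim / "genome.fa")
    genes = read_gff3(sim / "genes.gff3")
    truth = json.loads((sim / "truth.json").read_text())

    callsets: dict[str, dict[str, list]] = defaultdict(dict)
    for path in sorted(sim.glob("*.vcf")):
        calls, log = vp.read_caller_vcf(path)
        sample = path.name.split(".")[0]
        callsets[sample][log["caller"]] = calls
    print(f"loaded {sum(len(v) for v in callsets.values())} VCFs for {len(callsets)} samples")

    records, log = vp.consensus_mutations(callsets, genome, genes=genes)
    print(f"background exclusion removed {log['background_excluded_keys']} shared keys\n")

    summary_rows, perf_rows = [], []
    all_records = []
    for sample in sorted(records):
        recs = records[sample]
        all_records.extend(recs)
        got = {r.key for r in recs}
        want = {
            vp.normalize_variant(vp.VariantCall(c, p, r, a), genome).key
            for c, p, r, a in map(tuple, truth[sample]["induced"])
        }
        tp = len(got & want)
        precision = tp / len(got) if got else 1.0
        recall = tp / len(want) if want else 1.0
        s = vp.summarize_sample(recs)
        s["sample"] = sample
        summary_rows.append(s)
        perf_rows.append({"sample": sample, "precision": precision, "recall": recall,
                          "n_consensus": len(got), "n_truth": len(want)})
        titv = f"{s['sbs_ti']}/{s['sbs_tv']}"
        print(f"{sample:8s}: {s['total']:3d} mutations ({s['sbs_subtotal']} SBS [{titv}], "
              f"{s['indel_subtotal']} InDel), precision {precision:.3f}, recall {recall:.3f}")

    cols = ["sample"] + [c for c in summary_rows[0] if c != "sample"]
    pd.DataFrame(summary_rows)[cols].to_csv(res / "mutation_summary.tsv", sep="\t", index=False)
    pd.DataFrame(perf_rows).to_csv(res / "pipeline_performance.tsv", sep="\t", index=False)
    vp.indel_spectrum(all_records).to_csv(res / "indel_spectrum.tsv", sep="\t", index=False)
    vp.window_density(all_records, {c: len(s) for c, s in genome.items()}, window=50_000).to_csv(
        res / "window_density.tsv", sep="\t", index=False
    )
    (res / "pipeline_log.json").write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    print("\nTables -> results/{mutation_summary,pipeline_performance,indel_spectrum,window_density}.tsv")
    print("Run log with per-stage counts -> results/pipeline_log.json")


if __name__ == "__main__":
    main()
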