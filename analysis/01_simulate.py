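"""Simulate the full study's raw inputs with known ground truth.

Builds a toy two-chromosome genome with annotated genes, plants induced
and background mutations for a six-plant cohort plus an unirradiated
control, emits three noisy caller VCFs per sample, and generates the
phenotyping tables (dose-response series and panicle segregation
counts). Bulky regenerable files (FASTA/GFF3/VCF) go to scratch/sim/;
small tables go to results/.

Run from the repository root: python analysis/01_simulate.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

from ionmut import synthetic_data as sd
from ionmut.genome import generate_genome, write_fasta, write_gff3

ROOT = Path(__file__).resolve().parents[1]
CALLERS = ("gatk", "samtools", "varscan")
# sample ids mirror the six sequenced mutant plants (ion_dose)
SAMPLE_DOSES = [("Ar", 50), ("Ar", 100), ("C", 150), ("C", 200), ("Ne", 50), ("Ne", 100)]
# generating SHMT parameters per ion: Ar is high-LET (small shoulder),
# C and Ne lower LET (larger extrapolation number N)
ION_PARAMS = {"Ar": (55.0, 1.3), "C": (110.0, 3.5), "Ne": (105.0, 3.0)}
DOSES = [0, 50, 100, 150, 200, 300]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    seed = args.seed

    sim = ROOT / "scratch" / "sim"
    res = ROOT / "results"
    sim.mkdir(parents=True, exist_ok=True)
    res.mkdir(exist_ok=True)

    print("== genome and gene models ==")
    genome, genes = generate_genome(n_chrom=2, chrom_len=300_000, gene_density=40e-6, seed=seed)
    write_fasta(genome, sim / "genome.fa")
    write_gff3(genes, genome, sim / "genes.gff3")
    print(f"  {len(genome)} chromosomes x 300 kb, {len(genes)} genes -> scratch/sim/")

    print("== truth mutation sets and caller VCFs ==")
    truth = sd.generate_truth(
        genome, n_samples=6, n_induced=40, n_background=50,
        include_control=True, seed=seed + 10,
    )
    for t, (ion, dose) in zip(truth, SAMPLE_DOSES + [("WT", 0)]):
        if t.sample_id != "WT":
            t.sample_id = f"{ion}_{dose}"
    profiles = [
        sd.CallerProfile(c, fn_rate=0.02, fp_rate_per_mb=15.0, depth_mean=55.0)
        for c in CALLERS
    ]
    truth_manifest = {}
    for i, t in enumerate(truth):
        sd.generate_caller_vcfs(t, profiles, genome, sim, seed=seed + 100 + i)
        truth_manifest[t.sample_id] = {
            "n_induced": len(t.mutations),
            "n_background": len(t.background),
            "induced": [list(v.key) for v in t.mutations],
        }
    (sim / "truth.json").write_text(json.dumps(truth_manifest, indent=2, sort_keys=True))
    print(f"  {len(truth)} samples x 3 callers -> scratch/sim/*.vcf (truth in truth.json)")

    print("== dose-response tables ==")
    for ion, (d0, n) in ION_PARAMS.items():
        series = sd.generate_dose_response(
            d0, n, DOSES, noise_sd=3.0, replicates=10,
            seed=seed + 200 + hash(ion) % 97, genotype="DS551", ion=ion,
        )
        sd.write_dose_tsv(series, res / f"dose_response_{ion}.tsv")
    print(f"  3 ions x {len(DOSES)} doses x 10 replicates -> results/dose_response_<ion>.tsv")

    print("== panicle segregation tables ==")
    # indica-like: 3 panicles/plant, japonica-like: 5; generating P chosen
    # in the range the segregation analysis should recover
    for label, P, k in [("indica", 3, 3), ("japonica", 4, 5)]:
        table = sd.generate_panicle_table(
            P=P, m=0.2, k=k, n_plants=2_000, d=1.0, seed=seed + 300 + P
        )
        sd.write_panicle_tsv(table, res / f"panicles_{label}.tsv")
        print(f"  {label}: P={P}, k={k}, 2000 plants -> results/panicles_{label}.tsv")


if __name__ == "__main__":
    main()
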