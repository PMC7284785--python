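"""Synthetic inputs with known ground truth for the whole analysis chain.

Generates everything the pipeline consumes: truth mutation sets planted
on a toy genome (induced mutations disjoint between samples, background
variants shared by at least two), noisy per-caller VCFs with depth and
allele-fraction fields, SHMT-shaped dose-response tables, and panicle
segregation tables under the progenitor-cell chimera model. Every
generator is deterministic for a fixed seed, so recovery tests can
compare pipeline output against the planted truth exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import DoseResponseSeries, shmt_response
from .genome import BASES, generate_genome, revcomp, write_fasta, write_gff3  # noqa: F401  (re-export)
from .variant_pipeline import VariantCall

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class TruthMutationSet:
    """Planted variants for one sample: induced (private) + background (shared)."""

    sample_id: str
    mutations: list[VariantCall] = field(default_factory=list)
    background: list[VariantCall] = field(default_factory=list)

    @property
    def all_variants(self) -> list[VariantCall]:
        return sorted(self.mutations + self.background, key=lambda v: v.key)

    @property
    def induced_keys(self) -> set[tuple]:
        return {v.key for v in self.mutations}


@dataclass
class CallerProfile:
    """Error model of one variant caller."""

    caller_id: str
    fn_rate: float = 0.0
    fp_rate_per_mb: float = 0.0
    depth_mean: float = 50.0
    depth_dispersion: float = 50.0
    af_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.fn_rate <= 1.0:
            raise ValueError("fn_rate must be in [0, 1]")
        if self.fp_rate_per_mb < 0:
            raise ValueError("fp_rate_per_mb must be >= 0")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if self.af_noise_sd < 0:
            raise ValueError("af_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Truth sets

def generate_truth(
    genome: dict[str, str],
    n_samples: int,
    n_induced: int,
    n_background: int = 0,
    sbs_fraction: float = 0.85,
    titv_ratio: float = 2.0,
    indel_size_geom_p: float = 0.45,
    het_fraction: float = 0.5,
    deletion_fraction: float = 0.6,
    include_control: bool = False,
    seed: int = 0,
) -> list[TruthMutationSet]:
    """Plant per-sample induced mutations plus shared background variants.

    Each sample receives exactly ``n_induced`` private variants; induced
    sets are pairwise disjoint by (chrom, pos, ref, alt) because every
    variant gets a unique genomic position. Each of the ``n_background``
    variants is written identically into a random subset of >= 2 samples.
    SBS vs InDel mix is Bernoulli(``sbs_fraction``); transitions are
    drawn with probability titv/(1+titv); InDel sizes follow a geometric
    distribution clamped to [1, 50] with deletions favoured
    ``deletion_fraction`` : 1-``deletion_fraction``.

    With ``include_control=True`` an extra sample "WT" with zero induced
    mutations (but eligible to carry background) is appended.
    """
    if n_induced < 0 or n_background < 0:
        raise ValueError("variant counts must be >= 0")
    if titv_ratio <= 0:
        raise ValueError("titv_ratio must be > 0")
    if not 0.0 <= sbs_fraction <= 1.0:
        raise ValueError("sbs_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    if include_control:
        sample_ids.append("WT")
    total_needed = n_samples * n_induced + n_background
    capacity = sum(max(len(s) - 120, 0) for s in genome.values()) // 4
    if total_needed > capacity:
        raise ValueError(f"requested {total_needed} variants; genome supports ~{capacity}")

    positions = _draw_positions(genome, total_needed, rng)
    variants = [
        _make_variant(genome, chrom, pos, rng, sbs_fraction, titv_ratio, indel_size_geom_p,
                      het_fraction, deletion_fraction)
        for chrom, pos in positions
    ]
    truth = [TruthMutationSet(sample_id=s) for s in sample_ids]
    cursor = 0
    for i in range(n_samples):
        truth[i].mutations = sorted(variants[cursor : cursor + n_induced], key=lambda v: v.key)
        cursor += n_induced
    n_eligible = len(sample_ids)
    for v in variants[cursor:]:
        n_carriers = int(rng.integers(2, n_eligible + 1))
        for idx in rng.choice(n_eligible, size=n_carriers, replace=False):
            truth[idx].background.append(v)
    for t in truth:
        t.background.sort(key=lambda v: v.key)
    return truth


def _draw_positions(genome: dict[str, str], n: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Unique 1-based positions leaving >= 60 bp margins for indel alleles."""
    chroms = list(genome)
    lens = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights = lens / lens.sum()
    used: set[tuple[str, int]] = set()
    out: list[tuple[str, int]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError("could not place requested variants (genome too small)")
        ci = rng.choice(len(chroms), p=weights)
        chrom = chroms[ci]
        pos = int(rng.integers(60, len(genome[chrom]) - 60))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            out.append((chrom, pos))
    return out


def _make_variant(
    genome, chrom, pos, rng, sbs_fraction, titv_ratio, geom_p, het_fraction, deletion_fraction
) -> VariantCall:
    seq = genome[chrom]
    zyg = "het" if rng.random() < het_fraction else "hom"
    refbase = seq[pos - 1]
    if rng.random() < sbs_fraction:
        if rng.random() < titv_ratio / (1.0 + titv_ratio):
            alt = _TRANSITION[refbase]
        else:
            alt = str(rng.choice([b for b in BASES if b != refbase and b != _TRANSITION[refbase]]))
        return VariantCall(chrom=chrom, pos=pos, ref=refbase, alt=alt, zygosity=zyg)
    size = min(int(rng.geometric(geom_p)), 50)
    if rng.random() < deletion_fraction:
        ref = seq[pos - 1 : pos + size]
        return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=refbase, zygosity=zyg)
    ins = "".join(rng.choice(list(BASES), size=size))
    return VariantCall(chrom=chrom, pos=pos, ref=refbase, alt=refbase + ins, zygosity=zyg)


# ---------------------------------------------------------------------------
# Caller VCFs

def simulate_caller_calls(
    truth: TruthMutationSet,
    profiles: list[CallerProfile],
    genome: dict[str, str],
    seed: int = 0,
) -> dict[str, list[VariantCall]]:
    """Apply each caller's error model to one sample's truth set.

    Induced variants are dropped independently per caller with
    probability ``fn_rate``; background variants are emitted by every
    caller (they mimic real polymorphism, visible to all tools). False
    positives are added as SBSs at Poisson(``fp_rate_per_mb`` x genome
    Mb) positions absent from the truth and disjoint between callers.
    Every emitted call carries simulated DP (negative binomial) and AF
    (Gaussian around 0.5 het / 1.0 hom, clipped to (0, 1]).
    """
    if len(profiles) != 3 or len({p.caller_id for p in profiles}) != 3:
        raise ValueError("exactly three profiles with distinct caller_id required")
    rng = np.random.default_rng(seed)
    genome_mb = sum(len(s) for s in genome.values()) / 1e6
    truth_pos = {(v.chrom, v.pos) for v in truth.all_variants}
    fp_used: set[tuple[str, int]] = set(truth_pos)
    out: dict[str, list[VariantCall]] = {}
    for prof in profiles:
        calls: list[VariantCall] = []
        for v in truth.mutations:
            if rng.random() < prof.fn_rate:
                continue
            calls.append(_observe(v, prof, rng, caller=prof.caller_id, sample=truth.sample_id))
        for v in truth.background:
            calls.append(_observe(v, prof, rng, caller=prof.caller_id, sample=truth.sample_id))
        n_fp = int(rng.poisson(prof.fp_rate_per_mb * genome_mb))
        for chrom, pos in _draw_fp_positions(genome, n_fp, fp_used, rng):
            refbase = genome[chrom][pos - 1]
            alt = str(rng.choice([b for b in BASES if b != refbase]))
            fp = VariantCall(chrom=chrom, pos=pos, ref=refbase, alt=alt, zygosity="het")
            calls.append(_observe(fp, prof, rng, caller=prof.caller_id, sample=truth.sample_id))
        calls.sort(key=lambda c: c.key)
        out[prof.caller_id] = calls
    return out


def _draw_fp_positions(genome, n, used, rng) -> list[tuple[str, int]]:
    chroms = list(genome)
    lens = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights = lens / lens.sum()
    out = []
    while len(out) < n:
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        pos = int(rng.integers(60, len(genome[chrom]) - 60))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            out.append((chrom, pos))
    return out


def _observe(v: VariantCall, prof: CallerProfile, rng, caller: str, sample: str) -> VariantCall:
    r = prof.depth_dispersion
    mu = prof.depth_mean
    depth = max(1, int(rng.negative_binomial(r, r / (r + mu))))
    center = 1.0 if v.zygosity == "hom" else 0.5
    af = float(np.clip(center + rng.normal(0.0, prof.af_noise_sd), 0.01, 1.0))
    return VariantCall(
        chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
        depth=depth, af=af, caller=caller, sample=sample, zygosity=v.zygosity,
    )


def generate_caller_vcfs(
    truth: TruthMutationSet,
    profiles: list[CallerProfile],
    genome: dict[str, str],
    out_dir: str | Path,
    seed: int = 0,
) -> list[Path]:
    """Write one VCF per caller (``<sample>.<caller>.vcf``), sorted by site."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calls_by_caller = simulate_caller_calls(truth, profiles, genome, seed=seed)
    paths = []
    for prof in profiles:
        path = out_dir / f"{truth.sample_id}.{prof.caller_id}.vcf"
        write_vcf(calls_by_caller[prof.caller_id], truth.sample_id, genome, path)
        paths.append(path)
    return paths


def write_vcf(calls: list[VariantCall], sample: str, genome: dict[str, str], path: str | Path) -> None:
    """Write calls as a single-sample VCF 4.2 with GT:DP:AF fields."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
    ]
    lines += [f"##contig=<ID={c},length={len(s)}>" for c, s in genome.items()]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    chrom_order = {c: i for i, c in enumerate(genome)}
    for c in sorted(calls, key=lambda v: (chrom_order.get(v.chrom, 99), v.pos, v.ref, v.alt)):
        gt = "1/1" if c.zygosity == "hom" else "0/1"
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t.\tGT:DP:AF\t{gt}:{c.depth}:{c.af:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Dose-response tables

def generate_dose_response(
    D0: float,
    N: float,
    doses: list[float],
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    genotype: str = "",
    ion: str = "",
    endpoint: str = "seedling_survival",
) -> DoseResponseSeries:
    """SHMT-shaped response points with Gaussian noise, clipped to [0, 100]."""
    if D0 <= 0:
        raise ValueError("D0 must be > 0")
    if N < 1:
        raise ValueError("N must be >= 1")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        for d in doses:
            mu = shmt_response(d, D0, N)
            y = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"dose_gy": float(d), "response_pct": float(np.clip(y, 0.0, 100.0)), "replicate": rep + 1})
    return DoseResponseSeries(points=pd.DataFrame(rows), genotype=genotype, ion=ion, endpoint=endpoint)


def write_dose_tsv(series: DoseResponseSeries, path: str | Path) -> None:
    series.points.to_csv(path, sep="\t", index=False)


def read_dose_tsv(path: str | Path, **meta) -> DoseResponseSeries:
    return DoseResponseSeries(points=pd.read_csv(path, sep="\t"), **meta)


# ---------------------------------------------------------------------------
# Panicle segregation tables

def generate_panicle_table(
    P: int,
    m: float,
    k: int,
    n_plants: int,
    d: float = 1.0,
    seed: int = 0,
    allocation: str = "balanced",
) -> pd.DataFrame:
    """Simulate per-plant mutant-panicle counts under the chimera model.

    Each plant's k harvested panicles are allocated to P progenitor cells
    (balanced by default: counts differ by at most one, the remainder
    assigned to random progenitors); each progenitor mutates
    independently with probability m; panicles of mutated progenitors are
    detected as mutant with probability d. Columns: ``plant_id``, ``k``,
    ``n_mutant_panicles``.
    """
    if not 0.0 <= m <= 1.0 or not 0.0 <= d <= 1.0:
        raise ValueError("m and d must be probabilities in [0, 1]")
    if k < 1 or n_plants < 1 or P < 1:
        raise ValueError("P, k and n_plants must be >= 1")
    if not 1 <= P <= 6:
        warnings.warn(f"P={P} outside the biologically expected 1..6 range", stacklevel=2)

    rng = np.random.default_rng(seed)
    mutated = rng.random((n_plants, P)) < m
    if allocation == "balanced":
        base, rem = divmod(k, P)
        counts = np.full((n_plants, P), base, dtype=int)
        if rem:
            order = rng.random((n_plants, P)).argsort(axis=1)
            counts += (order < rem).astype(int)
        x = rng.binomial(counts * mutated, d).sum(axis=1)
    elif allocation == "uniform-random":
        assign = rng.integers(0, P, size=(n_plants, k))
        panicle_mut = np.take_along_axis(mutated, assign, axis=1)
        detected = panicle_mut & (rng.random((n_plants, k)) < d)
        x = detected.sum(axis=1)
    else:
        raise ValueError("allocation must be 'balanced' or 'uniform-random'")
    return pd.DataFrame(
        {
            "plant_id": [f"plant_{i + 1}" for i in range(n_plants)],
            "k": k,
            "n_mutant_panicles": x.astype(int),
        }
    )


def write_panicle_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_panicle_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
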