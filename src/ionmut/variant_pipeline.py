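"""Multi-caller consensus pipeline for induced-mutation identification.

Implements the post-calling half of a whole-genome mutation detection
workflow for mutagenized plants, consuming per-sample VCFs from three
independent variant callers:

    per-caller calls -> left-normalization -> background exclusion
    (variants shared by any two plants, control included) -> depth and
    allele-fraction filter (10 <= DP <= 100, AF >= 0.25) -> three-caller
    intersection -> classification and annotation.

Each stage only removes or annotates records, never adds them; removals
are counted in a run log so the effect of every decision is auditable.
Variants are matched by exact (chrom, pos, ref, alt) key after
left-alignment; genotype is ignored in matching.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

BASES = set("ACGT")

TI_CLASSES = ("C:G>T:A", "T:A>C:G")
TV_CLASSES = ("C:G>A:T", "C:G>G:C", "T:A>G:C", "T:A>A:T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class NormalizationError(ValueError):
    """REF allele inconsistent with the reference genome."""


@dataclass(frozen=True)
class VariantCall:
    """One caller's record for one alt allele."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int = 0
    af: float = 0.0
    caller: str = ""
    sample: str = ""
    zygosity: str = "het"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if set(self.ref) - BASES or set(self.alt) - BASES:
            raise ValueError(f"alleles must be over ACGT: {self.ref}>{self.alt}")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_sbs(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class MutationRecord:
    """A consensus induced mutation with its classification/annotation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    mut_class: str  # SBS | insertion | deletion
    sample: str = ""
    depth: int = 0
    af: float = 0.0
    sub_type: str | None = None  # SBS only, strand-collapsed class
    size: int | None = None  # InDel only, bp
    region: str | None = None
    effect: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _mutation_record_from_call(call: VariantCall) -> MutationRecord:
    if call.is_sbs:
        sub, _ = classify_sbs(call.ref, call.alt)
        return MutationRecord(
            chrom=call.chrom, pos=call.pos, ref=call.ref, alt=call.alt,
            mut_class="SBS", sample=call.sample, depth=call.depth, af=call.af, sub_type=sub,
        )
    size = abs(len(call.ref) - len(call.alt))
    mclass = "insertion" if len(call.alt) > len(call.ref) else "deletion"
    return MutationRecord(
        chrom=call.chrom, pos=call.pos, ref=call.ref, alt=call.alt,
        mut_class=mclass, sample=call.sample, depth=call.depth, af=call.af, size=size,
    )


# ---------------------------------------------------------------------------
# VCF input

_VCF_NAME_RE = re.compile(r"(?P<sample>[^.]+)\.(?P<caller>[^.]+)\.vcf$")


def read_caller_vcf(path: str | Path, caller: str | None = None) -> tuple[list[VariantCall], dict]:
    """Read one caller's single-sample VCF into VariantCall records.

    Multi-allelic records are split into one call per alt allele. DP is
    taken from FORMAT DP (fallback INFO DP); AF from FORMAT AF, else
    derived as alt reads / DP from FORMAT AD, else from INFO AF. Records
    where neither is derivable are excluded and counted in the log.
    Caller id defaults to the ``<sample>.<caller>.vcf`` filename field.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if caller is None:
        m = _VCF_NAME_RE.search(path.name)
        caller = m.group("caller") if m else path.stem
    vcf = VCF(str(path))
    sample = vcf.samples[0] if vcf.samples else path.stem.split(".")[0]
    calls: list[VariantCall] = []
    log = {"path": str(path), "caller": caller, "parsed": 0, "excluded_no_dp_af": 0}
    for v in vcf:
        dp = _first_int(v.format("DP")) if "DP" in (v.FORMAT or []) else None
        if dp is None:
            dp = v.INFO.get("DP")
        afs = _format_floats(v, "AF")
        if afs is None:
            ad = v.format("AD") if "AD" in (v.FORMAT or []) else None
            if ad is not None and dp:
                afs = [float(a) / dp for a in np.atleast_1d(ad[0])[1:]]
        if afs is None:
            info_af = v.INFO.get("AF")
            if info_af is not None:
                afs = list(np.atleast_1d(info_af).astype(float))
        if dp is None or afs is None:
            log["excluded_no_dp_af"] += 1
            continue
        gt = v.genotypes[0][:-1] if v.genotypes else []
        for i, alt in enumerate(v.ALT):
            af = float(afs[i]) if i < len(afs) else float(afs[0])
            zyg = "hom" if gt and all(a == i + 1 for a in gt if a >= 0) else "het"
            calls.append(
                VariantCall(
                    chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                    depth=int(dp), af=af, caller=caller, sample=sample, zygosity=zyg,
                )
            )
            log["parsed"] += 1
    calls.sort(key=lambda c: c.key)
    return calls, log


def _first_int(arr) -> int | None:
    if arr is None:
        return None
    val = np.atleast_1d(np.asarray(arr).ravel())[0]
    return None if val < 0 else int(val)


def _format_floats(v, tag: str) -> list[float] | None:
    try:
        arr = v.format(tag)
    except KeyError:
        return None
    if arr is None:
        return None
    return [float(x) for x in np.asarray(arr).ravel() if np.isfinite(x)]


# ---------------------------------------------------------------------------
# Normalization

def normalize_variant(call: VariantCall, genome: dict[str, str]) -> VariantCall:
    """Left-align and trim to the minimal (parsimonious) representation.

    Standard normalization: shared trailing bases are removed (extending
    left from the reference when an allele empties), then shared leading
    bases are removed keeping one anchor base. SBSs pass through
    unchanged; the operation is idempotent.
    """
    seq = genome.get(call.chrom)
    if seq is None:
        raise NormalizationError(f"unknown chromosome {call.chrom!r}")
    if seq[call.pos - 1 : call.pos - 1 + len(call.ref)].upper() != call.ref:
        raise NormalizationError(
            f"REF {call.ref!r} does not match genome at {call.chrom}:{call.pos}"
        )
    pos, ref, alt = call.pos, call.ref, call.alt
    if len(ref) == 1 and len(alt) == 1:
        return call
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if (len(ref) == 1 or len(alt) == 1) and pos == 1:
                break  # chromosome start: no base left to anchor on
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                pos -= 1
                base = seq[pos - 1].upper()
                ref, alt = base + ref, base + alt
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        else:
            break
    return replace(call, pos=pos, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# Filtering stages

def exclude_background(
    callsets: dict[str, list[VariantCall]],
) -> tuple[dict[str, list[VariantCall]], list[dict]]:
    """Remove variants shared by any two plants from every plant.

    ``callsets`` maps sample id (the unirradiated control counts as a
    sample) to that sample's calls, pooled across callers. A normalized
    key present in >= 2 samples is treated as a background variant —
    pre-existing polymorphism or systematic artifact — and removed from
    all samples. Returns the filtered callsets and a removal log with
    each excluded key and its carrier samples.
    """
    if len(callsets) < 2:
        raise ValueError("background exclusion needs >= 2 samples")
    carriers: dict[tuple, set[str]] = {}
    for sample, calls in callsets.items():
        for key in {c.key for c in calls}:
            carriers.setdefault(key, set()).add(sample)
    shared = {k for k, who in carriers.items() if len(who) >= 2}
    filtered = {
        sample: [c for c in calls if c.key not in shared]
        for sample, calls in callsets.items()
    }
    log = [
        {"key": k, "carriers": sorted(carriers[k])}
        for k in sorted(shared)
    ]
    return filtered, log


def apply_quality_filter(
    calls: list[VariantCall],
    min_dp: int = 10,
    max_dp: int = 100,
    min_af: float = 0.25,
) -> list[VariantCall]:
    """Keep calls with min_dp <= DP <= max_dp and AF >= min_af (inclusive)."""
    return [c for c in calls if min_dp <= c.depth <= max_dp and c.af >= min_af]


def intersect_callers(
    set1: list[VariantCall],
    set2: list[VariantCall],
    set3: list[VariantCall],
) -> list[MutationRecord]:
    """Three-caller consensus on (chrom, pos, ref, alt).

    Variants found by only one or two callers are excluded. The consensus
    record's DP/AF come from the first caller's call (deterministic
    provenance). Output is sorted by site key.
    """
    keys = {c.key for c in set1} & {c.key for c in set2} & {c.key for c in set3}
    by_key = {c.key: c for c in reversed(set1)}  # first occurrence wins
    return [_mutation_record_from_call(by_key[k]) for k in sorted(keys)]


# ---------------------------------------------------------------------------
# Classification

def classify_sbs(ref: str, alt: str) -> tuple[str, str]:
    """Strand-collapsed substitution class and Ti/Tv label.

    The 12 ordered single-base substitutions map onto 6 classes by
    pairing each base with its complement (G>A is the same event as C>T
    on the other strand). Transitions: C:G>T:A and T:A>C:G; the other
    four classes are transversions.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt or ref not in _COMP or alt not in _COMP:
        raise ValueError(f"not a single-base substitution: {ref!r}>{alt!r}")
    r, a = ref, alt
    if r in "AG":  # collapse to the pyrimidine-reference strand
        r, a = _COMP[r], _COMP[a]
    sub = f"{r}:{_COMP[r]}>{a}:{_COMP[a]}"
    return sub, ("Ti" if sub in TI_CLASSES else "Tv")


def titv_ratio(records: list[MutationRecord]) -> float:
    """Transition/transversion count ratio over the SBS records.

    Raises ``ValueError`` when no transversion is present (undefined)."""
    labels = [classify_sbs(r.ref, r.alt)[1] for r in records if r.mut_class == "SBS"]
    n_ti = labels.count("Ti")
    n_tv = labels.count("Tv")
    if n_tv == 0:
        raise ValueError("Ti/Tv undefined: zero transversions")
    return n_ti / n_tv


def indel_spectrum(records: list[MutationRecord], max_size: int = 50) -> pd.DataFrame:
    """Size histogram of insertions and deletions.

    Rows are sizes 1..max_size plus one overflow row (size 0 marks
    ``>max_size``); totals are conserved.
    """
    ins = Counter()
    dele = Counter()
    for r in records:
        if r.mut_class == "insertion":
            ins[min(r.size, max_size + 1)] += 1
        elif r.mut_class == "deletion":
            dele[min(r.size, max_size + 1)] += 1
    sizes = list(range(1, max_size + 2))
    df = pd.DataFrame(
        {
            "size": sizes,
            "insertions": [ins.get(s, 0) for s in sizes],
            "deletions": [dele.get(s, 0) for s in sizes],
        }
    )
    df.loc[df.index[-1], "size"] = 0  # overflow bin marker
    return df


def window_density(
    records: list[MutationRecord],
    chrom_lengths: dict[str, int],
    window: int = 500_000,
) -> pd.DataFrame:
    """SBS/InDel counts in non-overlapping genomic windows.

    Window w on a chromosome covers positions ((w-1)*window, w*window]
    (1-based, right-closed); the last window may be short. The sum of
    counts equals the number of records.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        n_win = (length + window - 1) // window
        sbs = np.zeros(n_win, dtype=int)
        ind = np.zeros(n_win, dtype=int)
        for r in records:
            if r.chrom != chrom:
                continue
            w = (r.pos - 1) // window
            if r.mut_class == "SBS":
                sbs[w] += 1
            else:
                ind[w] += 1
        for w in range(n_win):
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": w * window + 1,
                    "window_end": min((w + 1) * window, length),
                    "sbs_count": int(sbs[w]),
                    "indel_count": int(ind[w]),
                }
            )
    return pd.DataFrame(rows)


def summarize_sample(records: list[MutationRecord]) -> dict:
    """Per-sample mutation summary (totals, Ti/Tv, exonic effect classes).

    Schema: total; SBS subtotal with Ti and Tv counts and exonic
    synonymous/nonsynonymous/stop-gain/stop-loss; InDel subtotal with
    exonic frameshift/nonframeshift/stop-gain/stop-loss. Internal
    consistency: total = SBS subtotal + InDel subtotal.
    """
    sbs = [r for r in records if r.mut_class == "SBS"]
    indels = [r for r in records if r.mut_class in ("insertion", "deletion")]
    labels = [classify_sbs(r.ref, r.alt)[1] for r in sbs]
    exonic_sbs = [r for r in sbs if r.region == "exonic"]
    exonic_ind = [r for r in indels if r.region == "exonic"]

    def n_eff(rs, effect):
        return sum(1 for r in rs if r.effect == effect)

    return {
        "total": len(records),
        "sbs_subtotal": len(sbs),
        "sbs_ti": labels.count("Ti"),
        "sbs_tv": labels.count("Tv"),
        "sbs_exonic": len(exonic_sbs),
        "sbs_exonic_synonymous": n_eff(exonic_sbs, "synonymous"),
        "sbs_exonic_nonsynonymous": n_eff(exonic_sbs, "nonsynonymous"),
        "sbs_exonic_stopgain": n_eff(exonic_sbs, "stopgain"),
        "sbs_exonic_stoploss": n_eff(exonic_sbs, "stoploss"),
        "indel_subtotal": len(indels),
        "indel_exonic": len(exonic_ind),
        "indel_exonic_frameshift": n_eff(exonic_ind, "frameshift"),
        "indel_exonic_nonframeshift": n_eff(exonic_ind, "nonframeshift"),
        "indel_exonic_stopgain": n_eff(exonic_ind, "stopgain"),
        "indel_exonic_stoploss": n_eff(exonic_ind, "stoploss"),
    }


# ---------------------------------------------------------------------------
# Cohort driver

def consensus_mutations(
    callsets: dict[str, dict[str, list[VariantCall]]],
    genome: dict[str, str],
    genes=None,
    min_dp: int = 10,
    max_dp: int = 100,
    min_af: float = 0.25,
) -> tuple[dict[str, list[MutationRecord]], dict]:
    """Run the full post-calling pipeline over a cohort.

    ``callsets`` maps sample -> caller -> calls. Stages in fixed order:
    (1) left-normalize every call; (2) exclude background keys present in
    any two samples (per-sample key sets pooled over callers, computed
    before quality filtering; the control is one of the samples);
    (3) per-caller depth/AF filter; (4) three-caller intersection;
    (5) region/effect annotation when ``genes`` is given. Returns the
    consensus records per sample and a run log of per-stage counts.
    """
    from .annotation import annotate

    norm = {
        s: {c: [normalize_variant(v, genome) for v in calls] for c, calls in by_caller.items()}
        for s, by_caller in callsets.items()
    }
    pooled = {s: [v for calls in by_caller.values() for v in calls] for s, by_caller in norm.items()}
    filtered_pool, bg_log = exclude_background(pooled)
    bg_keys = {tuple(e["key"]) for e in bg_log}

    log: dict = {
        "stage_order": ["normalize", "background_exclusion", "quality_filter", "intersection", "annotation"],
        "background_excluded_keys": len(bg_keys),
        "background_log": bg_log,
        "samples": {},
    }
    out: dict[str, list[MutationRecord]] = {}
    for sample, by_caller in norm.items():
        slog = {"input": sum(len(v) for v in by_caller.values())}
        kept = {c: [v for v in calls if v.key not in bg_keys] for c, calls in by_caller.items()}
        slog["after_background"] = sum(len(v) for v in kept.values())
        qual = {c: apply_quality_filter(calls, min_dp, max_dp, min_af) for c, calls in kept.items()}
        slog["after_quality"] = sum(len(v) for v in qual.values())
        caller_lists = [qual[c] for c in sorted(qual)]
        if len(caller_lists) != 3:
            raise ValueError(f"sample {sample!r} has {len(caller_lists)} callers; expected 3")
        records = intersect_callers(*caller_lists)
        slog["consensus"] = len(records)
        if genes is not None:
            records = [annotate(r, genes, genome) for r in records]
        out[sample] = records
        log["samples"][sample] = slog
    return out, log
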