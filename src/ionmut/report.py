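"""Aggregation of module outputs into a reproducible report bundle.

Collects dose-response fits, chimera likelihood profiles, per-sample
mutation summaries and the pipeline run log into one JSON manifest plus
TSV tables. Every reported frequency travels with its denominator
(small-n estimates are flagged as unstable otherwise), and re-running on
identical inputs yields byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .chimera_model import mutation_frequency


class ReportError(RuntimeError):
    """A required report section is missing or unreadable."""


def frequency_table(tables: list[tuple[dict, pd.DataFrame]]) -> pd.DataFrame:
    """Long-format mutation-frequency table over panicle tables.

    ``tables`` is a list of (metadata, panicle table) pairs; metadata
    must carry ``genotype``, ``ion``, ``dose`` and ``trait``. One output
    row per (group, basis) with the frequency and its denominator.
    Duplicate group keys raise ``ValueError``.
    """
    seen = set()
    rows = []
    for meta, table in tables:
        key = (meta["genotype"], meta["ion"], meta["dose"], meta["trait"])
        if key in seen:
            raise ValueError(f"duplicate group key {key}")
        seen.add(key)
        if len(table) == 0:
            continue  # empty groups are omitted (caller logs them)
        for basis, denom in (("plant", len(table)), ("panicle", int(table["k"].sum()))):
            rows.append(
                {
                    "genotype": meta["genotype"],
                    "ion": meta["ion"],
                    "dose_gy": meta["dose"],
                    "trait": meta["trait"],
                    "basis": basis,
                    "frequency": mutation_frequency(table, basis),
                    "n": denom,
                }
            )
    return pd.DataFrame(rows)


def build_report(sections: dict[str, object], out_dir: str | Path, seeds: dict | None = None) -> dict:
    """Write a deterministic JSON + TSV bundle from named sections.

    DataFrame sections become ``<name>.tsv``; everything else is embedded
    in ``report.json`` alongside a manifest (version, seeds, section
    inventory). Sections whose value is None are recorded as gaps and
    raise :class:`ReportError` after the partial report is written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": {"name": "ionmut", "version": __version__},
        "seeds": seeds or {},
        "sections": sorted(sections),
        "gaps": sorted(name for name, val in sections.items() if val is None),
    }
    payload: dict = {"manifest": manifest}
    for name in sorted(sections):
        val = sections[name]
        if val is None:
            continue
        if isinstance(val, pd.DataFrame):
            val.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
            payload[name] = {"tsv": f"{name}.tsv", "n_rows": len(val)}
        else:
            payload[name] = val
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    if manifest["gaps"]:
        raise ReportError(f"missing report sections: {manifest['gaps']}")
    return payload
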