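"""End-to-end run processing: ingest → normalise → annotate → flag.

Operates on a run directory laid out as synthfix emits it (and as a real
pipeline drop would be staged): per-sample VCFs, ref.fa, transcripts.tsv,
assay.yaml (+ roi.bed), a mock/file-backed annotation source and the
amplicon read-count matrix.  Replicate samples are recognised by the
``<base>_R1``/``<base>_R2`` naming convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .anncache import AnnotationCache, TsvSource
from .filters import (AssayConfig, FlagResult, assign_flags, call_record,
                      merge_replicate_history, panel_frequency)
from .normalize import NormalizedVariant, Reference, normalize_variant
from .variants import Transcript, VariantCall, read_transcripts, read_vcf

_REPLICATE_RE = re.compile(r"^(.*)_R([12])$")


@dataclass
class ProcessedCall:
    call: VariantCall
    norm: NormalizedVariant
    flags: FlagResult
    annotations: dict[str, str]
    record: dict[str, Any]  # flattened, filterable view


@dataclass
class ProcessedRun:
    run_id: str
    calls: list[ProcessedCall]
    sample_keys: dict[str, set[str]]
    panel_history: dict[str, set[str]]
    cache_stats: Any = None


def partner_sample(sample_id: str) -> str | None:
    m = _REPLICATE_RE.match(sample_id)
    if not m:
        return None
    base, rep = m.group(1), m.group(2)
    return f"{base}_R{'2' if rep == '1' else '1'}"


def process_run(run_dir: str | Path, run_id: str = "RUN",
                cache: AnnotationCache | None = None,
                assay_yaml: str | None = None) -> ProcessedRun:
    """Process every non-NTC sample VCF in a run directory.

    Each raw call is trimmed, left-aligned (yielding its stable variant key),
    3'-shifted against the reportable transcripts for HGVS display, annotated
    through the cache as one batch, and flagged against the assay
    configuration with replicate and panel-recurrence context from the run
    itself.
    """
    run_dir = Path(run_dir)
    ref = Reference.from_fasta(str(run_dir / "ref.fa"))
    transcripts: list[Transcript] = read_transcripts(str(run_dir / "transcripts.tsv"))
    cfg = AssayConfig.from_yaml(assay_yaml or str(run_dir / "assay.yaml"))

    if cache is None:
        cache = AnnotationCache()
    if "synthdb" not in cache.sources and (run_dir / "synthdb.tsv").exists():
        cache.register_source(TsvSource("synthdb", str(run_dir / "synthdb.tsv")))

    vcfs = sorted(p for p in run_dir.glob("*.vcf") if not p.stem.startswith("NTC_"))
    per_sample: dict[str, list[tuple[VariantCall, NormalizedVariant]]] = {}
    sample_keys: dict[str, set[str]] = {}
    for path in vcfs:
        sid = path.stem
        rows = []
        keys = set()
        for call in read_vcf(str(path), sid):
            norm = normalize_variant(call, transcripts, ref)[0]
            rows.append((call, norm))
            keys.add(norm.variant_key)
        per_sample[sid] = rows
        sample_keys[sid] = keys

    panel_history = merge_replicate_history(sample_keys)
    all_keys = [n.variant_key for rows in per_sample.values() for _, n in rows]
    annotations, stats = cache.annotate_run(run_id, all_keys)

    processed: list[ProcessedCall] = []
    for sid, rows in per_sample.items():
        partner = partner_sample(sid)
        partner_keys = sample_keys.get(partner) if partner else None
        for call, norm in rows:
            key = norm.variant_key
            ann = annotations.get(key, {})
            frac = panel_frequency(key, panel_history)
            fr = assign_flags(call, cfg, annotations=ann,
                              replicate_partner_keys=partner_keys,
                              panel_frac=frac, variant_key=key)
            rec = call_record(call, annotations=ann, flag_result=fr,
                              gene=norm.gene or ann.get("gene"),
                              hgvs_g=norm.hgvs_g, hgvs_c=norm.hgvs_c,
                              hgvs_p=norm.hgvs_p, panel_frac=frac)
            rec["variant_key"] = key  # left-aligned canonical key
            processed.append(ProcessedCall(call, norm, fr, dict(ann), rec))
    return ProcessedRun(run_id, processed, sample_keys, panel_history, stats)


def compare_to_truth(run: ProcessedRun, truth_rows: list[dict],
                     min_depth: int = 500) -> dict[str, Any]:
    """Score recovered flags against the generator's truth table.

    A call matches when the flags it fired equal the truth row's expected
    set for its physical sample and variant key; only calls at or above the
    depth floor are scored (binomial VAF noise dominates below it).
    """
    expected: dict[tuple[str, str], set[str]] = {
        (r["physical_sample"], r["variant_key"]): r["expected_flags"]
        for r in truth_rows
    }
    n_scored = n_match = 0
    mismatches = []
    for pc in run.calls:
        if pc.call.total_depth < min_depth:
            continue
        m = _REPLICATE_RE.match(pc.call.sample_id)
        physical = m.group(1) if m else pc.call.sample_id
        exp = expected.get((physical, pc.norm.variant_key))
        if exp is None:
            continue
        n_scored += 1
        if pc.flags.flags == exp:
            n_match += 1
        else:
            mismatches.append((pc.call.sample_id, pc.norm.variant_key,
                               sorted(pc.flags.flags), sorted(exp)))
    return {
        "n_scored": n_scored,
        "n_match": n_match,
        "recovery": n_match / n_scored if n_scored else 0.0,
        "mismatches": mismatches,
    }
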