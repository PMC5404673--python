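"""Clinical report assembly and merge-field template rendering.

Templates are plain text or HTML with ``{{field}}`` merge fields and a
``{{#variants}}…{{/variants}}`` loop block for the reported-variant table.
Rendering is deterministic: the same template and context always produce
byte-identical output.  Draft reports are watermarked; previous renders are
archived immutably for comparison.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from .curation import CLASSIFICATIONS, KnowledgeBase, SampleReview

SUPPRESSED = "[SUPPRESSED]"

#: ROLE_DEV sees everything an admin does, minus patient identity
PHI_SUPPRESSED_ROLES = frozenset({"ROLE_DEV"})

#: states from which a draft may be built; final reports need final_review
DRAFTABLE_STATES = frozenset({"first_review", "second_review", "final_review",
                              "reported"})


class ReportError(ValueError):
    pass


class TemplateError(ReportError):
    """Template references fields absent from the context."""


@dataclass
class ReportContext:
    """The value set handed to the renderer for one sample."""

    patient_id: str
    patient_name: str
    patient_dob: str
    assay_id: str
    sample_id: str
    run_id: str
    qc_summary: str
    draft: bool
    variants: list[dict[str, Any]] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)

    def fields(self) -> dict[str, Any]:
        d = {
            "patient_id": self.patient_id,
            "patient_name": self.patient_name,
            "patient_dob": self.patient_dob,
            "assay_id": self.assay_id,
            "sample_id": self.sample_id,
            "run_id": self.run_id,
            "qc_summary": self.qc_summary,
            "n_variants": len(self.variants),
            "draft": "DRAFT" if self.draft else "FINAL",
        }
        d.update(self.extra)
        return d


_SEVERITY = {c: i for i, c in enumerate(CLASSIFICATIONS)}

UNRESOLVED_DESCRIPTION = "[curated description pending]"


def build_context(sample_meta: Mapping[str, Any], review: SampleReview,
                  reported_variants: Sequence[Mapping[str, Any]],
                  kb: KnowledgeBase, actor_role: str,
                  disease_context: str | None = None) -> ReportContext:
    """Assemble the merge-field context for a sample's report.

    The sample must have passed first review; the result is a draft unless
    the sample has reached final review.  Each reported variant is matched
    against the knowledge base for its classification and curated
    description (a flagged placeholder when absent).  Patient identity is
    suppressed for roles without PHI access.
    """
    if review.state not in DRAFTABLE_STATES:
        raise ReportError(
            f"sample {review.sample_id} in state {review.state!r}: "
            "reports need at least first review"
        )
    draft = review.state not in ("final_review", "reported")
    suppress = actor_role in PHI_SUPPRESSED_ROLES
    variants = []
    for v in reported_variants:
        hgvs = v.get("hgvs_c") or v.get("hgvs_g") or ""
        rec = kb.match(hgvs, disease_context) if hgvs else None
        variants.append({
            "gene": v.get("gene", ""),
            "hgvs_c": v.get("hgvs_c", "") or "",
            "hgvs_p": v.get("hgvs_p", "") or "",
            "vaf": f"{float(v['vaf']):.1%}" if "vaf" in v else "",
            "classification": rec.classification if rec else "Unknown pathogenicity",
            "description": (rec.description if rec and rec.description
                            else UNRESOLVED_DESCRIPTION),
            "citations": "; ".join(rec.citations) if rec else "",
        })
    variants.sort(key=lambda d: (_SEVERITY.get(d["classification"], 99), d["gene"]))
    return ReportContext(
        patient_id=str(sample_meta.get("patient_id", "")),
        patient_name=SUPPRESSED if suppress else str(sample_meta.get("patient_name", "")),
        patient_dob=SUPPRESSED if suppress else str(sample_meta.get("patient_dob", "")),
        assay_id=str(sample_meta.get("assay_id", "")),
        sample_id=review.sample_id,
        run_id=str(sample_meta.get("run_id", "")),
        qc_summary=str(sample_meta.get("qc_summary", "")),
        draft=draft,
        variants=variants,
    )


# ---------------------------------------------------------------------------
# merge-field rendering

_LOOP_RE = re.compile(r"\{\{#variants\}\}(.*?)\{\{/variants\}\}", re.S)
_FIELD_RE = re.compile(r"\{\{\s*([A-Za-z_][A-Za-z0-9_]*)\s*\}\}")

DRAFT_WATERMARK_TEXT = "*** DRAFT — NOT FOR CLINICAL USE ***"
DRAFT_WATERMARK_HTML = '<div class="watermark">DRAFT — NOT FOR CLINICAL USE</div>'


def _substitute(fragment: str, values: Mapping[str, Any]) -> str:
    missing = sorted({m.group(1) for m in _FIELD_RE.finditer(fragment)
                      if m.group(1) not in values})
    if missing:
        raise TemplateError("unknown merge fields: " + ", ".join(missing))
    return _FIELD_RE.sub(lambda m: str(values[m.group(1)]), fragment)


def render(template: str, ctx: ReportContext, format: str = "text") -> str:
    """Render a merge-field template against a report context.

    Every ``{{field}}`` must resolve (unknown fields raise a TemplateError
    naming them); the ``{{#variants}}`` block repeats once per reported
    variant.  Draft contexts are watermarked.
    """
    if format not in ("text", "html"):
        raise ReportError(f"format must be text|html, got {format!r}")
    base = ctx.fields()

    def expand_loop(m: re.Match) -> str:
        body = m.group(1)
        return "".join(_substitute(body, {**base, **v}) for v in ctx.variants)

    out = _LOOP_RE.sub(expand_loop, template)
    out = _substitute(out, base)
    if ctx.draft:
        mark = DRAFT_WATERMARK_HTML if format == "html" else DRAFT_WATERMARK_TEXT
        out = mark + "\n" + out
    return out


# ---------------------------------------------------------------------------
# archive

class ReportArchive:
    """Immutable versioned report store with a JSON manifest per sample."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _dir(self, sample_id: str) -> Path:
        d = self.root / sample_id
        d.mkdir(exist_ok=True)
        return d

    def archive(self, sample_id: str, document: str, format: str = "text") -> int:
        """Store a rendered document; returns the new version number."""
        d = self._dir(sample_id)
        versions = self.versions(sample_id)
        n = (versions[-1] if versions else 0) + 1
        ext = "html" if format == "html" else "txt"
        path = d / f"v{n}.{ext}"
        path.write_text(document)
        manifest = d / "manifest.json"
        entries = json.loads(manifest.read_text()) if manifest.exists() else []
        entries.append({
            "version": n, "file": path.name,
            "sha256": hashlib.sha256(document.encode()).hexdigest(),
        })
        manifest.write_text(json.dumps(entries, indent=1))
        return n

    def versions(self, sample_id: str) -> list[int]:
        d = self.root / sample_id
        if not d.exists():
            return []
        manifest = d / "manifest.json"
        if not manifest.exists():
            return []
        return sorted(e["version"] for e in json.loads(manifest.read_text()))

    def retrieve(self, sample_id: str, version: int) -> str:
        manifest = self.root / sample_id / "manifest.json"
        if not manifest.exists():
            raise ReportError(f"no archived reports for sample {sample_id}")
        for e in json.loads(manifest.read_text()):
            if e["version"] == version:
                return (self.root / sample_id / e["file"]).read_text()
        raise ReportError(f"sample {sample_id} has no version {version}")


DEFAULT_TEMPLATE = """\
MOLECULAR PATHOLOGY REPORT ({{draft}})
Patient: {{patient_name}} (id {{patient_id}}, DOB {{patient_dob}})
Sample: {{sample_id}}    Assay: {{assay_id}}    Run: {{run_id}}
QC: {{qc_summary}}

Reported variants ({{n_variants}}):
{{#variants}}- {{gene}} {{hgvs_c}} {{hgvs_p}} VAF {{vaf}} — {{classification}}
  {{description}}
{{/variants}}
End of report.
"""
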