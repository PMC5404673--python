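"""Curated-variant knowledge base, classification and review workflow.

A curated variant is keyed by its normalised HGVS string (3'-shifted,
reportable transcript) and optionally differentiated by patient disease
context — the same substitution can carry different clinical weight in
colorectal cancer than in melanoma.  A record is written once; every later
sample containing the variant (and context) matches it automatically, which
is why normalisation upstream must be deterministic.

Classification uses the published ACMG/AMP evidence-combining criteria over
five tiers, with local tier names: Pathogenic, Likely pathogenic, Unknown
pathogenicity (VUS), Unlikely pathogenic (likely benign), Not pathogenic
(benign).

Sample review follows the laboratory workflow: QC sign-off, first review
(lab scientist), second review, final review locked by a curator, then
reporting.  Every transition is role-guarded and audited.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

from .normalize import NormalizedVariant

ROLES = ("ROLE_ADMIN", "ROLE_DEV", "ROLE_CURATOR", "ROLE_EXPERT",
         "ROLE_LAB", "ROLE_VIEWER")

CLASSIFICATIONS = (
    "Pathogenic",
    "Likely pathogenic",
    "Unknown pathogenicity",
    "Unlikely pathogenic",
    "Not pathogenic",
)

STRENGTHS = ("very_strong", "strong", "moderate", "supporting", "stand_alone")

#: roles allowed to create/update curated evidence
CURATION_ROLES = frozenset({"ROLE_CURATOR", "ROLE_EXPERT", "ROLE_ADMIN", "ROLE_DEV"})


class CurationError(ValueError):
    pass


class WorkflowError(CurationError):
    """Illegal state transition."""


class RolePermissionError(CurationError):
    """Actor's role does not permit the action."""


@dataclass(frozen=True)
class EvidenceItem:
    """One ACMG-style evidence criterion asserted for a variant."""

    code: str  # e.g. PVS1, PS1, PM2, PP3, BA1, BS1, BP4
    polarity: str  # pathogenic | benign
    strength: str  # very_strong | strong | moderate | supporting | stand_alone
    germline_only: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("pathogenic", "benign"):
            raise CurationError(f"polarity {self.polarity!r} invalid")
        if self.strength not in STRENGTHS:
            raise CurationError(f"strength {self.strength!r} invalid")
        if self.strength == "stand_alone" and self.polarity != "benign":
            raise CurationError("stand_alone strength is benign-only (BA1)")


#: the standard ACMG/AMP criterion codes with their polarity and strength
STANDARD_CRITERIA: dict[str, tuple[str, str]] = {
    "PVS1": ("pathogenic", "very_strong"),
    **{f"PS{i}": ("pathogenic", "strong") for i in range(1, 5)},
    **{f"PM{i}": ("pathogenic", "moderate") for i in range(1, 7)},
    **{f"PP{i}": ("pathogenic", "supporting") for i in range(1, 6)},
    "BA1": ("benign", "stand_alone"),
    **{f"BS{i}": ("benign", "strong") for i in range(1, 5)},
    **{f"BP{i}": ("benign", "supporting") for i in range(1, 8)},
}


def evidence(code: str, note: str = "") -> EvidenceItem:
    """EvidenceItem for a standard ACMG criterion code."""
    try:
        polarity, strength = STANDARD_CRITERIA[code.upper()]
    except KeyError:
        raise CurationError(f"unknown ACMG criterion {code!r}") from None
    return EvidenceItem(code=code.upper(), polarity=polarity, strength=strength, note=note)


def classify(items: Iterable[EvidenceItem]) -> str:
    """Combine evidence into one of the five tiers (ACMG/AMP rules).

    Empty evidence is Unknown pathogenicity; when both a pathogenic and a
    benign combination are satisfied the result is Unknown pathogenicity
    (conflicting evidence).
    """
    items = list(items)
    pvs = sum(1 for e in items if e.polarity == "pathogenic" and e.strength == "very_strong")
    ps = sum(1 for e in items if e.polarity == "pathogenic" and e.strength == "strong")
    pm = sum(1 for e in items if e.polarity == "pathogenic" and e.strength == "moderate")
    pp = sum(1 for e in items if e.polarity == "pathogenic" and e.strength == "supporting")
    ba = sum(1 for e in items if e.polarity == "benign" and e.strength == "stand_alone")
    bs = sum(1 for e in items if e.polarity == "benign" and e.strength == "strong")
    bp = sum(1 for e in items if e.polarity == "benign" and e.strength == "supporting")

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps == 1 and pm >= 1)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_tier = "Pathogenic" if pathogenic else (
        "Likely pathogenic" if likely_pathogenic else None)
    benign_tier = "Not pathogenic" if benign else (
        "Unlikely pathogenic" if likely_benign else None)
    if path_tier and benign_tier:
        return "Unknown pathogenicity"  # conflicting evidence
    return path_tier or benign_tier or "Unknown pathogenicity"


@dataclass
class CuratedVariant:
    """One knowledge-base record: (hgvs_key, disease_context) is unique."""

    hgvs_key: str
    gene: str
    disease_context: str | None = None
    classification: str = "Unknown pathogenicity"
    evidence: tuple[EvidenceItem, ...] = ()
    description: str = ""
    citations: tuple[str, ...] = ()
    created_by: str = ""
    updated_by: str = ""
    manual_override: bool = False
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise CurationError(f"unknown classification {self.classification!r}")


def _norm_context(ctx: str | None) -> str | None:
    if ctx is None:
        return None
    ctx = " ".join(ctx.split()).lower()
    return ctx or None


class KnowledgeBase:
    """Persistent curated-variant store with audit trail.

    Persisted as JSON-lines; the audit log is itself JSON-lines and replaying
    it reconstructs the store.
    """

    def __init__(self) -> None:
        self._records: dict[tuple[str, str | None], CuratedVariant] = {}
        self.audit: list[dict[str, Any]] = []
        self._subscriptions: dict[str, set[str]] = {}  # user -> tags of interest

    def __len__(self) -> int:
        return len(self._records)

    def records(self) -> list[CuratedVariant]:
        return list(self._records.values())

    # -- mutation ----------------------------------------------------------
    def upsert(self, hgvs_key: str, gene: str, disease_context: str | None,
               evidence_items: Sequence[EvidenceItem], description: str,
               user: str, role: str, citations: Sequence[str] = (),
               classification_override: str | None = None,
               tags: Sequence[str] = ()) -> CuratedVariant:
        """Create or update the record for (hgvs_key, disease_context).

        Classification is recomputed from evidence unless an explicit manual
        override is given (recorded as such).  Curator-level roles only.
        """
        if role not in CURATION_ROLES:
            raise RolePermissionError(f"role {role} may not curate variants")
        if not hgvs_key or ":" not in hgvs_key:
            raise CurationError(f"malformed HGVS key {hgvs_key!r}")
        ctx = _norm_context(disease_context)
        key = (hgvs_key, ctx)
        existing = self._records.get(key)
        cls = classification_override or classify(evidence_items)
        if classification_override and classification_override not in CLASSIFICATIONS:
            raise CurationError(f"unknown classification {classification_override!r}")
        rec = CuratedVariant(
            hgvs_key=hgvs_key,
            gene=gene,
            disease_context=ctx,
            classification=cls,
            evidence=tuple(evidence_items),
            description=description,
            citations=tuple(citations),
            created_by=existing.created_by if existing else user,
            updated_by=user,
            manual_override=classification_override is not None,
            tags=tuple(tags),
        )
        self._records[key] = rec
        self._audit("upsert" if existing is None else "update", user, role, {
            "hgvs_key": hgvs_key, "context": ctx, "gene": gene,
            "classification": cls,
            "evidence": [e.code for e in evidence_items],
            "description": description, "citations": list(citations),
            "override": classification_override, "tags": list(tags),
        })
        return rec

    def _audit(self, action: str, user: str, role: str, detail: dict) -> None:
        self.audit.append({
            "action": action, "user": user, "role": role,
            "at": time.time(), "detail": detail,
        })

    # -- matching ----------------------------------------------------------
    def match(self, norm: NormalizedVariant | str,
              disease_context: str | None = None) -> CuratedVariant | None:
        """Match a normalised variant to a record.

        An exact disease-context match wins; otherwise a generic
        (context-free) record is returned; otherwise nothing.
        """
        keys: list[str]
        if isinstance(norm, str):
            keys = [norm]
        else:
            keys = [k for k in (norm.hgvs_c, norm.hgvs_g) if k]
        ctx = _norm_context(disease_context)
        for k in keys:
            if ctx is not None and (k, ctx) in self._records:
                return self._records[(k, ctx)]
        for k in keys:
            if (k, None) in self._records:
                return self._records[(k, None)]
        return None

    # -- subscriptions (interest registry only; no notification transport) --
    def subscribe(self, user: str, tag: str) -> None:
        self._subscriptions.setdefault(user, set()).add(tag)

    def subscribers(self, tag: str) -> set[str]:
        return {u for u, tags in self._subscriptions.items() if tag in tags}

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            for (k, ctx), r in sorted(self._records.items(),
                                      key=lambda kv: (kv[0][0], kv[0][1] or "")):
                fh.write(json.dumps({
                    "hgvs_key": r.hgvs_key, "gene": r.gene,
                    "disease_context": r.disease_context,
                    "classification": r.classification,
                    "evidence": [e.code for e in r.evidence],
                    "description": r.description,
                    "citations": list(r.citations),
                    "created_by": r.created_by, "updated_by": r.updated_by,
                    "manual_override": r.manual_override,
                    "tags": list(r.tags),
                }) + "\n")

    @classmethod
    def load(cls, path: str) -> "KnowledgeBase":
        kb = cls()
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                rec = CuratedVariant(
                    hgvs_key=d["hgvs_key"], gene=d["gene"],
                    disease_context=d["disease_context"],
                    classification=d["classification"],
                    evidence=tuple(evidence(c) for c in d["evidence"]),
                    description=d["description"],
                    citations=tuple(d["citations"]),
                    created_by=d["created_by"], updated_by=d["updated_by"],
                    manual_override=d["manual_override"],
                    tags=tuple(d.get("tags", ())),
                )
                kb._records[(rec.hgvs_key, rec.disease_context)] = rec
        return kb

    @classmethod
    def replay(cls, audit: Sequence[Mapping[str, Any]]) -> "KnowledgeBase":
        """Reconstruct a knowledge base from its audit log."""
        kb = cls()
        for entry in audit:
            if entry["action"] in ("upsert", "update"):
                d = entry["detail"]
                kb.upsert(
                    d["hgvs_key"], d["gene"], d["context"],
                    [evidence(c) for c in d["evidence"]],
                    d["description"], entry["user"], entry["role"],
                    citations=d.get("citations", ()),
                    classification_override=d.get("override"),
                    tags=d.get("tags", ()),
                )
        return kb


# ---------------------------------------------------------------------------
# sample review workflow

REVIEW_STATES = (
    "registered", "qc_pending", "qc_passed", "qc_failed",
    "first_review", "second_review", "final_review", "reported",
)

#: action -> (from_state, to_state, allowed roles)
TRANSITIONS: dict[str, tuple[str, str, frozenset[str]]] = {
    "begin_qc": ("registered", "qc_pending",
                 frozenset({"ROLE_LAB", "ROLE_ADMIN", "ROLE_DEV"})),
    "pass_qc": ("qc_pending", "qc_passed",
                frozenset({"ROLE_LAB", "ROLE_ADMIN", "ROLE_DEV"})),
    "fail_qc": ("qc_pending", "qc_failed",
                frozenset({"ROLE_LAB", "ROLE_ADMIN", "ROLE_DEV"})),
    "authorise_first_review": ("qc_passed", "first_review",
                               frozenset({"ROLE_LAB", "ROLE_ADMIN", "ROLE_DEV"})),
    "authorise_second_review": ("first_review", "second_review",
                                frozenset({"ROLE_LAB", "ROLE_CURATOR",
                                           "ROLE_EXPERT", "ROLE_ADMIN", "ROLE_DEV"})),
    "finalise": ("second_review", "final_review",
                 frozenset({"ROLE_CURATOR", "ROLE_EXPERT", "ROLE_ADMIN", "ROLE_DEV"})),
    "report": ("final_review", "reported",
               frozenset({"ROLE_CURATOR", "ROLE_EXPERT", "ROLE_ADMIN", "ROLE_DEV"})),
    # qc_failed is terminal except for an administrative override
    "override_qc_failure": ("qc_failed", "qc_pending",
                            frozenset({"ROLE_ADMIN", "ROLE_DEV"})),
}


@dataclass
class SampleReview:
    """Workflow state of one sample; layouts freeze at first review."""

    sample_id: str
    state: str = "registered"
    frozen_layout: bool = False
    history: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in REVIEW_STATES:
            raise CurationError(f"unknown review state {self.state!r}")


def advance_review(review: SampleReview, action: str, user: str, role: str
                   ) -> SampleReview:
    """Apply one workflow action; the input object is not mutated on error.

    Role checks follow the laboratory division of labour: lab scientists run
    QC and submit for first review; curators (and experts) lock samples into
    final review and release reports; admins may do anything, including
    overriding a failed QC.
    """
    if action not in TRANSITIONS:
        raise WorkflowError(f"unknown action {action!r}")
    src, dst, roles = TRANSITIONS[action]
    if review.state != src:
        raise WorkflowError(
            f"action {action!r} illegal from state {review.state!r} (needs {src!r})"
        )
    if role not in roles:
        raise RolePermissionError(f"role {role} may not {action}")
    updated = replace(review)
    updated.history = list(review.history)
    updated.state = dst
    if dst == "first_review":
        updated.frozen_layout = True
    updated.history.append({
        "action": action, "user": user, "role": role,
        "from": src, "to": dst, "at": time.time(),
    })
    return updated


def replay_review(sample_id: str, history: Sequence[Mapping[str, Any]]) -> SampleReview:
    """Rebuild a review's final state by replaying its audit history."""
    review = SampleReview(sample_id)
    for entry in history:
        review = advance_review(review, entry["action"], entry["user"], entry["role"])
    return review


# ---------------------------------------------------------------------------
# free-text search

@dataclass(frozen=True)
class SearchHit:
    object_type: str
    object_id: str
    field: str
    value: str
    span: tuple[int, int]


#: fields consulted per object type
SEARCHABLE_FIELDS = {
    "patient": ("id", "name", "tags"),
    "sample": ("sample_id", "assay_id", "tags"),
    "sequenced_variant": ("variant_key", "hgvs_g", "hgvs_c", "gene", "tags"),
    "curated_variant": ("hgvs_key", "gene", "disease_context", "description",
                        "classification", "citations", "tags"),
}


def search(objects: Iterable[tuple[str, Mapping[str, Any]]], query: str
           ) -> dict[str, list[SearchHit]]:
    """Case-insensitive substring search, hits grouped by object type.

    ``objects`` yields (object_type, field-mapping) pairs; list-valued fields
    (tags, citations) are searched element-wise.
    """
    if not query:
        raise CurationError("empty search query")
    q = query.lower()
    hits: dict[str, list[SearchHit]] = {}
    for otype, obj in objects:
        fields = SEARCHABLE_FIELDS.get(otype, tuple(obj.keys()))
        oid = str(obj.get("id") or obj.get("sample_id") or obj.get("variant_key")
                  or obj.get("hgvs_key") or "?")
        for f in fields:
            val = obj.get(f)
            if val is None:
                continue
            values = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
            for v in values:
                s = str(v)
                i = s.lower().find(q)
                if i >= 0:
                    hits.setdefault(otype, []).append(
                        SearchHit(otype, oid, f, s, (i, i + len(q)))
                    )
    return hits
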