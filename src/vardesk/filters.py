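"""Automatic assay filter flags and the user filter-expression engine.

Ten flags are attached to every call at load time; filtering is always a
view over the data, never a deletion — any variant may still be inspected
and reported regardless of its flags.

Flags and their default thresholds (strict inequalities, as printed in the
assay documentation; boundary values do not fire):

==== =====================================================================
pass passed all filters (no other flag fired)
vaf  low variant allele frequency (<8% somatic, <15% germline)
vrd  low total read depth (<100 reads)
vad  low variant read depth (<20 reads)
blk  assay-specific variant blacklist
oor  out of assay-specific region of interest
con  inferred benign consequence
gmaf high global minor allele frequency (>1%)
pnl  frequently occurring variant in assay history (>35% of samples)
sin  singleton in a replicate pair (not seen in both replicates)
==== =====================================================================
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .variants import RegionSet, VariantCall, read_roi_bed

logger = logging.getLogger(__name__)

FLAGS = ("pass", "vaf", "vrd", "vad", "blk", "oor", "con", "gmaf", "pnl", "sin")

#: consequence terms treated as inferred-benign by default (configurable)
DEFAULT_BENIGN_CONSEQUENCES = frozenset({
    "synonymous_variant",
    "intron_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "intergenic_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
})


class FilterError(ValueError):
    pass


@dataclass
class AssayConfig:
    """Per-assay thresholds, blacklist, region of interest and presets."""

    assay_id: str
    sample_type: str = "somatic"  # somatic | germline
    min_vaf: float | None = None  # defaults depend on sample_type
    min_total_depth: int = 100
    min_alt_depth: int = 20
    max_gmaf: float = 0.01
    max_panel_frac: float = 0.35
    blacklist: set[str] = field(default_factory=set)
    roi: RegionSet | None = None
    benign_consequences: frozenset[str] = DEFAULT_BENIGN_CONSEQUENCES
    presets: dict[str, "FilterExpression"] = field(default_factory=dict)
    # zygosity bands, germline display only
    het_band: tuple[float, float] = (0.35, 0.65)
    hom_min: float = 0.85

    def __post_init__(self) -> None:
        if self.sample_type not in ("somatic", "germline"):
            raise FilterError(f"sample_type must be somatic|germline, got {self.sample_type!r}")
        if self.min_vaf is None:
            self.min_vaf = 0.15 if self.sample_type == "germline" else 0.08
        for name in ("min_vaf", "max_gmaf", "max_panel_frac"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise FilterError(f"{name}={x} outside [0, 1]")
        if self.sample_type == "germline" and self.min_vaf < 0.08:
            raise FilterError("germline min_vaf below the somatic default")

    @classmethod
    def from_yaml(cls, path: str) -> "AssayConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        thr = d.get("thresholds", {})
        roi = read_roi_bed(d["roi_bed"]) if d.get("roi_bed") else None
        cfg = cls(
            assay_id=d["assay_id"],
            sample_type=d.get("sample_type", "somatic"),
            min_vaf=thr.get("min_vaf"),
            min_total_depth=thr.get("min_total_depth", 100),
            min_alt_depth=thr.get("min_alt_depth", 20),
            max_gmaf=thr.get("max_gmaf", 0.01),
            max_panel_frac=thr.get("max_panel_frac", 0.35),
            blacklist=set(d.get("blacklist", [])),
            roi=roi,
            benign_consequences=frozenset(d.get("benign_consequences",
                                                DEFAULT_BENIGN_CONSEQUENCES)),
        )
        for name, text in d.get("presets", {}).items():
            cfg.presets[name] = parse_filter(text)
        return cfg


@dataclass
class FlagResult:
    """Flags fired for one call, plus rules that could not be evaluated.

    ``pass`` is present iff no other flag fired; unevaluable rules are
    reported separately so a variant is never silently passed on missing
    data.
    """

    flags: set[str]
    unevaluable: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        fired = self.flags - {"pass"}
        if ("pass" in self.flags) != (not fired):
            raise FilterError("pass flag inconsistent with other flags")

    @property
    def passed(self) -> bool:
        return "pass" in self.flags and not self.unevaluable


def replicate_singleton(variant_key: str, replicate_a: set[str],
                        replicate_b: set[str]) -> bool:
    """True iff the key appears in exactly one of the two replicates."""
    in_a, in_b = variant_key in replicate_a, variant_key in replicate_b
    if not in_a and not in_b:
        logger.warning("key %s in neither replicate", variant_key)
        return False
    return in_a != in_b


def panel_frequency(variant_key: str,
                    assay_history: Mapping[str, set[str]]) -> float:
    """Fraction of historical assay samples carrying the key.

    ``assay_history`` maps one entry per physical sample (replicate pairs
    already merged by the caller) to its variant-key set.
    """
    if not assay_history:
        raise FilterError("empty assay history: panel frequency undefined")
    n = sum(1 for keys in assay_history.values() if variant_key in keys)
    return n / len(assay_history)


def merge_replicate_history(sample_keys: Mapping[str, set[str]],
                            pair_of: Mapping[str, str] | None = None
                            ) -> dict[str, set[str]]:
    """Collapse replicate samples to one history entry per physical sample.

    Replicates named ``<base>_R1``/``<base>_R2`` (or given explicitly via
    ``pair_of``) contribute the union of their keys under the base name, so
    a pair never counts twice in the panel-frequency denominator.
    """
    merged: dict[str, set[str]] = {}
    for sid, keys in sample_keys.items():
        if pair_of and sid in pair_of:
            base = pair_of[sid]
        else:
            m = re.match(r"^(.*)_R[12]$", sid)
            base = m.group(1) if m else sid
        merged.setdefault(base, set()).update(keys)
    return merged


def assign_flags(call: VariantCall, cfg: AssayConfig,
                 annotations: Mapping[str, Any] | None = None,
                 replicate_partner_keys: set[str] | None = None,
                 panel_frac: float | None = None,
                 variant_key: str | None = None) -> FlagResult:
    """Evaluate the ten automatic flag rules for one annotated call.

    Each rule fires independently; comparisons are strict as documented.
    ``annotations`` supplies ``gmaf`` (empty/None means absent from the
    population, i.e. frequency 0) and ``consequence``; a rule whose inputs
    are missing entirely is recorded as unevaluable, never silently passed.
    ``variant_key`` is the normalised (left-aligned) key used for blacklist
    and replicate matching; it defaults to the raw call's key, but callers
    that have normalised should always pass it — key stability is what makes
    those joins sound.
    """
    ann = dict(annotations or {})
    flags: set[str] = set()
    unevaluable: set[str] = set()
    v = call.variant
    key = variant_key or v.key

    if call.vaf < cfg.min_vaf:
        flags.add("vaf")
    if call.total_depth < cfg.min_total_depth:
        flags.add("vrd")
    if call.alt_depth < cfg.min_alt_depth:
        flags.add("vad")
    if key in cfg.blacklist:
        flags.add("blk")

    if cfg.roi is None:
        unevaluable.add("oor")
    elif not cfg.roi.contains(v.chrom, v.pos, v.end):
        flags.add("oor")

    if "consequence" not in ann:
        unevaluable.add("con")
    elif ann["consequence"] in cfg.benign_consequences:
        flags.add("con")

    if "gmaf" not in ann:
        unevaluable.add("gmaf")
    else:
        raw = ann["gmaf"]
        gmaf = 0.0 if raw in (None, "", ".") else float(raw)
        if gmaf > cfg.max_gmaf:
            flags.add("gmaf")

    if panel_frac is None:
        unevaluable.add("pnl")
    elif panel_frac > cfg.max_panel_frac:
        flags.add("pnl")

    if replicate_partner_keys is None:
        unevaluable.add("sin")
    elif key not in replicate_partner_keys:
        flags.add("sin")

    if not flags:
        flags.add("pass")
    return FlagResult(flags=flags, unevaluable=unevaluable)


def assign_zygosity(call: VariantCall, cfg: AssayConfig) -> str:
    """Germline zygosity from VAF bands; somatic assays get no call.

    Heterozygous within the het band (default 35–65% VAF), homozygous at or
    above the hom threshold (default 85%), otherwise 'other' — consistent
    with the bimodal germline VAF distribution peaking at 50% and 100%.
    """
    if cfg.sample_type != "germline":
        return "not_applicable"
    lo, hi = cfg.het_band
    if lo <= call.vaf <= hi:
        return "heterozygous"
    if call.vaf >= cfg.hom_min:
        return "homozygous"
    return "other"


def retained_fraction(n_retained: int, n_total: int) -> float:
    """Fraction of calls surviving a filter cascade."""
    if n_total <= 0:
        raise FilterError("n_total must be positive")
    if not 0 <= n_retained <= n_total:
        raise FilterError("n_retained outside [0, n_total]")
    return n_retained / n_total


def artefact_filter_retention(calls_with_flags: Sequence[tuple[Any, FlagResult]]
                              ) -> tuple[list, float]:
    """Apply the replicate-singleton / panel-recurrence / depth cascade.

    Removes calls flagged sin, pnl, vrd or vad and returns the survivors
    with the retained fraction — the artefact-removal view used to clean an
    amplicon panel's VAF distribution.
    """
    kept = [c for c, fr in calls_with_flags
            if not ({"sin", "pnl", "vrd", "vad"} & fr.flags)]
    return kept, retained_fraction(len(kept), len(calls_with_flags))


# ---------------------------------------------------------------------------
# user filter expressions

OPERATORS = {
    "equals": "eq", "is": "eq",
    "not equals": "ne", "is not": "ne",
    "less than": "lt", "less or equal": "le",
    "greater than": "gt", "greater or equal": "ge",
    "is in": "in", "not in": "not_in",
    "contains": "contains",
}

_CLAUSE_RE = re.compile(r"\[\s*([^'\[\]]+?)\s+'([^']+)'\s+([^\[\]]*?)\s*\]")


@dataclass(frozen=True)
class FilterClause:
    attribute: str
    operator: str  # canonical: eq ne lt le gt ge in not_in contains
    operand: Any


@dataclass(frozen=True)
class FilterExpression:
    """Conjunction of clauses over call/annotation/flag attributes."""

    clauses: tuple[FilterClause, ...] = ()

    def matches(self, record: Mapping[str, Any]) -> bool:
        return all(_eval_clause(c, record) for c in self.clauses)


def parse_filter(text: str, known_attributes: Iterable[str] | None = None
                 ) -> FilterExpression:
    """Parse ``[<attr> '<op>' <operand>]`` clauses (implicit AND).

    An empty string is the match-all expression.  Operator names are the
    human-readable forms ('Is In', 'Greater Than', ...); operands for list
    operators are comma-separated.
    """
    text = text.strip()
    if not text:
        return FilterExpression()
    clauses = []
    pos = 0
    known = {a.lower() for a in known_attributes} if known_attributes is not None else None
    for m in _CLAUSE_RE.finditer(text):
        between = text[pos:m.start()].strip()
        if between:
            raise FilterError(f"unparseable filter text at position {pos}: {between!r}")
        attr, op_name, operand_text = m.group(1).strip(), m.group(2), m.group(3).strip()
        op = OPERATORS.get(op_name.lower())
        if op is None:
            raise FilterError(
                f"unknown operator {op_name!r} at position {m.start(2)}"
            )
        if known is not None and attr.lower() not in known:
            raise FilterError(f"unknown attribute {attr!r} at position {m.start(1)}")
        operand: Any
        if op in ("in", "not_in"):
            operand = tuple(x.strip() for x in operand_text.split(",") if x.strip())
        else:
            operand = _coerce(operand_text)
        clauses.append(FilterClause(attr, op, operand))
        pos = m.end()
    tail = text[pos:].strip()
    if tail:
        raise FilterError(f"unparseable filter text at position {pos}: {tail!r}")
    return FilterExpression(tuple(clauses))


def _coerce(text: str) -> Any:
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def _lookup(record: Mapping[str, Any], attr: str) -> Any:
    for k in (attr, attr.lower()):
        if k in record:
            return record[k]
    lower = {k.lower(): v for k, v in record.items()}
    return lower.get(attr.lower())


def _eval_clause(c: FilterClause, record: Mapping[str, Any]) -> bool:
    value = _lookup(record, c.attribute)
    if c.operator in ("in", "not_in"):
        operands = c.operand if isinstance(c.operand, tuple) else (c.operand,)
        if isinstance(value, (set, frozenset, list, tuple)):
            # set-valued attribute (e.g. flags): membership of operands in it
            hit = any(str(o) in {str(x) for x in value} for o in operands)
        else:
            hit = str(value) in {str(o) for o in operands}
        return hit if c.operator == "in" else not hit
    if c.operator == "contains":
        if isinstance(value, (set, frozenset, list, tuple)):
            return str(c.operand) in {str(x) for x in value}
        return str(c.operand) in str(value)
    if value is None:
        return False
    if c.operator == "eq":
        return _cmp_eq(value, c.operand)
    if c.operator == "ne":
        return not _cmp_eq(value, c.operand)
    try:
        lhs, rhs = float(value), float(c.operand)
    except (TypeError, ValueError) as exc:
        raise FilterError(
            f"clause [{c.attribute} {c.operator} {c.operand!r}]: "
            f"non-numeric comparison with {value!r}"
        ) from exc
    return {"lt": lhs < rhs, "le": lhs <= rhs,
            "gt": lhs > rhs, "ge": lhs >= rhs}[c.operator]


def _cmp_eq(value: Any, operand: Any) -> bool:
    try:
        return float(value) == float(operand)
    except (TypeError, ValueError):
        return str(value) == str(operand)


def apply_filter(expr: FilterExpression, records: Sequence[Mapping[str, Any]]
                 ) -> list[Mapping[str, Any]]:
    """Return the matching subset, preserving order; input is untouched."""
    return [r for r in records if expr.matches(r)]


# ---------------------------------------------------------------------------
# preset filters

PRESET_GENES = {
    "Colorectal": ("BRAF", "KRAS", "NRAS"),
    "Melanoma": ("BRAF", "NRAS", "RAC1", "KIT"),
    "Lung": ("BRAF", "EGFR", "KRAS", "MET"),
    "GIST": ("KIT", "PDGFRA"),
    "BRCA Only": ("BRCA1", "BRCA2"),
    "MNP Simple": ("JAK2", "MPL", "CALR", "KIT", "SF3B1", "CSF3R", "ASXL1"),
}


def preset_filter(name: str, cfg: AssayConfig) -> FilterExpression:
    """A shipped preset: tumour-stream genes plus the standard clean-up
    clauses (not blacklisted, in both replicates, protein-coding consequence,
    rare in the population, not a recurrent panel artefact)."""
    if name in cfg.presets:
        return cfg.presets[name]
    if name not in PRESET_GENES:
        raise FilterError(
            f"unknown preset {name!r}; available: "
            + ", ".join(sorted(set(PRESET_GENES) | set(cfg.presets)))
        )
    genes = PRESET_GENES[name]
    return FilterExpression((
        FilterClause("gene", "in", genes),
        FilterClause("filter_flags", "not_in", ("blk",)),
        FilterClause("filter_flags", "not_in", ("sin",)),
        FilterClause("consequence", "not_in", tuple(sorted(cfg.benign_consequences))),
        FilterClause("gmaf", "lt", cfg.max_gmaf),
        FilterClause("filter_flags", "not_in", ("pnl",)),
    ))


def call_record(call: VariantCall, annotations: Mapping[str, Any] | None = None,
                flag_result: FlagResult | None = None,
                gene: str | None = None, **extra: Any) -> dict[str, Any]:
    """Flatten a call + annotations + flags into a filterable record."""
    rec: dict[str, Any] = {
        "chrom": call.variant.chrom,
        "pos": call.variant.pos,
        "ref": call.variant.ref,
        "alt": call.variant.alt,
        "variant_key": call.variant.key,
        "sample_id": call.sample_id,
        "vaf": call.vaf,
        "total_depth": call.total_depth,
        "alt_depth": call.alt_depth,
    }
    if gene is not None:
        rec["gene"] = gene
    if annotations:
        for k, v in annotations.items():
            rec.setdefault(k, v)
    if flag_result is not None:
        rec["filter_flags"] = frozenset(flag_result.flags)
        rec["flag"] = rec["filter_flags"]
        rec["unevaluable"] = frozenset(flag_result.unevaluable)
    rec.update(extra)
    return rec
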