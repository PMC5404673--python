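"""Batch per-run annotation with a persistent cache.

Samples in a run share many variants (recurrent assay artefacts, common
polymorphisms), so a run's calls are annotated as one batch: only distinct
variant keys are looked up, and keys already cached from earlier runs are
served without touching the source at all.  The cache is keyed by
(variant_key, source); attribute values are stored unnormalised as strings.
"""

from __future__ import annotations

import json
import statistics
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence


class AnnotationError(Exception):
    pass


@dataclass(frozen=True)
class AttributeMeta:
    """Describes one annotation attribute a source provides."""

    name: str
    source: str
    category: str = ""
    description: str = ""
    tags: tuple[str, ...] = ()


@dataclass
class AnnotationRecord:
    variant_key: str
    source: str
    attributes: dict[str, str]
    fetched_at: float = field(default_factory=time.time)


@dataclass(frozen=True)
class CacheStats:
    """Per-run annotation-workload accounting.

    n_novel <= n_distinct <= n_calls always holds: novel keys are a subset of
    the run's distinct keys, which de-duplicate the sample-level calls.
    """

    run_id: str
    n_calls: int
    n_distinct: int
    n_novel: int

    def __post_init__(self) -> None:
        if not (self.n_novel <= self.n_distinct <= self.n_calls):
            raise AnnotationError(
                f"inconsistent stats: novel {self.n_novel} distinct "
                f"{self.n_distinct} calls {self.n_calls}"
            )

    @property
    def distinct_frac(self) -> float:
        return self.n_distinct / self.n_calls if self.n_calls else 0.0

    @property
    def novel_frac(self) -> float:
        return self.n_novel / self.n_distinct if self.n_distinct else 0.0


def annotation_workload(median_distinct_frac: float, median_novel_frac: float) -> float:
    """Fraction of a run's calls that actually require a source lookup.

    The product of the median distinct fraction (batch de-duplication) and
    the median novel fraction (cache misses among distinct keys).
    """
    for x in (median_distinct_frac, median_novel_frac):
        if not 0.0 <= x <= 1.0:
            raise AnnotationError(f"fraction {x} outside [0, 1]")
    return median_distinct_frac * median_novel_frac


def fold_reduction(workload: float) -> float:
    """Annotation-time fold reduction implied by a fractional workload."""
    if workload < 0:
        raise AnnotationError("workload must be non-negative")
    if workload == 0:
        return float("inf")
    return 1.0 / workload


class AnnotationSource:
    """A pluggable annotation provider.

    ``fetcher`` maps a batch of variant keys to ``{key: {attr: value}}``;
    keys absent from the source may be omitted from the result.
    """

    def __init__(self, name: str, fetcher: Callable[[Sequence[str]], Mapping[str, Mapping[str, str]]],
                 metadata: Iterable[AttributeMeta] = ()):
        self.name = name
        self.fetcher = fetcher
        self.metadata = list(metadata)
        self.n_fetches = 0  # fetcher invocations (batches)
        self.n_keys_fetched = 0

    def fetch(self, keys: Sequence[str]) -> dict[str, dict[str, str]]:
        self.n_fetches += 1
        self.n_keys_fetched += len(keys)
        return {k: dict(v) for k, v in self.fetcher(keys).items()}


class TsvSource(AnnotationSource):
    """File-backed source: TSV with a ``variant_key`` column plus one column
    per attribute.  This is the bundled mock-source format."""

    def __init__(self, name: str, path: str, category: str = "synthetic",
                 tags: Mapping[str, Sequence[str]] | None = None):
        import csv

        table: dict[str, dict[str, str]] = {}
        cols: list[str] = []
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                key = row.pop("variant_key")
                table[key] = {k: v for k, v in row.items()}
                cols = list(row)
        meta = [
            AttributeMeta(name=c, source=name, category=category,
                          tags=tuple((tags or {}).get(c, ())))
            for c in cols
        ]
        super().__init__(name, lambda keys: {k: table[k] for k in keys if k in table}, meta)


class AnnotationCache:
    """Persistent (variant_key, source) annotation store with batch lookup."""

    def __init__(self, cache_dir: str | Path | None = None):
        self.cache_dir = Path(cache_dir) if cache_dir else None
        self._sources: dict[str, AnnotationSource] = {}
        self._store: dict[tuple[str, str], AnnotationRecord] = {}
        self._meta: dict[str, AttributeMeta] = {}
        self.stats_history: list[CacheStats] = []
        self.errors: list[tuple[str, str]] = []  # (source, message)
        if self.cache_dir is not None:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
            self._load()

    # -- source registry --------------------------------------------------
    def register_source(self, source: AnnotationSource) -> None:
        if source.name in self._sources:
            raise AnnotationError(f"source {source.name!r} already registered")
        for m in source.metadata:
            if m.name in self._meta and self._meta[m.name].source != source.name:
                raise AnnotationError(
                    f"attribute {m.name!r} already registered by "
                    f"{self._meta[m.name].source!r}"
                )
            self._meta[m.name] = m
        self._sources[source.name] = source

    @property
    def sources(self) -> list[str]:
        return list(self._sources)

    def attribute_meta(self, name: str) -> AttributeMeta:
        return self._meta[name]

    def search_attributes(self, tag: str) -> list[AttributeMeta]:
        """Attributes carrying a given metadata tag."""
        return [m for m in self._meta.values() if tag in m.tags]

    @property
    def known_attributes(self) -> list[str]:
        return list(self._meta)

    # -- annotation -------------------------------------------------------
    def annotate_run(self, run_id: str, variant_keys: Sequence[str],
                     sources: Sequence[str] | None = None
                     ) -> tuple[dict[str, dict[str, str]], CacheStats]:
        """Annotate one run's calls as a batch.

        ``variant_keys`` is one entry per sample-level call (duplicates
        expected); each distinct key is fetched at most once per source, and
        only if absent from the cache.  Returns merged per-key attribute maps
        and the run's workload stats.  A failing source is recorded in
        ``errors`` and does not disturb the others.
        """
        names = list(sources) if sources is not None else list(self._sources)
        distinct = sorted(set(variant_keys))
        novel = [k for k in distinct
                 if any((k, s) not in self._store for s in names)]
        for name in names:
            src = self._sources[name]
            missing = [k for k in distinct if (k, name) not in self._store]
            if missing:
                try:
                    fetched = src.fetch(missing)
                except Exception as exc:  # noqa: BLE001 - per-source isolation
                    self.errors.append((name, str(exc)))
                    continue
                for k in missing:
                    attrs = {str(a): str(v) for a, v in fetched.get(k, {}).items()}
                    self._store[(k, name)] = AnnotationRecord(k, name, attrs)
        stats = CacheStats(run_id, len(variant_keys), len(distinct), len(novel))
        self.stats_history.append(stats)
        if self.cache_dir is not None:
            self._save()
        return {k: self.annotations_for(k, names) for k in distinct}, stats

    def annotations_for(self, key: str, sources: Sequence[str] | None = None) -> dict[str, str]:
        merged: dict[str, str] = {}
        for name in (sources if sources is not None else list(self._sources)):
            rec = self._store.get((key, name))
            if rec:
                merged.update(rec.attributes)
        return merged

    def purge_source(self, name: str) -> int:
        """Drop every cached record of one source (refresh = purge + refetch)."""
        doomed = [k for k in self._store if k[1] == name]
        for k in doomed:
            del self._store[k]
        if self.cache_dir is not None:
            self._save()
        return len(doomed)

    def __contains__(self, key_source: tuple[str, str]) -> bool:
        return key_source in self._store

    # -- persistence (JSON-lines per source) -------------------------------
    def _path(self, source: str) -> Path:
        assert self.cache_dir is not None
        return self.cache_dir / f"{source}.jsonl"

    def _save(self) -> None:
        assert self.cache_dir is not None
        by_source: dict[str, list[AnnotationRecord]] = {}
        for (_, s), rec in self._store.items():
            by_source.setdefault(s, []).append(rec)
        for s, recs in by_source.items():
            with open(self._path(s), "w") as fh:
                for r in sorted(recs, key=lambda r: r.variant_key):
                    fh.write(json.dumps({"variant_key": r.variant_key,
                                         "attributes": r.attributes,
                                         "fetched_at": r.fetched_at}) + "\n")

    def _load(self) -> None:
        assert self.cache_dir is not None
        for p in sorted(self.cache_dir.glob("*.jsonl")):
            source = p.stem
            with open(p) as fh:
                for line in fh:
                    d = json.loads(line)
                    self._store[(d["variant_key"], source)] = AnnotationRecord(
                        d["variant_key"], source, d["attributes"], d["fetched_at"]
                    )


def median_workload(history: Iterable[CacheStats]) -> tuple[float, float, float]:
    """(median distinct fraction, median novel fraction, workload product)."""
    hist = list(history)
    if not hist:
        raise AnnotationError("empty stats history")
    df = statistics.median(s.distinct_frac for s in hist)
    nf = statistics.median(s.novel_frac for s in hist)
    return df, nf, annotation_workload(df, nf)
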