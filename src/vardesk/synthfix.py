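"""Synthetic fixtures: reference, panel, replicate-paired runs, QC history.

Everything the toolkit consumes can be generated here deterministically from
one seed, at the scale of a routine amplicon sequencing run: patient samples
sequenced as technical replicates at high mean depth (~2300×), a germline
control sample and a non-template control, spiked with a designed mix of
true variants and the artefact phenomenology the filter flags exist to
catch — low-VAF noise, panel-recurrent artefacts, replicate singletons,
blacklisted and out-of-region calls, common population SNPs.

Read support is sampled binomially around each spike's target VAF; the
sequencing physics beyond that (error profiles, strand bias) is deliberately
not modelled — the flags, not the chemistry, are the test target.  A truth
table records the flags each call is expected to attract.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .filters import DEFAULT_BENIGN_CONSEQUENCES
from .normalize import Reference, left_align
from .variants import GenomicVariant, Transcript, trim

CHROM = "chr1"


@dataclass
class SpikeSpec:
    """One designed variant and how it presents across the run."""

    name: str
    pos: int  # left-aligned anchored representation
    ref: str
    alt: str
    vaf: float
    carrier_frac: float  # fraction of physical (non-NTC) samples carrying it
    in_both_replicates: bool = True
    is_artefact: bool = False
    gmaf: float = 0.0
    consequence: str = "missense_variant"
    blacklisted: bool = False
    in_roi: bool = True
    in_control: bool = False
    messy_rep: bool = False  # emit an un-normalised VCF representation

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError(f"spike {self.name}: vaf must be in (0, 1]")


@dataclass
class SimSpec:
    """Deterministic run recipe; all randomness flows from ``seed``."""

    seed: int = 0
    ref_length: int = 12000
    n_amplicons: int = 24
    n_patients: int = 11
    include_control: bool = True
    include_ntc: bool = True
    mean_depth: int = 2297
    depth_dispersion: float = 0.12  # CV of per-amplicon read counts
    ntc_contamination: int = 0  # reads leaking into the NTC
    assay_id: str = "SOMA-1"
    run_id: str = "RUN001"
    history_runs: int = 10
    # None: derived from the run composition (amplicons x samples x depth)
    history_yield_mean: float | None = None
    history_yield_sd: float | None = None
    spikes: list[SpikeSpec] = field(default_factory=list)

    @property
    def n_run_samples(self) -> int:
        return 2 * self.n_patients + (1 if self.include_control else 0)

    def yield_distribution(self) -> tuple[float, float]:
        """Mean/sd of historical run yields; defaults track the simulated
        run's own expected total so the ±2 SD check is self-consistent."""
        mean = (self.history_yield_mean
                if self.history_yield_mean is not None
                else float(self.n_amplicons * self.n_run_samples * self.mean_depth))
        sd = (self.history_yield_sd
              if self.history_yield_sd is not None else 0.04 * mean)
        return mean, sd

    @classmethod
    def from_yaml(cls, path: str) -> "SimSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        spikes = [SpikeSpec(**s) for s in d.pop("spikes", [])]
        return cls(spikes=spikes, **d)


# ---------------------------------------------------------------------------
# reference + transcripts

BRAF_EXONS = ((2001, 2300), (2601, 2900), (3201, 3500))
KRAS_EXONS = ((6001, 6300), (6601, 6900), (7201, 7500))

#: regions the synthetic assay is validated for (1-based inclusive)
ROI_REGIONS = ((1990, 3600), (5990, 7600))


def make_reference(spec: SimSpec, out_dir: str | Path
                   ) -> tuple[Reference, list[Transcript]]:
    """Write ref.fa and transcripts.tsv; returns in-memory copies.

    The sequence embeds repeat tracts (a CA×10 dinucleotide run, a T×8
    homopolymer, an AG×8 run in the − strand gene) so indel normalisation
    has something to shift, and two reportable transcripts, one per strand.
    """
    if spec.ref_length < 1000:
        raise ValueError("ref_length must be >= 1000")
    rng = np.random.default_rng(spec.seed)
    seq = rng.choice(list("ACGT"), size=spec.ref_length)

    def put(pos: int, s: str) -> None:  # pos 1-based
        seq[pos - 1 : pos - 1 + len(s)] = list(s)

    put(2700, "T" + "CA" * 10)           # 2701-2720 CA tract, guarded left
    put(2721, "G")
    put(3300, "G" + "T" * 8 + "C")       # 3301-3308 homopolymer
    put(6700, "T" + "AG" * 8)            # 6701-6716 AG tract (KRAS, − strand)
    put(6717, "C")
    put(9490, "C" + "TG" * 6 + "A")      # intergenic repeat
    put(2051, "ATG")                     # BRAF CDS start codon
    put(2150, "GTG")                     # codon 34: Val
    put(2201, "CTG")                     # codon 51: Leu (CTG→CTA synonymous)
    put(2250, "C")
    put(2850, "T")
    put(3250, "A")
    put(9550, "G")

    sequence = "".join(seq)
    ref = Reference({CHROM: sequence})
    transcripts = [
        Transcript("BRAF", "TX.BRAF.1", CHROM, "+", BRAF_EXONS, 2051, 3450, True),
        Transcript("KRAS", "TX.KRAS.1", CHROM, "-", KRAS_EXONS, 6051, 7450, True),
    ]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "ref.fa", "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")
    with open(out / "transcripts.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene", "transcript_id", "chrom", "strand", "exon_starts",
                    "exon_ends", "cds_start", "cds_end", "reportable"])
        for t in transcripts:
            w.writerow([t.gene, t.transcript_id, t.chrom, t.strand,
                        ",".join(str(s) for s, _ in t.exons),
                        ",".join(str(e) for _, e in t.exons),
                        t.cds_start, t.cds_end, "1" if t.reportable else "0"])
    return ref, transcripts


def default_spikes(ref: Reference) -> list[SpikeSpec]:
    """The standard spike mix: true calls plus one exemplar per artefact class."""
    b = lambda p: ref.base(CHROM, p)  # noqa: E731
    alt_of = {"A": "G", "C": "T", "G": "A", "T": "C"}
    return [
        # true somatic hotspot, clean: expected pass
        SpikeSpec("braf_hotspot", 2151, "T", "A", vaf=0.35, carrier_frac=0.30),
        # common population SNP carried by most samples: gmaf + pnl
        SpikeSpec("common_snp", 2250, "C", alt_of[b(2250)] if b(2250) != "C" else "T",
                  vaf=0.50, carrier_frac=0.80, gmaf=0.12, in_control=True),
        # low-VAF PCR artefact, CA-repeat deletion, panel-recurrent: vaf + pnl
        SpikeSpec("repeat_del_artefact", 2700, "TCA", "T", vaf=0.04,
                  carrier_frac=0.50, is_artefact=True, messy_rep=True,
                  consequence="inframe_deletion"),
        # replicate singleton artefact: sin
        SpikeSpec("singleton_artefact", 2850, "T", "C", vaf=0.10,
                  carrier_frac=0.25, in_both_replicates=False, is_artefact=True),
        # known assay artefact on the blacklist: blk
        SpikeSpec("blacklisted_artefact", 3250, "A", "T", vaf=0.30,
                  carrier_frac=0.30, is_artefact=True, blacklisted=True),
        # real variant outside the validated region: oor (+ benign consequence)
        SpikeSpec("off_target", 9550, "G", "A", vaf=0.40, carrier_frac=0.25,
                  in_roi=False, consequence="intergenic_variant"),
        # synonymous change in BRAF: con
        SpikeSpec("synonymous", 2203, "G", "A", vaf=0.45, carrier_frac=0.25,
                  consequence="synonymous_variant", in_control=True),
        # AG-repeat insertion in the − strand gene, clean: expected pass
        SpikeSpec("kras_repeat_ins", 6700, "T", "TAG", vaf=0.25,
                  carrier_frac=0.30, consequence="inframe_insertion",
                  messy_rep=True),
    ]


# ---------------------------------------------------------------------------
# run simulation

MIN_VAF_DEFAULT = 0.08  # somatic assay


def expected_flags(spike: SpikeSpec, realized_frac: float, paired: bool) -> set[str]:
    """Flags this spike should attract, from its design parameters alone."""
    flags: set[str] = set()
    if spike.vaf < MIN_VAF_DEFAULT:
        flags.add("vaf")
    if spike.blacklisted:
        flags.add("blk")
    if not spike.in_roi:
        flags.add("oor")
    if spike.consequence in DEFAULT_BENIGN_CONSEQUENCES:
        flags.add("con")
    if spike.gmaf > 0.01:
        flags.add("gmaf")
    if realized_frac > 0.35:
        flags.add("pnl")
    if paired and not spike.in_both_replicates:
        flags.add("sin")
    if not flags:
        flags.add("pass")
    return flags


def _messy(v: GenomicVariant, ref: Reference) -> GenomicVariant:
    """An equivalent but un-normalised representation of the same edit.

    Indels inside repeat tracts are re-anchored one repeat unit to the right
    (validity checked by round-trip through left alignment) and a shared
    suffix base is padded on, so ingestion has real trimming/shifting to do.
    """
    pos, r, a = v.pos, v.ref, v.alt
    cand = None
    if len(r) > len(a) == 1:  # anchored deletion: slide anchor into the tract
        unit = len(r) - 1
        cand = GenomicVariant(
            CHROM, pos + unit,
            ref.fetch(CHROM, pos + unit, pos + unit + len(r) - 1),
            ref.base(CHROM, pos + unit), state="raw")
    elif len(a) > len(r) == 1:  # anchored insertion
        unit = len(a) - 1
        anchor = ref.base(CHROM, pos + unit)
        cand = GenomicVariant(CHROM, pos + unit, anchor, anchor + a[1:], state="raw")
    if cand is not None:
        try:
            if left_align(trim(cand), ref).key == left_align(trim(v), ref).key:
                pos, r, a = cand.pos, cand.ref, cand.alt
        except Exception:  # noqa: BLE001 - fall back to the canonical form
            pass
    pad = ref.base(CHROM, pos + len(r))
    return GenomicVariant(CHROM, pos, r + pad, a + pad, state="raw")


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


@dataclass
class RunBundle:
    """Paths and in-memory truth for one simulated run."""

    run_dir: Path
    ref: Reference
    transcripts: list[Transcript]
    sample_ids: list[str]  # VCF-bearing samples, replicate naming <base>_R1/_R2
    physical_samples: list[str]
    ntc_sample: str | None
    vcf_paths: dict[str, Path]
    counts_path: Path
    truth_path: Path
    annotation_path: Path
    assay_yaml: Path
    roi_bed: Path
    history_path: Path


def simulate_run(spec: SimSpec, out_dir: str | Path) -> RunBundle:
    """Generate a complete run directory.

    Layout: ref.fa, transcripts.tsv, roi.bed, assay.yaml, <sample>.vcf per
    sample, counts.tsv (amplicon × sample), truth.tsv (expected flags per
    call), synthdb.tsv (mock annotation source) and runhist.tsv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref, transcripts = make_reference(spec, out)
    rng = np.random.default_rng(spec.seed + 1)
    spikes = spec.spikes or default_spikes(ref)

    patients = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    physical = patients + (["NA12878"] if spec.include_control else [])
    sample_ids: list[str] = []
    for p in patients:
        sample_ids += [f"{p}_R1", f"{p}_R2"]
    if spec.include_control:
        sample_ids.append("NA12878")
    ntc = "NTC_1" if spec.include_ntc else None

    # deterministic carrier assignment per spike
    carriers: dict[str, set[str]] = {}
    realized: dict[str, float] = {}
    for sp in spikes:
        n = max(1, round(sp.carrier_frac * len(physical)))
        with_control = sp.in_control and spec.include_control
        n_patients_carrying = min(n - (1 if with_control else 0), len(patients))
        chosen = sorted(rng.choice(patients, size=n_patients_carrying, replace=False))
        if with_control:
            chosen.append("NA12878")
        carriers[sp.name] = set(chosen)
        realized[sp.name] = len(chosen) / len(physical)

    # canonical keys (left-aligned) for annotation/blacklist/truth
    canon: dict[str, GenomicVariant] = {}
    for sp in spikes:
        canon[sp.name] = left_align(trim(GenomicVariant(CHROM, sp.pos, sp.ref, sp.alt)), ref)

    # per-sample VCFs
    vcf_paths: dict[str, Path] = {}
    truth_rows: list[dict] = []
    sample_variants: dict[str, list[tuple[GenomicVariant, int, int]]] = {s: [] for s in sample_ids}
    for sp in spikes:
        for base in sorted(carriers[sp.name]):
            reps = ([f"{base}_R1", f"{base}_R2"] if base in patients else [base])
            present_in = reps if sp.in_both_replicates else reps[:1]
            for sid in present_in:
                depth = int(rng.poisson(spec.mean_depth))
                alt = int(rng.binomial(depth, sp.vaf))
                if alt == 0:
                    continue
                v = GenomicVariant(CHROM, sp.pos, sp.ref, sp.alt)
                rep = _messy(v, ref) if sp.messy_rep else v
                sample_variants[sid].append((rep, depth, alt))
            paired = base in patients
            truth_rows.append({
                "physical_sample": base,
                "spike": sp.name,
                "variant_key": canon[sp.name].key,
                "target_vaf": sp.vaf,
                "is_artefact": int(sp.is_artefact),
                "in_both_replicates": int(sp.in_both_replicates),
                "expected_flags": ",".join(sorted(
                    expected_flags(sp, realized[sp.name], paired))),
            })

    all_vcf_samples = sample_ids + ([ntc] if ntc else [])
    for sid in all_vcf_samples:
        path = out / f"{sid}.vcf"
        vcf_paths[sid] = path
        with open(path, "w") as fh:
            fh.write(VCF_HEADER.format(chrom=CHROM, length=spec.ref_length, sample=sid))
            for v, depth, alt in sorted(sample_variants.get(sid, []), key=lambda t: t[0].pos):
                fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t100\tPASS\t.\t"
                         f"GT:DP:AD\t0/1:{depth}:{depth - alt},{alt}\n")

    # amplicon × sample read counts
    amps = [f"AMP{i + 1:03d}" for i in range(spec.n_amplicons)]
    cols = all_vcf_samples
    counts_path = out / "counts.tsv"
    with open(counts_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["amplicon"] + cols)
        sd = spec.mean_depth * spec.depth_dispersion
        for amp in amps:
            row = []
            for s in cols:
                if ntc and s == ntc:
                    row.append(spec.ntc_contamination)
                else:
                    row.append(max(0, int(rng.normal(spec.mean_depth, sd))))
            w.writerow([amp] + row)

    # truth table
    truth_path = out / "truth.tsv"
    with open(truth_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, delimiter="\t", fieldnames=list(truth_rows[0]))
        w.writeheader()
        w.writerows(truth_rows)

    # mock annotation source
    annotation_path = out / "synthdb.tsv"
    with open(annotation_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["variant_key", "gene", "consequence", "gmaf", "dbsnp_id",
                    "cosmic_count", "protein_domain"])
        for sp in spikes:
            v = canon[sp.name]
            gene = ("BRAF" if 2001 <= v.pos <= 3500 else
                    "KRAS" if 6001 <= v.pos <= 7500 else "")
            dbsnp = f"rs{900000 + v.pos}" if sp.gmaf > 0 else ""
            cosmic = 0 if sp.is_artefact or sp.gmaf > 0 else 10 + v.pos % 50
            w.writerow([v.key, gene, sp.consequence, f"{sp.gmaf:.4f}", dbsnp,
                        cosmic, "kinase" if gene else ""])

    # region of interest + assay config
    roi_bed = out / "roi.bed"
    with open(roi_bed, "w") as fh:
        for s, e in ROI_REGIONS:
            fh.write(f"{CHROM}\t{s - 1}\t{e}\n")
    assay_yaml = out / "assay.yaml"
    blacklist = [canon[sp.name].key for sp in spikes if sp.blacklisted]
    with open(assay_yaml, "w") as fh:
        yaml.safe_dump({
            "assay_id": spec.assay_id,
            "sample_type": "somatic",
            "thresholds": {"min_vaf": 0.08, "min_total_depth": 100,
                           "min_alt_depth": 20, "max_gmaf": 0.01,
                           "max_panel_frac": 0.35},
            "blacklist": blacklist,
            "roi_bed": str(roi_bed),
        }, fh)

    history_path = simulate_history(spec, out / "runhist.tsv")
    return RunBundle(
        run_dir=out, ref=ref, transcripts=transcripts,
        sample_ids=sample_ids, physical_samples=physical, ntc_sample=ntc,
        vcf_paths=vcf_paths, counts_path=counts_path, truth_path=truth_path,
        annotation_path=annotation_path, assay_yaml=assay_yaml,
        roi_bed=roi_bed, history_path=history_path,
    )


def simulate_history(spec: SimSpec, path: str | Path) -> Path:
    """Historical run yields drawn from the configured normal distribution."""
    rng = np.random.default_rng(spec.seed + 2)
    mean, sd = spec.yield_distribution()
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["run_id", "assay_id", "total_reads", "date", "verdict"])
        for i in range(spec.history_runs):
            y = max(0.0, rng.normal(mean, sd))
            w.writerow([f"HIST{i + 1:03d}", spec.assay_id, int(y),
                        f"2016-{(i % 12) + 1:02d}-01", "passed"])
    return path


def simulate_key_series(n_runs: int, calls_per_run: int, distinct_frac: float,
                        novel_frac: float, seed: int = 0) -> list[list[str]]:
    """Per-run variant-key lists with controlled batch overlap.

    Each run has ``round(distinct_frac * calls_per_run)`` distinct keys, of
    which ``round(novel_frac * n_distinct)`` are novel (never seen in an
    earlier run) — except the first run, where every key is necessarily
    novel.  Used to exercise the annotation cache's workload accounting.
    """
    rng = np.random.default_rng(seed)
    pool: list[str] = []
    next_id = 0
    runs: list[list[str]] = []
    for r in range(n_runs):
        n_distinct = max(1, round(distinct_frac * calls_per_run))
        n_new = n_distinct if r == 0 else max(0, round(novel_frac * n_distinct))
        n_new = min(n_new, n_distinct)
        new_keys = [f"chr1:{1000 + next_id + i}:A:G" for i in range(n_new)]
        next_id += n_new
        n_old = n_distinct - n_new
        old_keys = list(rng.choice(pool, size=n_old, replace=False)) if n_old else []
        keys = new_keys + old_keys
        # every distinct key appears at least once; pad to calls_per_run
        calls = keys + list(rng.choice(keys, size=calls_per_run - len(keys)))
        rng.shuffle(calls)
        runs.append([str(k) for k in calls])
        pool.extend(new_keys)
    return runs


def read_truth(path: str | Path) -> list[dict]:
    with open(path) as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    for r in rows:
        r["target_vaf"] = float(r["target_vaf"])
        r["is_artefact"] = bool(int(r["is_artefact"]))
        r["in_both_replicates"] = bool(int(r["in_both_replicates"]))
        r["expected_flags"] = set(r["expected_flags"].split(","))
    return rows
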