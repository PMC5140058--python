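"""Synthetic paired-biopsy tumor-exome cohort generator.

Emulates the data regime of a deep-exome trial cohort: per patient a clonal
tree with per-sample cancer cell fractions (CCF) for a pre-treatment and a
post-treatment biopsy, mutation spectra drawn from a mutational-signature
mixture, allele-specific arm-level copy-number profiles with optional
whole-genome doubling, sample purity drawn from a configurable range, and
binomial read sampling at exome depths. Each sample's truth set is pushed
through four pseudo-callers with independent per-caller false-negative and
false-positive errors, yielding one VCF per caller per sample, so that the
multi-caller consensus rules downstream are exercised against known truth.

The pseudo-callers are: ``mutect`` and ``strelka`` (SNVs only), ``varscan``
(SNVs and indels), ``pindel`` (indels only). The expected variant allele
fraction of a mutation with multiplicity ``m`` and cancer cell fraction
``ccf`` on a segment with total tumor copy number ``cnt`` in a sample of
purity ``rho`` is::

    vaf = rho * m * ccf / (rho * cnt + 2 * (1 - rho))

and alt read counts are Binomial(depth, vaf) at Poisson-distributed depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import contexts
from .copy_number import AlleleSegment
from .errors import ConfigError
from .signatures import synthetic_catalog

CALLERS = ("mutect", "strelka", "varscan", "pindel")
SNV_CALLERS = ("mutect", "strelka", "varscan")
INDEL_CALLERS = ("varscan", "pindel")
TIMEPOINTS = ("pre", "post")

DEFAULT_GENOME = [("chr1", 100_000_000, 40_000_000),
                  ("chr2", 100_000_000, 40_000_000),
                  ("chr3", 100_000_000, 40_000_000)]

#: Age-dominated (1A/1B) plus APOBEC (2/13) mixture with a minor flat
#: component, emulating an age+APOBEC dominated breast-tumor spectrum.
DEFAULT_SIGNATURE_WEIGHTS = {"1A": 0.35, "1B": 0.25, "2": 0.15, "13": 0.15, "3": 0.10}

#: Independent Bernoulli miss rate and false-positive rate per pseudo-caller
#: (false positives are drawn Poisson with mean fp_rate x true variants).
DEFAULT_CALLER_ERROR = {
    "mutect": (0.05, 0.02),
    "strelka": (0.08, 0.03),
    "varscan": (0.12, 0.05),
    "pindel": (0.10, 0.04),
}


@dataclass
class Clone:
    clone_id: int
    parent_id: int | None
    ccf: dict  # timepoint -> CCF in [0, 1]
    n_mutations: int


@dataclass
class CloneTree:
    """A rooted clone tree with per-sample CCFs.

    Invariants: exactly one root with CCF 1.0 wherever the tumor is present;
    every child's CCF never exceeds its parent's in any sample; ids unique
    and parent references acyclic.
    """

    clones: list[Clone]

    def validate(self) -> None:
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ConfigError("clone ids not unique")
        roots = [c for c in self.clones if c.parent_id is None]
        if len(roots) != 1:
            raise ConfigError("clone tree must have exactly one root")
        by_id = {c.clone_id: c for c in self.clones}
        for tp in TIMEPOINTS:
            if roots[0].ccf[tp] != 1.0:
                raise ConfigError(f"root CCF must be 1.0 in sample {tp}")
        for c in self.clones:
            if c.parent_id is None:
                continue
            seen = {c.clone_id}
            p = c.parent_id
            while p is not None:
                if p in seen:
                    raise ConfigError("cycle in clone parent references")
                seen.add(p)
                parent = by_id.get(p)
                if parent is None:
                    raise ConfigError(f"unknown parent clone {p}")
                p = parent.parent_id
            parent = by_id[c.parent_id]
            for tp in TIMEPOINTS:
                if c.ccf[tp] > parent.ccf[tp] + 1e-12:
                    raise ConfigError(
                        f"clone {c.clone_id} CCF exceeds parent in sample {tp}"
                    )


@dataclass
class SimulationConfig:
    """Parameters of a simulated cohort.

    ``evolution_modes`` may list one of {branched, clonal_shift, stable} per
    patient; by default branched evolution is planted in eight of every nine
    patients and a pure clonal shift in the ninth. ``purity_range`` defaults
    to 0.2-0.9 (no per-patient purity values are published for the cohort
    this emulates, so the range is an assumption).
    """

    n_patients: int = 6
    genome: list = field(default_factory=lambda: list(DEFAULT_GENOME))
    purity_range: tuple = (0.2, 0.9)
    depth_mean: float = 400.0
    signature_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURE_WEIGHTS))
    wgd_probability: float = 0.7
    evolution_modes: list | None = None
    caller_error: dict = field(default_factory=lambda: dict(DEFAULT_CALLER_ERROR))
    truncal_mutations_mean: float = 70.0
    subclone_mutations_mean: float = 25.0
    indel_fraction: float = 0.05
    arm_aberration_rate: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        for name, length, cen in self.genome:
            if not (0 < cen < length):
                raise ConfigError(
                    f"genome: centromere must lie inside chromosome {name}")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError("purity_range must satisfy 0 < lo <= hi <= 1")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        total = sum(self.signature_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"signature_weights must sum to 1 (got {total})")
        if not (0 <= self.wgd_probability <= 1):
            raise ConfigError("wgd_probability must be in [0,1]")
        if not (0 <= self.indel_fraction <= 1):
            raise ConfigError("indel_fraction must be in [0,1]")
        if not (0 <= self.arm_aberration_rate <= 1):
            raise ConfigError("arm_aberration_rate must be in [0,1]")
        for caller, (fnr, fpr) in self.caller_error.items():
            if not (0 <= fnr <= 1 and 0 <= fpr <= 1):
                raise ConfigError(f"caller_error[{caller}] rates must be in [0,1]")
        if self.evolution_modes is not None:
            if len(self.evolution_modes) != self.n_patients:
                raise ConfigError("evolution_modes length must equal n_patients")
            for m in self.evolution_modes:
                if m not in ("branched", "clonal_shift", "stable"):
                    raise ConfigError(f"evolution_modes: unknown mode {m!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        if "genome" in kwargs:
            kwargs["genome"] = [tuple(g) for g in kwargs["genome"]]
        if "purity_range" in kwargs:
            kwargs["purity_range"] = tuple(kwargs["purity_range"])
        if "caller_error" in kwargs:
            kwargs["caller_error"] = {
                k: tuple(v) for k, v in kwargs["caller_error"].items()}
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class TruthMutation:
    chromosome: str
    position: int
    ref: str
    alt: str
    variant_class: str  # SNV | insertion | deletion
    clone_id: int
    substitution: str | None  # pyrimidine-strand, e.g. "C>T"; None for indels
    context: str | None  # 3-base pyrimidine-normalized context
    multiplicity: int

    @property
    def key(self):
        return (self.chromosome, self.position, self.ref, self.alt)


@dataclass
class FalsePositive:
    chromosome: str
    position: int
    ref: str
    alt: str
    variant_class: str
    alt_depth: int
    depth: int


@dataclass
class SampleTruth:
    sample: str
    patient: str
    timepoint: str
    purity: float
    ploidy: float
    wgd: bool
    segments: list
    reads: dict  # mutation key -> (alt_depth, depth); only mutations with CCF>0
    calls: dict  # caller -> set of mutation keys called
    false_positives: dict  # caller -> list[FalsePositive]


@dataclass
class PatientTruth:
    patient: str
    tree: CloneTree
    evolution_mode: str
    mutations: list  # TruthMutation


@dataclass
class TruthBundle:
    config: SimulationConfig
    patients: list
    samples: list  # SampleTruth, ordered patient-major then pre/post


def expected_vaf(purity: float, cnt: int, m: int, ccf: float) -> float:
    """Expected variant allele fraction under the standard admixture model."""
    denom = purity * cnt + 2.0 * (1.0 - purity)
    if denom <= 0:
        return 0.0
    return min(purity * m * ccf / denom, 1.0)


def _make_tree(mode: str, rng: np.random.Generator, cfg: SimulationConfig) -> CloneTree:
    def n_mut(mean):
        return int(rng.poisson(mean)) + 1

    root = Clone(0, None, {"pre": 1.0, "post": 1.0}, n_mut(cfg.truncal_mutations_mean))
    clones = [root]
    if mode == "stable":
        a = float(rng.uniform(0.35, 0.65))
        b = float(rng.uniform(0.1, min(a * 0.8, 1.0 - a)))
        clones.append(Clone(1, 0, {"pre": a, "post": a}, n_mut(cfg.subclone_mutations_mean)))
        clones.append(Clone(2, 0, {"pre": b, "post": b}, n_mut(cfg.subclone_mutations_mean)))
    elif mode == "branched":
        # one subclone is eliminated by treatment, a new one emerges, and a
        # third persists with only drift
        lost = float(rng.uniform(0.25, 0.5))
        new = float(rng.uniform(0.25, 0.5))
        keep_pre = float(rng.uniform(0.1, min(0.35, 1.0 - lost)))
        keep_post = min(keep_pre + float(rng.uniform(-0.05, 0.05)), 1.0 - new)
        keep_post = max(keep_post, 0.02)
        clones.append(Clone(1, 0, {"pre": lost, "post": 0.0}, n_mut(cfg.subclone_mutations_mean)))
        clones.append(Clone(2, 0, {"pre": 0.0, "post": new}, n_mut(cfg.subclone_mutations_mean)))
        clones.append(Clone(3, 0, {"pre": keep_pre, "post": keep_post}, n_mut(cfg.subclone_mutations_mean)))
    elif mode == "clonal_shift":
        # two subclones swap dominance without appearing or disappearing,
        # emulating treatment-driven expansion of minor subclones
        a_pre = float(rng.uniform(0.02, 0.25))
        a_post = float(rng.uniform(a_pre + 0.2, 0.8))
        b_pre = float(rng.uniform(0.3, 1.0 - a_pre))
        b_post = float(rng.uniform(0.05, min(b_pre - 0.2, 1.0 - a_post)))
        clones.append(Clone(1, 0, {"pre": a_pre, "post": a_post}, n_mut(cfg.subclone_mutations_mean)))
        clones.append(Clone(2, 0, {"pre": b_pre, "post": b_post}, n_mut(cfg.subclone_mutations_mean)))
    else:  # pragma: no cover - guarded by config validation
        raise ConfigError(f"unknown evolution mode {mode!r}")
    tree = CloneTree(clones)
    tree.validate()
    return tree


def _sample_positions(rng, genome, n):
    """Uniform positions without replacement, chromosome picked by length."""
    lengths = np.array([g[1] for g in genome], dtype=float)
    probs = lengths / lengths.sum()
    out = []
    used = set()
    while len(out) < n:
        ci = int(rng.choice(len(genome), p=probs))
        # keep away from chromosome edges so flanks always exist
        pos = int(rng.integers(2, genome[ci][1] - 1))
        if (ci, pos) in used:
            continue
        used.add((ci, pos))
        out.append((genome[ci][0], pos))
    return out


_PURINE = {"C": "G", "T": "A"}


def _snv_alleles(rng, substitution, context):
    """Emit VCF ref/alt for a pyrimidine-strand substitution, flipping to the
    purine strand half the time (as real callers report either strand)."""
    ref, alt = substitution[0], substitution[2]
    if rng.random() < 0.5:
        return contexts.revcomp(ref), contexts.revcomp(alt)
    return ref, alt


def _indel_alleles(rng):
    base = "ACGT"[int(rng.integers(0, 4))]
    ins = "ACGT"[int(rng.integers(0, 4))]
    if rng.random() < 0.5:
        return base, base + ins, "insertion"
    return base + ins, base, "deletion"


def _make_segments(rng, cfg, wgd):
    """Arm-level allele-specific segments; returns (segments, ploidy)."""
    base = (2, 2) if wgd else (1, 1)
    segs = []
    for name, length, cen in cfg.genome:
        for (start, end) in ((1, cen), (cen + 1, length)):
            major, minor = base
            if rng.random() < cfg.arm_aberration_rate:
                if rng.random() < 0.5:
                    major += 1
                else:
                    minor = max(minor - 1, 0)
            segs.append(AlleleSegment(name, start, end, major, minor))
    total_len = sum(s.length for s in segs)
    ploidy = sum(s.total * s.length for s in segs) / total_len
    return segs, ploidy


def simulate_cohort(config: SimulationConfig) -> TruthBundle:
    """Simulate a full paired-biopsy cohort; deterministic given config+seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    catalog = synthetic_catalog()
    sig_ids = list(config.signature_weights)
    for sid in sig_ids:
        if sid not in catalog.signatures:
            raise ConfigError(f"signature_weights: unknown signature {sid!r}")
    weights = np.array([config.signature_weights[s] for s in sig_ids])
    mixture = np.zeros(96)
    for sid, w in zip(sig_ids, weights):
        mixture += w * catalog.signatures[sid]
    mixture = mixture / mixture.sum()

    patients = []
    samples = []
    for ip in range(config.n_patients):
        pid = f"P{ip + 1:03d}"
        if config.evolution_modes is not None:
            mode = config.evolution_modes[ip]
        else:
            mode = "branched" if ip % 9 != 8 else "clonal_shift"
        tree = _make_tree(mode, rng, config)
        n_total = sum(c.n_mutations for c in tree.clones)
        positions = _sample_positions(rng, config.genome, n_total)
        mutations = []
        i = 0
        for clone in tree.clones:
            for _ in range(clone.n_mutations):
                chrom, pos = positions[i]
                i += 1
                if rng.random() < config.indel_fraction:
                    ref, alt, vclass = _indel_alleles(rng)
                    mutations.append(TruthMutation(
                        chrom, pos, ref, alt, vclass, clone.clone_id,
                        None, None, 1))
                else:
                    bin_ = int(rng.choice(96, p=mixture))
                    sub, ctx = contexts.parse_label(contexts.CONTEXT_LABELS[bin_])
                    ref, alt = _snv_alleles(rng, sub, ctx)
                    mutations.append(TruthMutation(
                        chrom, pos, ref, alt, "SNV", clone.clone_id,
                        sub, ctx, 1))
        patients.append(PatientTruth(pid, tree, mode, mutations))

        wgd = bool(rng.random() < config.wgd_probability)
        ccf_by_clone = {c.clone_id: c.ccf for c in tree.clones}
        # doubled genomes carry truncal mutations on both copies half the
        # time (mutation predates the doubling); a property of the mutation,
        # shared by both timepoints
        mult = {}
        for mut in mutations:
            m = 1
            if wgd and mut.clone_id == 0 and mut.variant_class == "SNV":
                m = 2 if rng.random() < 0.5 else 1
            mult[mut.key] = m
            mut.multiplicity = m
        for tp in TIMEPOINTS:
            sample = f"{pid}_{tp}"
            segs, ploidy = _make_segments(rng, config, wgd)
            purity = float(rng.uniform(*config.purity_range))
            seg_of = _segment_lookup(segs)
            reads = {}
            for mut in mutations:
                ccf = ccf_by_clone[mut.clone_id][tp]
                if ccf <= 0:
                    continue
                seg = seg_of(mut.chromosome, mut.position)
                m = min(mult[mut.key], max(1, seg.major))
                vaf = expected_vaf(purity, seg.total, m, ccf)
                depth = max(int(rng.poisson(config.depth_mean)), 1)
                alt_reads = int(rng.binomial(depth, vaf))
                reads[mut.key] = (alt_reads, depth)
            calls = {}
            fps = {}
            for caller in CALLERS:
                fnr, fp_rate = config.caller_error.get(caller, (0.0, 0.0))
                callable_keys = [
                    mut.key for mut in mutations
                    if mut.key in reads and _caller_handles(caller, mut.variant_class)
                ]
                kept = {k for k in callable_keys if rng.random() >= fnr}
                calls[caller] = kept
                n_fp = int(rng.poisson(fp_rate * len(callable_keys)))
                fp_list = []
                for (chrom, pos) in _sample_positions(rng, config.genome, n_fp):
                    if caller == "pindel":
                        ref, alt, vclass = _indel_alleles(rng)
                    else:
                        ref = "ACGT"[int(rng.integers(0, 4))]
                        alt = rng.choice([b for b in "ACGT" if b != ref])
                        vclass = "SNV"
                    depth = max(int(rng.poisson(config.depth_mean)), 1)
                    alt_reads = max(int(rng.binomial(depth, 0.08)), 1)
                    fp_list.append(FalsePositive(chrom, pos, ref, str(alt),
                                                 vclass, alt_reads, depth))
                fps[caller] = fp_list
            samples.append(SampleTruth(sample, pid, tp, purity, ploidy, wgd,
                                       segs, reads, calls, fps))
    return TruthBundle(config, patients, samples)


def _caller_handles(caller: str, variant_class: str) -> bool:
    if variant_class == "SNV":
        return caller in SNV_CALLERS
    return caller in INDEL_CALLERS


def _segment_lookup(segments):
    by_chrom = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)

    def lookup(chrom, pos):
        for seg in by_chrom.get(chrom, ()):
            if seg.start <= pos <= seg.end:
                return seg
        raise KeyError(f"no segment covering {chrom}:{pos}")

    return lookup


# ---------------------------------------------------------------------------
# fixture writing

_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
"""


def _write_vcf(path: Path, genome, records):
    """records: iterable of (chrom, pos, ref, alt, alt_depth, depth)."""
    contigs = "".join(f"##contig=<ID={name},length={length}>\n"
                      for name, length, _ in genome)
    order = {name: i for i, (name, _, _) in enumerate(genome)}
    lines = [_VCF_HEADER.format(contigs=contigs)]
    for chrom, pos, ref, alt, ad, dp in sorted(
            records, key=lambda r: (order.get(r[0], 99), r[1], r[2], r[3])):
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
                     f"AD:DP\t{dp - ad},{ad}:{dp}\n")
    path.write_text("".join(lines))


def write_fixture(bundle: TruthBundle, directory) -> dict:
    """Write VCFs, segment/purity tables and truth tables; returns the manifest.

    Layout: ``<dir>/<sample>/<caller>.vcf`` (4 per sample), plus
    ``segments.tsv``, ``purity_ploidy.tsv``, ``truth/*.tsv`` and
    ``manifest.json``.
    """
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    genome = bundle.config.genome
    mut_by_patient = {p.patient: {m.key: m for m in p.mutations}
                      for p in bundle.patients}
    manifest = {"seed": bundle.config.seed,
                "config": _config_to_jsonable(bundle.config),
                "samples": []}
    seg_lines = ["sample\tchrom\tstart\tend\tnMajor\tnMinor\n"]
    pp_lines = ["sample\tpurity\tploidy\n"]
    call_lines = ["sample\tcaller\tchrom\tpos\tref\talt\tis_false_positive\talt_depth\tdepth\n"]
    for s in bundle.samples:
        sdir = root / s.sample
        sdir.mkdir(exist_ok=True)
        entry = {"sample": s.sample, "patient": s.patient, "timepoint": s.timepoint,
                 "purity": s.purity, "ploidy": s.ploidy, "wgd": s.wgd,
                 "n_true_variants": len(s.reads), "vcfs": {}, "caller_counts": {}}
        for caller in CALLERS:
            records = []
            for key in sorted(s.calls[caller]):
                chrom, pos, ref, alt = key
                ad, dp = s.reads[key]
                records.append((chrom, pos, ref, alt, ad, dp))
                call_lines.append(f"{s.sample}\t{caller}\t{chrom}\t{pos}\t{ref}\t{alt}\t0\t{ad}\t{dp}\n")
            for fp in s.false_positives[caller]:
                records.append((fp.chromosome, fp.position, fp.ref, fp.alt,
                                fp.alt_depth, fp.depth))
                call_lines.append(f"{s.sample}\t{caller}\t{fp.chromosome}\t{fp.position}\t"
                                  f"{fp.ref}\t{fp.alt}\t1\t{fp.alt_depth}\t{fp.depth}\n")
            vcf_path = sdir / f"{caller}.vcf"
            _write_vcf(vcf_path, genome, records)
            entry["vcfs"][caller] = str(vcf_path.relative_to(root))
            entry["caller_counts"][caller] = len(records)
        for seg in s.segments:
            seg_lines.append(f"{s.sample}\t{seg.chromosome}\t{seg.start}\t{seg.end}\t"
                             f"{seg.major}\t{seg.minor}\n")
        pp_lines.append(f"{s.sample}\t{s.purity:.6f}\t{s.ploidy:.6f}\n")
        manifest["samples"].append(entry)
    (root / "segments.tsv").write_text("".join(seg_lines))
    (root / "purity_ploidy.tsv").write_text("".join(pp_lines))
    tdir = root / "truth"
    tdir.mkdir(exist_ok=True)
    mut_lines = ["patient\tchrom\tpos\tref\talt\tclass\tclone\tsubstitution\tcontext\tmultiplicity\n"]
    for p in bundle.patients:
        for m in p.mutations:
            mut_lines.append(f"{p.patient}\t{m.chromosome}\t{m.position}\t{m.ref}\t{m.alt}\t"
                             f"{m.variant_class}\t{m.clone_id}\t{m.substitution or '.'}\t"
                             f"{m.context or '.'}\t{m.multiplicity}\n")
    (tdir / "truth_mutations.tsv").write_text("".join(mut_lines))
    clone_lines = ["patient\tclone\tparent\tccf_pre\tccf_post\tn_mutations\tmode\n"]
    for p in bundle.patients:
        for c in p.tree.clones:
            parent = "." if c.parent_id is None else str(c.parent_id)
            clone_lines.append(f"{p.patient}\t{c.clone_id}\t{parent}\t{c.ccf['pre']:.4f}\t"
                               f"{c.ccf['post']:.4f}\t{c.n_mutations}\t{p.evolution_mode}\n")
    (tdir / "truth_clones.tsv").write_text("".join(clone_lines))
    (tdir / "truth_calls.tsv").write_text("".join(call_lines))
    manifest["files"] = ["segments.tsv", "purity_ploidy.tsv",
                         "truth/truth_mutations.tsv", "truth/truth_clones.tsv",
                         "truth/truth_calls.tsv"]
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_to_jsonable(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["genome"] = [list(g) for g in d["genome"]]
    d["purity_range"] = list(d["purity_range"])
    d["caller_error"] = {k: list(v) for k, v in d["caller_error"].items()}
    return d
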