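"""Ploidy-relative copy-number classification, wGII, and the genome-doubling test.

Allele-specific segmented copy number (major/minor integer copies per
interval) together with sample purity and mean ploidy drive three analyses:

* classification of each segment as amplification / gain / neutral / loss on
  the log2 scale relative to sample mean ploidy, with cutoffs at
  log2(4/2), log2(2.5/2) and log2(1.5/2);
* the weighted genomic instability index (wGII): for each autosome the
  base-pair fraction whose total copy number deviates from rounded ploidy,
  averaged unweighted across autosomes so large chromosomes do not dominate;
* a Monte-Carlo whole-genome-doubling (WGD) test: the sample is reduced to a
  chromosome-arm profile of major/minor copies; the observed number of
  unit aberrations relative to diploid (Ns) and the empirical gain/loss step
  probabilities (Ps) parameterize a null in which Ns sequential unit steps
  are applied to a diploid profile; the p-value is the fraction of
  simulations whose proportion of arms with major copy >= 2 exceeds the
  observed proportion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DomainError

logger = logging.getLogger(__name__)

LOG2_AMP = math.log2(4 / 2)
LOG2_GAIN = math.log2(2.5 / 2)
LOG2_LOSS = math.log2(1.5 / 2)


@dataclass(frozen=True)
class AlleleSegment:
    """A genomic interval with integer major/minor allele copy numbers.

    Coordinates are 1-based inclusive.
    """

    chromosome: str
    start: int
    end: int
    major: int
    minor: int

    def __post_init__(self):
        if self.start > self.end:
            raise DomainError(f"segment start > end: {self}")
        if not (self.major >= self.minor >= 0):
            raise DomainError(f"segment requires major >= minor >= 0: {self}")

    @property
    def total(self) -> int:
        return self.major + self.minor

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SamplePurityPloidy:
    sample: str
    purity: float
    ploidy: float

    def __post_init__(self):
        if not (0 < self.purity <= 1):
            raise DomainError(f"purity must be in (0,1]: {self.purity}")
        if self.ploidy <= 0:
            raise DomainError(f"ploidy must be positive: {self.ploidy}")


@dataclass(frozen=True)
class SCNACall:
    segment: AlleleSegment
    log2_ratio: float
    scna_class: str  # amplification | gain | neutral | loss


@dataclass
class ArmProfile:
    """Major/minor copy numbers at chromosome-arm resolution.

    ``n_aberrations`` (Ns) counts unit copy-number steps away from the
    diploid (1,1) state summed over arms and alleles; ``p_gain``/``p_loss``
    (Ps) are the fractions of those steps that were gains and losses.
    """

    arms: list[tuple[str, int, int]]  # (arm label, major, minor)
    n_aberrations: int = field(init=False)
    p_gain: float = field(init=False)
    p_loss: float = field(init=False)

    def __post_init__(self):
        gain = sum(max(m - 1, 0) + max(n - 1, 0) for _, m, n in self.arms)
        loss = sum(max(1 - m, 0) + max(1 - n, 0) for _, m, n in self.arms)
        self.n_aberrations = gain + loss
        if self.n_aberrations > 0:
            self.p_gain = gain / self.n_aberrations
            self.p_loss = loss / self.n_aberrations
        else:
            self.p_gain = 0.0
            self.p_loss = 0.0

    @property
    def observed_doubled_fraction(self) -> float:
        """Fraction of arms whose major allele copy number is >= 2."""
        if not self.arms:
            return 0.0
        return sum(1 for _, m, _ in self.arms if m >= 2) / len(self.arms)


@dataclass(frozen=True)
class WGDResult:
    observed_fraction: float
    p_value: float
    n_simulations: int
    doubled: bool


def classify_segments(
    segments: list[AlleleSegment], purity_ploidy: SamplePurityPloidy
) -> list[SCNACall]:
    """Classify each segment relative to sample mean ploidy.

    The segment's total copy number is divided by ploidy and log2
    transformed; amplification at ratio >= log2(4/2), gain on
    [log2(2.5/2), log2(4/2)), loss at <= log2(1.5/2), neutral in the open
    middle band. Zero total copy number maps to -inf, i.e. loss.
    """
    psi = purity_ploidy.ploidy
    calls = []
    for seg in segments:
        r = math.log2(seg.total / psi) if seg.total > 0 else -math.inf
        if r >= LOG2_AMP:
            cls = "amplification"
        elif r >= LOG2_GAIN:
            cls = "gain"
        elif r <= LOG2_LOSS:
            cls = "loss"
        else:
            cls = "neutral"
        calls.append(SCNACall(seg, r, cls))
    return calls


def wgii(
    segments: list[AlleleSegment],
    purity_ploidy: SamplePurityPloidy,
    autosomes: list[str] | None = None,
) -> float:
    """Weighted genomic instability index.

    Per autosome: the fraction of covered base-pairs in segments whose total
    copy number differs from round(ploidy); wGII is the unweighted mean of
    those fractions over autosomes with at least one segment. ``autosomes``
    restricts which chromosomes count (default: every chromosome present,
    which suits synthetic genomes; pass the 22 human autosome labels for
    real data).
    """
    if not segments:
        raise DomainError("wGII undefined: no segments provided")
    target = int(math.floor(purity_ploidy.ploidy + 0.5))
    by_chrom: dict[str, list[AlleleSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    chroms = autosomes if autosomes is not None else sorted(by_chrom)
    fractions = []
    for chrom in chroms:
        segs = by_chrom.get(chrom)
        if not segs:
            continue
        total_len = sum(s.length for s in segs)
        aberrant_len = sum(s.length for s in segs if s.total != target)
        fractions.append(aberrant_len / total_len)
    if not fractions:
        raise DomainError("wGII undefined: no segments on requested autosomes")
    return float(np.mean(fractions))


def load_arm_table(path=None) -> pd.DataFrame:
    """Load a chromosome-arm table (chrom, arm, start, end; 1-based inclusive).

    With no path, returns the packaged hg19-like 39-arm table (acrocentric
    short arms 13p/14p/15p/21p/22p excluded, as is standard for arm-level
    analyses).
    """
    if path is None:
        ref = resources.files("ibcpipe.data").joinpath("hg19_arms.tsv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def arm_table_for_genome(genome: list[tuple[str, int, int]]) -> pd.DataFrame:
    """Build a two-arm-per-chromosome table from (name, length, centromere)."""
    rows = []
    for name, length, cen in genome:
        rows.append({"chrom": name, "arm": f"{name}p", "start": 1, "end": cen})
        rows.append({"chrom": name, "arm": f"{name}q", "start": cen + 1, "end": length})
    return pd.DataFrame(rows)


def arm_profile(segments: list[AlleleSegment], arm_table: pd.DataFrame) -> ArmProfile:
    """Reduce segments to arm-level major/minor copies.

    Each arm takes the length-weighted modal (most-covered) (major, minor)
    pair among overlapping segments; arms with no overlap are omitted with a
    warning.
    """
    arms = []
    for row in arm_table.itertuples(index=False):
        cover: dict[tuple[int, int], int] = {}
        for seg in segments:
            if seg.chromosome != row.chrom:
                continue
            lo = max(seg.start, row.start)
            hi = min(seg.end, row.end)
            if lo <= hi:
                key = (seg.major, seg.minor)
                cover[key] = cover.get(key, 0) + (hi - lo + 1)
        if not cover:
            logger.warning("arm %s has no overlapping segment; omitted", row.arm)
            continue
        # deterministic tie-break: longer coverage first, then lower copies
        best = max(cover.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))
        arms.append((row.arm, best[0][0], best[0][1]))
    return ArmProfile(arms)


def genome_doubling_test(
    profile: ArmProfile,
    n_simulations: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> WGDResult:
    """Monte-Carlo test for whole-genome doubling.

    Each simulation starts every arm at (1,1) and applies Ns sequential unit
    steps; each step picks an arm uniformly, an allele uniformly, and a
    direction (gain/loss) with the observed step probabilities Ps. A loss on
    an allele already at 0 copies is redrawn. The p-value is the fraction of
    simulations whose proportion of arms with major copy >= 2 strictly
    exceeds the observed proportion. The sample is called doubled when the
    observed proportion is >= 0.5 and p < alpha.
    """
    if not profile.arms:
        raise DomainError("arm profile is empty")
    observed = profile.observed_doubled_fraction
    ns = profile.n_aberrations
    if ns == 0:
        return WGDResult(observed, 1.0, n_simulations, False)
    rng = np.random.default_rng(seed)
    n_arms = len(profile.arms)
    # allele copies: (n_simulations, n_arms, 2), all starting diploid
    copies = np.ones((n_simulations, n_arms, 2), dtype=np.int64)
    sims = np.arange(n_simulations)
    for _ in range(ns):
        pending = np.ones(n_simulations, dtype=bool)
        while pending.any():
            k = int(pending.sum())
            arm = rng.integers(0, n_arms, size=k)
            allele = rng.integers(0, 2, size=k)
            step = np.where(rng.random(k) < profile.p_gain, 1, -1)
            idx = sims[pending]
            cur = copies[idx, arm, allele]
            ok = (cur + step) >= 0
            copies[idx[ok], arm[ok], allele[ok]] = cur[ok] + step[ok]
            pending[idx[ok]] = False
    sim_fraction = (copies.max(axis=2) >= 2).mean(axis=1)
    p_value = float((sim_fraction > observed).sum() / n_simulations)
    doubled = bool(observed >= 0.5 and p_value < alpha)
    return WGDResult(observed, p_value, n_simulations, doubled)


def read_segments(path) -> dict[str, list[AlleleSegment]]:
    """Read a tab-delimited segment file (sample, chrom, start, end, nMajor, nMinor)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[AlleleSegment]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample), []).append(
            AlleleSegment(str(row.chrom), int(row.start), int(row.end), int(row.nMajor), int(row.nMinor))
        )
    return out


def read_purity_ploidy(path) -> dict[str, SamplePurityPloidy]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.sample): SamplePurityPloidy(str(r.sample), float(r.purity), float(r.ploidy))
        for r in df.itertuples(index=False)
    }
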