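"""Cancer cell fractions, Dirichlet-process clonal clustering, and
evolution-pattern classification for paired biopsies.

The mutation copy number of a variant with allele fraction ``vaf`` on a
segment of total tumor copy number ``cnt`` in a sample of purity ``rho``
is::

    nmut = vaf * (rho * cnt + 2 * (1 - rho)) / rho

The integer multiplicity ``m`` (copies bearing the mutation) is chosen from
{1, ..., max(1, major)} by maximizing the binomial likelihood of the
observed alt-read count under the expected VAF implied by each candidate,
with ties broken toward the smallest m; the cancer cell fraction is then
``ccf = min(nmut / m, 1)``.

Mutations from one patient's pre- and post-treatment samples are clustered
jointly with a Chinese-restaurant-process Gibbs sampler: cluster parameters
are per-sample CCFs phi on a discrete grid of 101 points in [0, 1], and the
emission for each mutation in each sample is Binomial(depth, vaf(m, phi)).
A point clustering is extracted from the posterior co-assignment matrix by
average-linkage clustering cut at 0.5; clusters with 3 or fewer SNVs are
excluded from reporting. Mutations absent from one sample are entered as
zero alt reads at that sample's median depth (absence treated as an
observation of zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .errors import DomainError
from .synthdata import expected_vaf

logger = logging.getLogger(__name__)

MIN_CLUSTER_SIZE = 4  # clusters with 3 or fewer SNVs are excluded

GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class CCFRecord:
    variant_key: tuple
    sample: str
    multiplicity: int
    mutation_copy_number: float
    ccf: float
    alt_depth: int
    total_depth: int
    total_cn: int
    major_cn: int
    purity: float


@dataclass
class CloneCluster:
    cluster_id: int
    members: list  # variant keys
    mean_ccf: dict  # sample label -> phi in [0, 1]
    size: int = field(init=False)

    def __post_init__(self):
        self.size = len(self.members)


@dataclass(frozen=True)
class EvolutionCall:
    patient: str
    pattern: str  # branched | clonal_shift | stable
    evidence: list  # (cluster_id, pre_ccf, post_ccf, event)


def compute_ccf(variant, segment, purity: float, sample: str = "sample") -> CCFRecord:
    """Compute multiplicity, mutation copy number and CCF for one variant.

    ``variant`` needs ``chromosome``, ``position``, ``alt_depth``,
    ``total_depth``; ``segment`` provides major/minor copies at the locus.
    """
    if not (0 < purity <= 1):
        raise DomainError(f"purity must be in (0,1]: {purity}")
    if not (segment.chromosome == variant.chromosome
            and segment.start <= variant.position <= segment.end):
        raise DomainError(
            f"variant {variant.chromosome}:{variant.position} outside segment")
    cnt = segment.total
    if cnt < 1:
        raise DomainError("total copy number at locus must be >= 1")
    vaf = variant.alt_depth / variant.total_depth if variant.total_depth else 0.0
    nmut = vaf * (purity * cnt + 2.0 * (1.0 - purity)) / purity
    best_m, best_ll = 1, -np.inf
    for m in range(1, max(1, segment.major) + 1):
        ccf_m = min(max(nmut / m, 1e-9), 1.0)
        p = expected_vaf(purity, cnt, m, ccf_m)
        p = min(max(p, 1e-12), 1 - 1e-12)
        ll = binom.logpmf(variant.alt_depth, variant.total_depth, p)
        if ll > best_ll + 1e-12:  # ties break to smallest m
            best_m, best_ll = m, ll
    ccf = min(nmut / best_m, 1.0)
    return CCFRecord(
        variant_key=(variant.chromosome, variant.position, variant.ref, variant.alt),
        sample=sample,
        multiplicity=best_m,
        mutation_copy_number=nmut,
        ccf=ccf,
        alt_depth=variant.alt_depth,
        total_depth=variant.total_depth,
        total_cn=cnt,
        major_cn=segment.major,
        purity=purity,
    )


def _log_binom_grid(records, samples):
    """Per-mutation per-sample log-likelihood over the phi grid.

    records: dict variant_key -> {sample: CCFRecord}. Returns
    (keys, ll) with ll shape (n_mut, n_samples, n_grid).
    """
    keys = sorted(records)
    n = len(keys)
    ll = np.zeros((n, len(samples), len(GRID)))
    for i, key in enumerate(keys):
        for j, s in enumerate(samples):
            rec = records[key][s]
            p = np.array([
                min(max(expected_vaf(rec.purity, rec.total_cn,
                                     rec.multiplicity, phi), 1e-9), 1 - 1e-9)
                for phi in GRID
            ])
            k, d = rec.alt_depth, rec.total_depth
            logc = gammaln(d + 1) - gammaln(k + 1) - gammaln(d - k + 1)
            ll[i, j] = logc + k * np.log(p) + (d - k) * np.log1p(-p)
    return keys, ll


def dp_cluster(
    records: dict,
    concentration: float = 1.0,
    iterations: int = 5000,
    burn_in: int = 2500,
    seed: int | None = None,
):
    """Cluster mutations across samples with a CRP Gibbs sampler.

    ``records`` maps variant key -> {sample label: CCFRecord}; every variant
    must carry a record for every sample (use zero alt reads for absence).
    Returns ``(retained, excluded)`` lists of :class:`CloneCluster`.
    Deterministic given ``seed``.
    """
    if not records:
        raise DomainError("no mutations to cluster")
    samples = sorted({s for recs in records.values() for s in recs})
    for key, recs in records.items():
        if set(recs) != set(samples):
            raise DomainError(f"variant {key} lacks a record in some sample")
    keys, ll = _log_binom_grid(records, samples)
    n = len(keys)
    if n < MIN_CLUSTER_SIZE:
        logger.warning("only %d mutations; all excluded from clustering", n)
        phi = {s: float(np.mean([records[k][s].ccf for k in keys])) for s in samples}
        return [], [CloneCluster(0, list(keys), phi)]
    rng = np.random.default_rng(seed)
    n_grid = len(GRID)
    # marginal likelihood of a singleton cluster: uniform prior over the grid
    log_marginal = (logsumexp(ll, axis=2) - np.log(n_grid)).sum(axis=1)

    assign = np.zeros(n, dtype=int)
    cluster_grid = {0: np.array([int(np.argmax(ll[:, j, :].sum(axis=0)))
                                 for j in range(len(samples))])}
    counts = {0: n}
    next_id = 1
    coassign = np.zeros((n, n))
    n_recorded = 0
    log_alpha = np.log(concentration)
    n_samples = len(samples)
    sample_idx = np.arange(n_samples)

    def draw(probs):
        # inverse-CDF draw; cheaper than rng.choice for small vectors
        return int(np.searchsorted(np.cumsum(probs), rng.random() * probs.sum()))

    for it in range(iterations):
        for i in range(n):
            c = assign[i]
            counts[c] -= 1
            if counts[c] == 0:
                del counts[c]
                del cluster_grid[c]
            cids = list(counts)
            # (K, n_samples) grid indices -> summed log-lik per cluster
            grid_mat = np.array([cluster_grid[cid] for cid in cids])
            logp = np.empty(len(cids) + 1)
            logp[:-1] = (np.log([counts[cid] for cid in cids])
                         + ll[i][sample_idx, grid_mat].sum(axis=1))
            logp[-1] = log_alpha + log_marginal[i]
            probs = np.exp(logp - logp.max())
            choice = draw(probs)
            if choice == len(cids):
                cid = next_id
                next_id += 1
                # draw the new cluster's phi from its single-member posterior
                grid_idx = np.empty(n_samples, dtype=int)
                for j in range(n_samples):
                    w = np.exp(ll[i, j] - ll[i, j].max())
                    grid_idx[j] = draw(w)
                cluster_grid[cid] = grid_idx
                counts[cid] = 1
            else:
                cid = cids[choice]
                counts[cid] += 1
            assign[i] = cid
        # update phi per cluster per sample from the member likelihoods
        for cid in counts:
            members = np.flatnonzero(assign == cid)
            w = ll[members].sum(axis=0)  # (n_samples, n_grid)
            w = np.exp(w - w.max(axis=1, keepdims=True))
            for j in range(n_samples):
                cluster_grid[cid][j] = draw(w[j])
        if it >= burn_in:
            same = assign[:, None] == assign[None, :]
            coassign += same
            n_recorded += 1
    coassign /= max(n_recorded, 1)

    # point clustering: average linkage on 1 - coassignment, cut at 0.5
    dist = 1.0 - coassign
    np.fill_diagonal(dist, 0.0)
    if n > 1:
        z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(z, t=0.5, criterion="distance")
    else:
        labels = np.array([1])

    retained, excluded = [], []
    for cid in sorted(set(labels)):
        members = [keys[i] for i in np.flatnonzero(labels == cid)]
        idx = np.flatnonzero(labels == cid)
        phi = {}
        for j, s in enumerate(samples):
            w = ll[idx, j, :].sum(axis=0)
            w = np.exp(w - logsumexp(w))
            phi[s] = float((GRID * w).sum())
        cluster = CloneCluster(int(cid), members, phi)
        (retained if cluster.size >= MIN_CLUSTER_SIZE else excluded).append(cluster)
    if not retained:
        logger.warning("no cluster reached the minimum size of %d", MIN_CLUSTER_SIZE)
    return retained, excluded


def classify_evolution(
    clusters: list,
    patient: str = "patient",
    pre_label: str = "pre",
    post_label: str = "post",
    presence_threshold: float = 0.02,
    shift_threshold: float = 0.20,
) -> EvolutionCall:
    """Classify the pre/post clonal dynamics of one patient.

    Per cluster: *new* if pre-CCF < presence_threshold <= post-CCF; *lost*
    for the reverse; *expanded*/*contracted* when |delta CCF| >=
    shift_threshold; otherwise *stable*. Pattern: *branched* when any
    cluster is new or lost; *clonal_shift* when none is but some expanded or
    contracted; *stable* otherwise.

    The presence threshold defaults to 0.02: a subclone observed at a CCF
    of 2% before treatment counts as present, so its later expansion is a
    shift in clonal structure rather than the appearance of a new clone.
    """
    if not clusters:
        raise DomainError("no retained clusters to classify")
    evidence = []
    any_new_lost = False
    any_shift = False
    for cl in clusters:
        if pre_label not in cl.mean_ccf or post_label not in cl.mean_ccf:
            raise DomainError(f"cluster {cl.cluster_id} lacks a sample CCF")
        pre, post = cl.mean_ccf[pre_label], cl.mean_ccf[post_label]
        if pre < presence_threshold <= post:
            event = "new"
            any_new_lost = True
        elif post < presence_threshold <= pre:
            event = "lost"
            any_new_lost = True
        elif post - pre >= shift_threshold:
            event = "expanded"
            any_shift = True
        elif pre - post >= shift_threshold:
            event = "contracted"
            any_shift = True
        else:
            event = "stable"
        evidence.append((cl.cluster_id, pre, post, event))
    if any_new_lost:
        pattern = "branched"
    elif any_shift:
        pattern = "clonal_shift"
    else:
        pattern = "stable"
    return EvolutionCall(patient, pattern, evidence)


def shared_mutation_fraction(pre_variants, post_variants) -> float:
    """|post intersect pre| / |post| over identically keyed variant sets."""
    pre_keys = {getattr(v, "key", v) for v in pre_variants}
    post_keys = {getattr(v, "key", v) for v in post_variants}
    if not post_keys:
        raise DomainError("post-treatment variant set is empty")
    return len(post_keys & pre_keys) / len(post_keys)


def records_for_pair(
    pre_variants, post_variants, pre_segments, post_segments,
    pre_purity: float, post_purity: float,
    pre_label: str = "pre", post_label: str = "post",
) -> dict:
    """Build the joint record map for :func:`dp_cluster` from two samples.

    Variants observed in only one sample get a zero-alt record at the other
    sample's median depth. Variants falling outside every segment in either
    sample are dropped with a warning.
    """
    from .copy_number import AlleleSegment  # noqa: F401  (typing aid)

    def find_segment(segments, chrom, pos):
        for seg in segments:
            if seg.chromosome == chrom and seg.start <= pos <= seg.end:
                return seg
        return None

    def median_depth(variants):
        depths = [v.total_depth for v in variants if v.total_depth > 0]
        return int(np.median(depths)) if depths else 100

    pre_by_key = {v.key: v for v in pre_variants}
    post_by_key = {v.key: v for v in post_variants}
    med_pre, med_post = median_depth(pre_variants), median_depth(post_variants)
    records = {}
    for key in sorted(set(pre_by_key) | set(post_by_key)):
        chrom, pos, ref, alt = key
        seg_pre = find_segment(pre_segments, chrom, pos)
        seg_post = find_segment(post_segments, chrom, pos)
        if seg_pre is None or seg_post is None:
            logger.warning("variant %s outside segments; excluded from clustering", key)
            continue
        pair = {}
        for label, by_key, seg, purity, med in (
            (pre_label, pre_by_key, seg_pre, pre_purity, med_pre),
            (post_label, post_by_key, seg_post, post_purity, med_post),
        ):
            v = by_key.get(key)
            if v is None:
                v = _AbsentVariant(chrom, pos, ref, alt, med)
            pair[label] = compute_ccf(v, seg, purity, sample=label)
        records[key] = pair
    return records


class _AbsentVariant:
    """Zero-alt observation standing in for a mutation undetected in one sample."""

    def __init__(self, chromosome, position, ref, alt, depth):
        self.chromosome = chromosome
        self.position = position
        self.ref = ref
        self.alt = alt
        self.alt_depth = 0
        self.total_depth = depth
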