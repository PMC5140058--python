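"""96-context mutation spectra and signature refitting.

A sample's single-nucleotide variants are tallied into the 96 trinucleotide
categories (pyrimidine-strand substitution x flanking bases) and expressed
as fractions. The refitting step finds a non-negative weighted combination
of a fixed signature catalog that most closely reconstructs the observed
fractions, by greedy forward selection: at each iteration the (signature,
weight) pair that most reduces the sum of squared differences between the
normalized reconstruction and the observed spectrum is chosen, the scalar
weight being located by golden-section search on [0, 1]; iteration stops
when the best achievable improvement falls below ``error_tolerance``.
Weights below ``weight_floor`` are then zeroed and the remainder
renormalized to sum to one. The floor (0.06) and tolerance (1e-3) follow
the published defaults of the standard refitting approach.

No exome/genome trinucleotide-abundance renormalization is applied unless
an abundance vector is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contexts import CONTEXT_LABELS, CONTEXT_INDEX, bin_index
from .errors import DomainError, FormatError


@dataclass
class MutationSpectrum:
    """Counts over the 96 mutation categories, in canonical label order."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise DomainError("spectrum must have 96 bins")
        if (self.counts < 0).any():
            raise DomainError("spectrum counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        t = self.total
        if t == 0:
            raise DomainError("empty spectrum has no fractions")
        return self.counts / t


@dataclass
class SignatureCatalog:
    """Named 96-vectors of context fractions, each summing to 1."""

    signatures: dict  # id -> np.ndarray of shape (96,)

    def __post_init__(self):
        for sid, vec in self.signatures.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (96,) or (vec < 0).any():
                raise FormatError(f"signature {sid}: not a non-negative 96-vector")
            if abs(vec.sum() - 1.0) > 1e-6:
                raise FormatError(f"signature {sid}: fractions sum to {vec.sum()}, not 1")
            self.signatures[sid] = vec

    @property
    def ids(self) -> list:
        return list(self.signatures)

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.signatures[s] for s in self.signatures])


@dataclass
class ExposureFit:
    weights: dict  # signature id -> weight in [0,1]; retained weights sum to 1
    reconstruction_error: float
    n_mutations: int


#: Reporting map from signature ids to etiology groups: signatures 1A/1B are
#: the age-related clock-like processes; 2 and 13 are APOBEC deaminase
#: activity. Used for aggregation only, never in the fit itself.
ETIOLOGY_GROUPS = {"age": ("1A", "1B"), "apobec": ("2", "13")}


def build_spectrum(variants) -> MutationSpectrum:
    """Tally SNVs carrying pyrimidine-normalized contexts into 96 bins.

    Indels and context-less variants are skipped (their count is recorded on
    the returned object as ``n_skipped``). Raises if nothing is usable.
    """
    counts = np.zeros(96)
    skipped = 0
    for v in variants:
        sub = getattr(v, "substitution", None)
        ctx = getattr(v, "context", None)
        if sub is None or ctx is None or getattr(v, "variant_class", "SNV") != "SNV":
            skipped += 1
            continue
        counts[bin_index(sub, ctx)] += 1
    if counts.sum() == 0:
        raise DomainError("no SNVs with trinucleotide context; spectrum is empty")
    spec = MutationSpectrum(counts)
    spec.n_skipped = skipped
    return spec


def spectrum_from_labels(labels) -> MutationSpectrum:
    """Build a spectrum from an iterable of ``A[C>T]G``-style labels."""
    counts = np.zeros(96)
    for lab in labels:
        counts[CONTEXT_INDEX[lab]] += 1
    return MutationSpectrum(counts)


def _golden_section(f, lo=0.0, hi=1.0, tol=1e-4):
    """Minimize a unimodal scalar function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = (a + b) / 2
    return x, f(x)


def refit(
    spectrum: MutationSpectrum,
    catalog: SignatureCatalog,
    weight_floor: float = 0.06,
    error_tolerance: float = 1e-3,
    abundance: np.ndarray | None = None,
) -> ExposureFit:
    """Greedy forward-selection refit of a spectrum against a catalog.

    ``abundance`` optionally rescales the observed fractions by relative
    trinucleotide abundance before fitting (off by default).
    """
    target = spectrum.fractions.copy()
    if abundance is not None:
        abundance = np.asarray(abundance, dtype=float)
        target = target * abundance
        target = target / target.sum()
    ids = catalog.ids
    sigs = catalog.matrix()

    weights = np.zeros(len(ids))

    def sse(w):
        total = w.sum()
        if total <= 0:
            return float(np.sum(target ** 2))
        recon = sigs @ (w / total)
        return float(np.sum((recon - target) ** 2))

    current = sse(weights)
    while True:
        best = None
        for j in range(len(ids)):
            def f(x, j=j):
                trial = weights.copy()
                trial[j] = x
                return sse(trial)
            x, fx = _golden_section(f)
            if best is None or fx < best[2]:
                best = (j, x, fx)
        j, x, fx = best
        if current - fx < error_tolerance:
            break
        weights[j] = x
        current = fx
    total = weights.sum()
    norm = weights / total if total > 0 else weights
    norm[norm < weight_floor] = 0.0
    if norm.sum() > 0:
        norm = norm / norm.sum()
    final_err = sse(norm)
    return ExposureFit(
        weights={sid: float(w) for sid, w in zip(ids, norm)},
        reconstruction_error=final_err,
        n_mutations=int(round(spectrum.total)),
    )


def aggregate_exposures(fit: ExposureFit) -> dict:
    """Collapse per-signature weights into age / APOBEC / other groups."""
    out = {g: 0.0 for g in ETIOLOGY_GROUPS}
    out["other"] = 0.0
    for sid, w in fit.weights.items():
        for group, members in ETIOLOGY_GROUPS.items():
            if sid in members:
                out[group] += w
                break
        else:
            out["other"] += w
    return out


# ---------------------------------------------------------------------------
# catalog construction and I/O

def synthetic_catalog(n_background: int = 23, seed: int = 20160101) -> SignatureCatalog:
    """A deterministic SYNTHETIC 27-signature catalog.

    This is a stand-in constructed in code, not the published catalog: the
    ids mirror the published naming (1A, 1B, 2-21, R1-R3, U1, U2 would be 27;
    here 1A, 1B, 2, 13 plus ``n_background`` numbered background signatures)
    and the four biologically anchored columns carry the canonical features:
    1A/1B concentrate C>T at NpCpG (spontaneous deamination, age-related);
    2 and 13 concentrate C>T and C>G respectively at TpCpN (APOBEC).
    Background columns are smooth Dirichlet draws from a fixed seed.
    """
    rng = np.random.default_rng(seed)
    sigs: dict[str, np.ndarray] = {}

    def sharp(pairs, peak_mass=0.75):
        vec = np.full(96, (1 - peak_mass) / 96)
        idx = [CONTEXT_INDEX[lab] for lab in pairs]
        vec[idx] += peak_mass / len(idx)
        return vec / vec.sum()

    cpg_ct = [f"{five}[C>T]G" for five in "ACGT"]
    sigs["1A"] = sharp(cpg_ct, 0.80)
    # 1B: clock-like C>T spread over all contexts rather than the CpG spike
    all_ct = [f"{f}[C>T]{t}" for f in "ACGT" for t in "ACGT"]
    sigs["1B"] = sharp(all_ct, 0.70)
    tpc = [f"T[C>T]{three}" for three in "ACT"]
    sigs["2"] = sharp(tpc, 0.78)
    tpc_cg = [f"T[C>G]{three}" for three in "ACT"]
    sigs["13"] = sharp(tpc_cg, 0.78)
    background_ids = [str(k) for k in range(3, 22) if k != 13] + ["R1", "R2", "R3", "U1", "U2"]
    for sid in background_ids[:n_background]:
        sigs[sid] = rng.dirichlet(np.full(96, 0.5))
    return SignatureCatalog(sigs)


def read_catalog(path) -> SignatureCatalog:
    """Read a tab-delimited catalog: first column context labels, one column
    per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CONTEXT_LABELS) - set(df.index)
    if missing:
        raise FormatError(f"catalog missing contexts, e.g. {sorted(missing)[:3]}")
    df = df.loc[list(CONTEXT_LABELS)]
    return SignatureCatalog({c: df[c].to_numpy() for c in df.columns})


def write_catalog(catalog: SignatureCatalog, path) -> None:
    df = pd.DataFrame(
        {sid: vec for sid, vec in catalog.signatures.items()},
        index=list(CONTEXT_LABELS),
    )
    df.index.name = "context"
    df.to_csv(path, sep="\t")


def write_spectrum(spectrum: MutationSpectrum, path, name: str = "sample") -> None:
    df = pd.DataFrame({name: spectrum.counts}, index=list(CONTEXT_LABELS))
    df.index.name = "context"
    df.to_csv(path, sep="\t")
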