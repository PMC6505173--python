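"""36-state diplotype hidden Markov model for Diversity Outbred genomes.

A DO genome is a mosaic of eight founder haplotypes.  At any autosomal locus
the hidden state is the unordered pair of founders carried by the two
chromosomes: 36 diplotypes (8 homozygous + 28 heterozygous).  Observations
are biallelic SNP calls (AA/AB/BB/missing); the founder strains' alleles at
each marker link diplotypes to SNP genotypes.

States are ordered lower-triangle row-wise over founders A..H:
AA, AB, BB, AC, BC, CC, ..., HH.  All serialization uses these labels.

The transition kernel is an exchangeable-founder exponential-mosaic
approximation: along each haplotype, founder-exchange points occur at
density ``a = n_gen_eff * 8/7`` per Morgan and the founder is redrawn
uniformly (self allowed) at each, so visible founder switches accumulate at
``n_gen_eff`` per Morgan.  The two haplotypes are independent (random
mating; the model is applied to autosomes only).  Inter-marker distances
pass through the configured map function (Carter-Falconer by default) to a
recombination fraction, which is floored to keep the chain irreducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_io import (
    ALLELE_NA,
    FOUNDER_LABELS,
    GENO_NA,
    N_FOUNDERS,
    FounderGenotypes,
    GeneticMap,
    GenotypeMatrix,
)
from .map_functions import MapFunctionSpec, interval_rf, map_expansion_rate

N_STATES = 36

#: (36, 2) array of founder index pairs (k, j) with k <= j, in state order.
STATE_PAIRS = np.array([(k, j) for j in range(N_FOUNDERS) for k in range(j + 1)])

STATE_LABELS = [FOUNDER_LABELS[k] + FOUNDER_LABELS[j] for k, j in STATE_PAIRS]

STATE_IS_HOM = STATE_PAIRS[:, 0] == STATE_PAIRS[:, 1]

#: Stationary distribution: uniform over ordered founder pairs, i.e. 1/64 for
#: each homozygous state and 2/64 for each heterozygous state.
STATIONARY = np.where(STATE_IS_HOM, 1.0 / 64.0, 2.0 / 64.0)


def state_index(f1: int, f2: int) -> int:
    """Index of the unordered diplotype state for founder indices ``f1, f2``."""
    k, j = sorted((int(f1), int(f2)))
    if not 0 <= k <= j < N_FOUNDERS:
        raise ValueError("founder indices must be in 0..7")
    return j * (j + 1) // 2 + k


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

#: Effective switch densities (visible founder switches per Morgan per
#: haplotype) for the two DO outbreeding generations of the motivating
#: dataset, calibrated so that simulated genome-wide crossover counts on the
#: default synthetic genome bracket the observed generation averages.
DO_GEN_EFF_ANCHORS = {8: 7.6, 11: 9.0}


def n_gen_eff_for(generation) -> float:
    """Effective switch density for a DO outbreeding generation.

    Linear in generation through the calibrated anchors for generations 8
    and 11; clipped below at a small positive value.
    """
    g = float(generation)
    lo, hi = DO_GEN_EFF_ANCHORS[8], DO_GEN_EFF_ANCHORS[11]
    return max(lo + (hi - lo) / 3.0 * (g - 8.0), 0.5)


@dataclass(frozen=True)
class HmmParams:
    """Tunable parameters of the diplotype HMM.

    epsilon
        Genotyping error rate (probability an observed call is wrong);
        default 0.002.
    n_gen_eff
        Visible founder-switch density per Morgan per haplotype.  Defaults
        to the generation-11 calibration; pipelines normally override it
        per sample from the recorded outbreeding generation.
    map_function
        Distance <-> recombination-fraction conversion used for marker
        intervals.
    lod_cap
        Ceiling (and symmetric floor) for genotyping-error LOD scores at
        degenerate posteriors.
    """

    epsilon: float = 0.002
    n_gen_eff: float = DO_GEN_EFF_ANCHORS[11]
    map_function: MapFunctionSpec = field(default_factory=MapFunctionSpec)
    lod_cap: float = 12.0

    def __post_init__(self):
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")
        if self.n_gen_eff <= 0:
            raise ValueError("n_gen_eff must be positive")


@dataclass
class DiplotypePosterior:
    """Marginal diplotype posteriors along one chromosome of one sample."""

    sample: str
    chromosome: str
    markers: pd.Index
    probs: np.ndarray  # (n_markers, 36), rows sum to 1
    loglik: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.markers, columns=STATE_LABELS)


# ---------------------------------------------------------------------------
# model building blocks
# ---------------------------------------------------------------------------


def haplotype_kernel(d_cM: float, a: float, map_function: MapFunctionSpec | None = None) -> np.ndarray:
    """8x8 single-haplotype founder transition matrix over a marker interval.

    The interval length is mapped to a recombination fraction (with a small
    floor) and back to an effective distance, then the exchange process with
    density ``a`` per Morgan gives stay probability
    ``exp(-a d/100) + (1 - exp(-a d/100))/8`` and probability
    ``(1 - exp(-a d/100))/8`` of landing on each other founder.
    """
    spec = map_function or MapFunctionSpec()
    r = interval_rf(d_cM, spec)
    d_eff = spec.dist(r)
    lam = a * d_eff / 100.0
    p_each = (1.0 - np.exp(-lam)) / N_FOUNDERS
    kernel = np.full((N_FOUNDERS, N_FOUNDERS), p_each)
    np.fill_diagonal(kernel, p_each + np.exp(-lam))
    return kernel


def transition_matrix(d_cM: float, params: HmmParams) -> np.ndarray:
    """36x36 diplotype transition matrix for a marker interval of ``d_cM``.

    Product of two independent single-haplotype kernels, collapsed from
    ordered founder pairs to the 36 unordered states.  Rows sum to 1.
    """
    if d_cM < 0:
        raise ValueError("interval length must be non-negative")
    a = map_expansion_rate(params.n_gen_eff)
    k1 = haplotype_kernel(d_cM, a, params.map_function)
    src_k = STATE_PAIRS[:, 0][:, None]
    src_j = STATE_PAIRS[:, 1][:, None]
    dst_k = STATE_PAIRS[:, 0][None, :]
    dst_j = STATE_PAIRS[:, 1][None, :]
    direct = k1[src_k, dst_k] * k1[src_j, dst_j]
    crossed = k1[src_k, dst_j] * k1[src_j, dst_k]
    het_dst = (STATE_PAIRS[:, 0] != STATE_PAIRS[:, 1])[None, :]
    return np.where(het_dst, direct + crossed, direct)


def emission_probs(obs: int, founder_calls: np.ndarray, epsilon: float) -> np.ndarray:
    """Emission probabilities of one observed call under each of 36 states.

    For state (j, k) the true SNP genotype is the sum of the founder allele
    codes; the observation matches with probability ``1 - epsilon`` and is
    each wrong genotype with probability ``epsilon / 2``.  A missing
    observation, or a state involving a founder with a missing call, is
    uninformative (emission 1).
    """
    f = np.asarray(founder_calls)
    return _emissions(np.array([obs]), f[None, :], epsilon)[0]


def _emissions(obs: np.ndarray, founder_calls: np.ndarray, epsilon: float) -> np.ndarray:
    """(n_markers, 36) emission matrix; vectorized form of emission_probs."""
    fk = founder_calls[:, STATE_PAIRS[:, 0]]
    fj = founder_calls[:, STATE_PAIRS[:, 1]]
    true_geno = fk + fj
    invalid = (fk == ALLELE_NA) | (fj == ALLELE_NA)
    e = np.where(true_geno == obs[:, None], 1.0 - epsilon, epsilon / 2.0)
    e[invalid] = 1.0
    e[obs == GENO_NA, :] = 1.0
    return e


# ---------------------------------------------------------------------------
# forward-backward
# ---------------------------------------------------------------------------


def forward_backward(
    obs: np.ndarray,
    founder_calls: np.ndarray,
    positions_cM: np.ndarray,
    params: HmmParams,
    *,
    sample: str = "",
    chromosome: str = "",
    markers: pd.Index | None = None,
    _trans_cache: dict | None = None,
) -> DiplotypePosterior:
    """Marginal diplotype posteriors for one sample along one chromosome.

    ``obs`` holds genotype codes, ``founder_calls`` the (n, 8) founder
    allele codes, and ``positions_cM`` the map positions.  The chain starts
    from the stationary distribution and uses per-marker scaled forward and
    backward passes, so chromosomes with tens of thousands of markers do
    not underflow.  An all-missing chromosome yields the stationary
    distribution at every marker.
    """
    obs = np.asarray(obs)
    n = len(obs)
    if n == 0:
        raise ValueError("need at least one marker")
    pos = np.asarray(positions_cM, dtype=float)
    e = _emissions(obs, np.asarray(founder_calls), params.epsilon)

    cache = _trans_cache if _trans_cache is not None else {}

    def trans(d: float) -> np.ndarray:
        key = (round(d, 9), round(params.n_gen_eff, 9), params.map_function.name)
        if key not in cache:
            cache[key] = transition_matrix(d, params)
        return cache[key]

    alpha = np.empty((n, N_STATES))
    scale = np.empty(n)
    a_t = STATIONARY * e[0]
    scale[0] = a_t.sum()
    alpha[0] = a_t / scale[0]
    for t in range(1, n):
        a_t = (alpha[t - 1] @ trans(pos[t] - pos[t - 1])) * e[t]
        scale[t] = a_t.sum()
        alpha[t] = a_t / scale[t]

    beta = np.empty((n, N_STATES))
    beta[n - 1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = trans(pos[t + 1] - pos[t]) @ (e[t + 1] * beta[t + 1]) / scale[t + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return DiplotypePosterior(
        sample=sample,
        chromosome=chromosome,
        markers=markers if markers is not None else pd.RangeIndex(n),
        probs=post,
        loglik=float(np.log(scale).sum()),
    )


def reconstruct(
    gm: GenotypeMatrix,
    founders: FounderGenotypes,
    gmap: GeneticMap,
    params: HmmParams | None = None,
    *,
    samples=None,
    chromosomes=None,
    gen_eff: pd.Series | None = None,
) -> dict[tuple[str, str], DiplotypePosterior]:
    """Diplotype posteriors for every (sample, autosome) pair.

    ``gen_eff`` optionally maps sample id -> switch density; otherwise the
    density is derived from each sample's recorded outbreeding generation
    (falling back to ``params.n_gen_eff``).  Returns a dict keyed by
    (sample, chromosome).
    """
    params = params or HmmParams()
    samples = list(samples) if samples is not None else list(gm.sample_ids)
    chromosomes = list(chromosomes) if chromosomes is not None else gmap.autosomes

    if gen_eff is None:
        gens = gm.sample_meta["generation"]
        gen_eff = pd.Series(
            [
                n_gen_eff_for(gens.loc[s]) if s in gens.index and pd.notna(gens.loc[s])
                else params.n_gen_eff
                for s in samples
            ],
            index=samples,
        )

    out: dict[tuple[str, str], DiplotypePosterior] = {}
    cache: dict = {}
    for chrom in chromosomes:
        chrom_markers = gmap.markers_on(chrom)
        markers = chrom_markers[chrom_markers.isin(gm.marker_ids)]
        if len(markers) == 0:
            continue
        pos = gmap.table.loc[markers, "position_cM"].to_numpy()
        fcalls = founders.calls.loc[markers].to_numpy()
        calls = gm.calls.loc[markers, samples].to_numpy()
        for si, s in enumerate(samples):
            p = replace(params, n_gen_eff=float(gen_eff.loc[s]))
            out[(s, chrom)] = forward_backward(
                calls[:, si],
                fcalls,
                pos,
                p,
                sample=s,
                chromosome=chrom,
                markers=markers,
                _trans_cache=cache,
            )
    return out


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def collapse_to_snp_probs(probs: np.ndarray, founder_calls: np.ndarray) -> np.ndarray:
    """Collapse 36-state posteriors to (p_AA, p_AB, p_BB) per marker.

    Each diplotype's mass is added to the SNP genotype implied by the two
    founder alleles.  Markers with any missing founder call are flagged
    partial: their row is all-NaN.
    """
    single = probs.ndim == 1
    p = probs[None, :] if single else probs
    f = np.asarray(founder_calls)
    f = f[None, :] if f.ndim == 1 else f
    fk = f[:, STATE_PAIRS[:, 0]]
    fj = f[:, STATE_PAIRS[:, 1]]
    true_geno = fk + fj
    out = np.empty((p.shape[0], 3))
    for g in range(3):
        out[:, g] = np.where(true_geno == g, p, 0.0).sum(axis=1)
    out[((fk == ALLELE_NA) | (fj == ALLELE_NA)).any(axis=1)] = np.nan
    return out[0] if single else out


def call_max_marginal(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Max-marginal diplotype call per marker; missing (-1) unless the
    maximum posterior strictly exceeds ``threshold``."""
    single = probs.ndim == 1
    p = probs[None, :] if single else probs
    idx = p.argmax(axis=1)
    best = p[np.arange(len(idx)), idx]
    calls = np.where(best > threshold, idx, -1).astype(np.int32)
    return int(calls[0]) if single else calls


def call_all(
    posteriors: dict[tuple[str, str], DiplotypePosterior], threshold: float = 0.5
) -> dict[tuple[str, str], np.ndarray]:
    """Max-marginal calls for every reconstructed (sample, chromosome)."""
    return {key: call_max_marginal(dp.probs, threshold) for key, dp in posteriors.items()}


def predicted_snp_genotypes(calls: np.ndarray, founder_calls: np.ndarray) -> np.ndarray:
    """SNP genotypes implied by called diplotypes via the founder alleles.

    Missing calls, or incomplete founder genotypes for the called state,
    yield missing.
    """
    calls = np.asarray(calls)
    f = np.asarray(founder_calls)
    out = np.full(len(calls), GENO_NA, dtype=np.int8)
    ok = calls >= 0
    if ok.any():
        fk = f[np.arange(len(calls))[ok], STATE_PAIRS[calls[ok], 0]]
        fj = f[np.arange(len(calls))[ok], STATE_PAIRS[calls[ok], 1]]
        geno = (fk + fj).astype(np.int8)
        geno[(fk == ALLELE_NA) | (fj == ALLELE_NA)] = GENO_NA
        out[ok] = geno
    return out


def genotyping_error_lod(
    snp_probs: np.ndarray, obs: np.ndarray, epsilon: float, cap: float = 12.0
) -> np.ndarray:
    """Genotyping-error LOD score per marker.

    With ``q_y`` the posterior probability of the *observed* SNP genotype,

        LOD = log10[(1 - q_y) / q_y] + log10[(1 - epsilon) / epsilon].

    Large values mean the multipoint information contradicts the observed
    call.  Missing observations and partial (NaN) posteriors get NaN;
    degenerate posteriors are clipped to ``+/- cap``.
    """
    single = np.ndim(obs) == 0
    o = np.atleast_1d(np.asarray(obs))
    p = np.atleast_2d(np.asarray(snp_probs, dtype=float))
    out = np.full(len(o), np.nan)
    ok = (o != GENO_NA) & ~np.isnan(p).any(axis=1)
    if ok.any():
        q = p[np.arange(len(o))[ok], o[ok]]
        with np.errstate(divide="ignore"):
            lod = np.log10((1.0 - q) / q) + np.log10((1.0 - epsilon) / epsilon)
        out[ok] = np.clip(lod, -cap, cap)
    return float(out[0]) if single else out


def posterior_abs_diff(post_before: np.ndarray, post_after: np.ndarray) -> np.ndarray | float:
    """Sum of absolute differences between two posteriors, in [0, 2].

    0 iff identical; 2 iff the probability mass moved to a disjoint set of
    diplotype states.  Operates row-wise on matrices.
    """
    a = np.asarray(post_before, dtype=float)
    b = np.asarray(post_after, dtype=float)
    d = np.abs(a - b).sum(axis=-1)
    return float(d) if d.ndim == 0 else d


def error_lod_table(
    posteriors: dict[tuple[str, str], DiplotypePosterior],
    gm: GenotypeMatrix,
    founders: FounderGenotypes,
    epsilon: float = 0.002,
    call_threshold: float = 0.5,
    lod_cap: float = 12.0,
) -> pd.DataFrame:
    """Tidy per-site error-LOD table.

    One row per (sample, marker) covered by the reconstructions, with the
    observed call, the predicted call from the max-marginal diplotype, and
    the error LOD (NaN where unscorable: missing observation or incomplete
    founder genotypes).
    """
    frames = []
    for (s, chrom), dp in sorted(posteriors.items()):
        fcalls = founders.calls.loc[dp.markers].to_numpy()
        obs = gm.calls.loc[dp.markers, s].to_numpy()
        snp_p = collapse_to_snp_probs(dp.probs, fcalls)
        lod = genotyping_error_lod(snp_p, obs, epsilon, cap=lod_cap)
        calls = call_max_marginal(dp.probs, call_threshold)
        pred = predicted_snp_genotypes(calls, fcalls)
        frames.append(
            pd.DataFrame(
                {
                    "sample": s,
                    "chromosome": chrom,
                    "marker": dp.markers,
                    "obs": obs,
                    "predicted": pred,
                    "lod": lod,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["sample", "chromosome", "marker", "obs", "predicted", "lod"])
    return pd.concat(frames, ignore_index=True)


__all__ = [
    "N_STATES",
    "STATE_PAIRS",
    "STATE_LABELS",
    "STATE_IS_HOM",
    "STATIONARY",
    "DO_GEN_EFF_ANCHORS",
    "state_index",
    "n_gen_eff_for",
    "HmmParams",
    "DiplotypePosterior",
    "haplotype_kernel",
    "transition_matrix",
    "emission_probs",
    "forward_backward",
    "reconstruct",
    "collapse_to_snp_probs",
    "call_max_marginal",
    "call_all",
    "predicted_snp_genotypes",
    "genotyping_error_lod",
    "posterior_abs_diff",
    "error_lod_table",
]
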