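"""Synthetic Diversity-Outbred-like datasets with known ground truth.

The generator emulates the structure of an 8-founder outbred cohort typed
on a SNP array: founder strains with a realistic minor-allele-frequency
spectrum, per-sample founder-haplotype mosaics whose switch density grows
with outbreeding generation, biallelic genotypes derived from founder
alleles, independent genotyping error and missingness, engineered problem
samples (high missingness, duplicates, sex mislabels, XO/XXY), and
clustered two-channel probe intensities with sex-chromosome dosage
effects.

The mosaic switch kernel is identical to the transition kernel of the
diplotype HMM (exchange points at density ``a = n_gen_eff * 8/7`` per
Morgan, founder redrawn uniformly with self allowed), so reconstruction
round-trips are exact model matches.  Crossover interference is not
simulated; the Carter-Falconer map function enters only at inference time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (
    ALLELE_NA,
    GENO_NA,
    FOUNDER_LABELS,
    N_FOUNDERS,
    DatasetBundle,
    FounderGenotypes,
    GeneticMap,
    GenotypeMatrix,
    IntensityMatrix,
    write_control_file,
    write_founders,
    write_genotypes,
    write_intensities,
    write_map,
    write_sample_meta,
)
from .do_hmm import n_gen_eff_for
from .map_functions import map_expansion_rate

#: Default founder-MAF class weights: minor-allele counts 1..4 under
#: independent uniform allele assignment, conditioned on polymorphism
#: (binomial(8, 1/2) folded at 4).
BINOMIAL_MAF_WEIGHTS = (16 / 254, 56 / 254, 112 / 254, 70 / 254)


@dataclass(frozen=True)
class BadSampleSpec:
    """Elevated missingness / error rates for one engineered bad sample."""

    missing_rate: float = 0.25
    error_rate: float = 0.02


@dataclass(frozen=True)
class IntensityParams:
    """Cluster parameters for simulated two-channel probe intensities.

    ``mean_*`` are (x, y) channel means for each autosomal genotype
    cluster; ``sd`` the common per-channel noise; ``y_level`` the Y-marker
    intensity in samples carrying a Y; ``background`` the level of absent
    targets.  X markers are scaled by X dosage (XX = 1, XY = XO = 0.5,
    XXY = 1) and Y markers by Y presence.
    """

    mean_AA: tuple[float, float] = (1.0, 0.1)
    mean_AB: tuple[float, float] = (0.55, 0.55)
    mean_BB: tuple[float, float] = (0.1, 1.0)
    sd: float = 0.08
    y_level: float = 0.55
    background: float = 0.06


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic dataset.

    Defaults describe the standard desk-scale cohort: 60 samples from two
    outbreeding generations (20 at generation 8, 40 at generation 11,
    mirroring the roughly 1:2 split of the motivating study), 10 autosomes
    of 200 markers at 1 cM spacing, genotyping error rate 0.2% and 1%
    missingness, two high-missingness samples, one duplicate pair, one
    sex-mislabeled sample, one XO female and one XXY male.
    """

    n_chromosomes: int = 10
    n_markers_per_chromosome: int = 200
    marker_spacing_cM: float = 1.0
    n_samples_by_generation: tuple[tuple[int, int], ...] = ((8, 20), (11, 40))
    n_gen_eff_by_generation: tuple[tuple[int, float], ...] | None = None
    maf_weights: tuple[float, float, float, float] = BINOMIAL_MAF_WEIGHTS
    founder_missing_rate: float = 0.0
    epsilon_sim: float = 0.002
    missing_rate: float = 0.01
    bad_samples: tuple[BadSampleSpec, ...] = (
        BadSampleSpec(0.25, 0.02),
        BadSampleSpec(0.55, 0.05),
    )
    duplicate_pairs: tuple[tuple[int, int], ...] = ((-2, -1),)
    n_xo_females: int = 1
    n_xxy_males: int = 1
    n_sex_mislabels: int = 1
    n_x_markers: int = 100
    n_y_markers: int = 30
    intensity: IntensityParams = field(default_factory=IntensityParams)
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.n_samples_by_generation)

    def gen_eff(self, generation: int) -> float:
        if self.n_gen_eff_by_generation is not None:
            table = dict(self.n_gen_eff_by_generation)
            if generation in table:
                return float(table[generation])
        return n_gen_eff_for(generation)


@dataclass
class SimTruth:
    """Hidden state of a simulated dataset (the oracle for every diagnostic)."""

    mosaics: dict  # sample -> chromosome -> (hap1, hap2 or None)
    true_calls: pd.DataFrame  # markers x samples, int8, pre-corruption
    error_mask: pd.DataFrame  # bool, injected genotype errors
    missing_mask: pd.DataFrame  # bool, injected missingness
    founder_alleles: pd.DataFrame  # complete founder alleles (no masking)
    true_sex: pd.Series  # XX / XY / XO / XXY
    nominal_sex: pd.Series  # M / F as labeled (mislabels included)
    generation: pd.Series
    n_gen_eff: pd.Series
    duplicates: list[tuple[str, str]]
    bad_samples: dict  # sample -> BadSampleSpec

    def visible_switches(self, sample: str, chromosomes=None) -> int:
        """Number of founder switches visible in the sample's mosaic."""
        total = 0
        for chrom, haps in self.mosaics[sample].items():
            if chromosomes is not None and chrom not in chromosomes:
                continue
            for hap in haps:
                if hap is not None:
                    total += int((np.asarray(hap)[1:] != np.asarray(hap)[:-1]).sum())
        return total


@dataclass
class SimDataset:
    """A complete simulated dataset plus its hidden truth."""

    genotypes: GenotypeMatrix
    founders: FounderGenotypes
    gmap: GeneticMap
    intensities: IntensityMatrix
    truth: SimTruth
    config: SimConfig

    @property
    def bundle(self) -> DatasetBundle:
        return DatasetBundle(self.genotypes, self.founders, self.gmap, self.intensities)


# ---------------------------------------------------------------------------
# component generators
# ---------------------------------------------------------------------------


def simulate_founders(
    n_markers: int,
    maf_weights=BINOMIAL_MAF_WEIGHTS,
    seed=None,
    *,
    index: pd.Index | None = None,
) -> FounderGenotypes:
    """Founder allele matrix with the given MAF-class spectrum.

    Each marker draws a minor-allele count (class 1..4) from
    ``maf_weights`` and assigns allele B to a uniformly chosen founder
    subset of that size, so every marker is polymorphic and A is the
    founder-major allele (classes 1-3) or the tie-broken major (class 4).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.asarray(maf_weights, dtype=float)
    if w.shape != (4,) or not np.isclose(w.sum(), 1.0):
        raise ValueError("maf_weights must be 4 class weights summing to 1")
    classes = rng.choice(np.arange(1, 5), size=n_markers, p=w)
    alleles = np.zeros((n_markers, N_FOUNDERS), dtype=np.int8)
    for i, c in enumerate(classes):
        minor = rng.choice(N_FOUNDERS, size=c, replace=False)
        alleles[i, minor] = 1
    if index is None:
        index = pd.Index([f"m{i:05d}" for i in range(n_markers)], name="marker")
    return FounderGenotypes(
        pd.DataFrame(alleles, index=index, columns=list(FOUNDER_LABELS))
    )


def simulate_mosaic(positions_cM: np.ndarray, n_gen_eff: float, rng) -> np.ndarray:
    """One haplotype's founder-label sequence along a chromosome.

    The initial founder is uniform on 8; over an interval of ``d`` cM a
    switch event occurs with probability ``1 - exp(-a d / 100)`` with
    ``a = n_gen_eff * 8/7``, after which the founder is redrawn uniformly
    (self allowed), so visible switches occur at 7/8 of the event rate.
    """
    pos = np.asarray(positions_cM, dtype=float)
    n = len(pos)
    a = map_expansion_rate(n_gen_eff)
    d = np.diff(pos)
    switched = rng.random(n - 1) < 1.0 - np.exp(-a * d / 100.0)
    seg_id = np.concatenate([[0], np.cumsum(switched)])
    seg_founders = rng.integers(0, N_FOUNDERS, size=seg_id[-1] + 1)
    return seg_founders[seg_id].astype(np.int8)


def genotypes_from_mosaic(
    hap1: np.ndarray, hap2: np.ndarray | None, founder_alleles: np.ndarray
) -> np.ndarray:
    """SNP genotypes implied by one or two founder-label sequences.

    With allele codes 0/1 the genotype code is simply the allele sum; a
    hemizygous chromosome (``hap2`` None) reports the homozygous call for
    its single allele.  Missing founder alleles propagate to missing.
    """
    f = np.asarray(founder_alleles)
    idx = np.arange(len(hap1))
    a1 = f[idx, np.asarray(hap1)]
    a2 = a1 if hap2 is None else f[idx, np.asarray(hap2)]
    g = (a1 + a2).astype(np.int8)
    g[(a1 == ALLELE_NA) | (a2 == ALLELE_NA)] = GENO_NA
    return g


def corrupt(
    clean: pd.DataFrame,
    epsilon_sim: float,
    missing_rate: float,
    bad_sample_specs: dict | None = None,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Inject missingness and genotyping errors into a clean call matrix.

    Each call goes missing independently with its sample's missing rate;
    surviving calls flip to a uniformly chosen other genotype with the
    sample's error rate.  ``bad_sample_specs`` maps sample id ->
    :class:`BadSampleSpec` overriding the global rates.  Returns the
    observed matrix plus boolean error and missing masks (disjoint).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bad = bad_sample_specs or {}
    arr = clean.to_numpy().copy()
    miss_rate = np.array(
        [bad[s].missing_rate if s in bad else missing_rate for s in clean.columns]
    )
    err_rate = np.array(
        [bad[s].error_rate if s in bad else epsilon_sim for s in clean.columns]
    )
    defined = arr != GENO_NA
    miss = (rng.random(arr.shape) < miss_rate[None, :]) & defined
    err = (rng.random(arr.shape) < err_rate[None, :]) & defined & ~miss
    offset = rng.integers(1, 3, size=arr.shape)
    arr[err] = (arr[err] + offset[err]) % 3
    arr[miss] = GENO_NA
    observed = pd.DataFrame(arr, index=clean.index, columns=clean.columns)
    mk = lambda m: pd.DataFrame(m, index=clean.index, columns=clean.columns)
    return observed, mk(err), mk(miss)


# X/Y dosage by sex-chromosome constitution
_X_DOSE = {"XX": 1.0, "XY": 0.5, "XO": 0.5, "XXY": 1.0}
_HAS_Y = {"XX": False, "XY": True, "XO": False, "XXY": True}


def simulate_intensities(
    genotypes: pd.DataFrame,
    true_sex: pd.Series,
    params: IntensityParams,
    x_markers,
    y_markers,
    seed=None,
) -> IntensityMatrix:
    """Two-channel probe intensities for all markers of a dataset.

    Autosomal (and X) markers draw from the genotype's cluster with
    independent Gaussian noise per channel; X markers are scaled by the
    sample's X dosage and Y markers sit at the carrier level or background
    according to Y presence.  Intensities are clipped at zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x_markers = pd.Index(x_markers)
    y_markers = pd.Index(y_markers)
    all_markers = genotypes.index.append(y_markers)
    samples = genotypes.columns
    means = np.array([params.mean_AA, params.mean_AB, params.mean_BB, (params.background,) * 2])
    geno = genotypes.to_numpy().copy()
    geno[geno == GENO_NA] = 3  # background cluster for undefined truth

    mu = means[geno]  # (n_geno_markers, n_samples, 2)
    x_dose = true_sex.loc[samples].map(_X_DOSE).to_numpy()
    on_x = genotypes.index.isin(x_markers)
    mu = mu * np.where(on_x[:, None], x_dose[None, :], 1.0)[:, :, None]

    y_dose = np.array([params.y_level if _HAS_Y[s] else params.background for s in true_sex.loc[samples]])
    mu_y = np.broadcast_to(y_dose[None, :, None], (len(y_markers), len(samples), 2))
    mu = np.concatenate([mu, mu_y], axis=0)

    noise = rng.normal(0.0, params.sd, size=mu.shape)
    vals = np.clip(mu + noise, 0.0, None)
    x = pd.DataFrame(vals[:, :, 0], index=all_markers, columns=samples)
    y = pd.DataFrame(vals[:, :, 1], index=all_markers, columns=samples)
    return IntensityMatrix(x, y)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def _build_map(config: SimConfig) -> tuple[GeneticMap, pd.Index, pd.Index, pd.Index]:
    rows = []
    sp = config.marker_spacing_cM
    for c in range(1, config.n_chromosomes + 1):
        for i in range(config.n_markers_per_chromosome):
            rows.append((f"m{c:02d}_{i:04d}", str(c), i * sp))
    for i in range(config.n_x_markers):
        rows.append((f"mX_{i:04d}", "X", i * sp))
    for i in range(config.n_y_markers):
        rows.append((f"mY_{i:04d}", "Y", i * sp))
    table = pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"]).set_index(
        "marker"
    )
    gmap = GeneticMap(table)
    auto = table.index[table["chromosome"].str.isdigit()]
    x = table.index[table["chromosome"] == "X"]
    y = table.index[table["chromosome"] == "Y"]
    return gmap, auto, x, y


def make_dataset(config: SimConfig) -> SimDataset:
    """Generate a fully consistent synthetic dataset from one seed.

    Identical configurations (including the seed) produce bit-identical
    datasets.  Duplicate samples share a mosaic but are corrupted
    independently.
    """
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_founders = np.random.default_rng(streams[0])
    rng_roles = np.random.default_rng(streams[1])
    rng_mosaic = np.random.default_rng(streams[2])
    rng_corrupt = np.random.default_rng(streams[3])
    rng_intens = np.random.default_rng(streams[4])

    gmap, auto_markers, x_markers, y_markers = _build_map(config)
    geno_markers = auto_markers.append(x_markers)

    founder_full = simulate_founders(
        len(geno_markers), config.maf_weights, rng_founders, index=geno_markers
    ).calls

    n = config.n_samples
    generations = np.concatenate(
        [np.full(k, g) for g, k in config.n_samples_by_generation]
    )

    # --- sample roles ---------------------------------------------------
    base_male = rng_roles.random(n) < 0.5
    true_sex = np.where(base_male, "XY", "XX").astype(object)

    dup_pairs = [(i % n, j % n) for i, j in config.duplicate_pairs]
    special = {i for pair in dup_pairs for i in pair}
    for i, j in dup_pairs:
        true_sex[j] = true_sex[i]
        generations[j] = generations[i]

    def draw(mask_ok, k):
        pool = [i for i in range(n) if i not in special and mask_ok(i)]
        take = list(rng_roles.choice(pool, size=min(k, len(pool)), replace=False))
        special.update(take)
        return take

    xo = draw(lambda i: true_sex[i] == "XX", config.n_xo_females)
    for i in xo:
        true_sex[i] = "XO"
    xxy = draw(lambda i: true_sex[i] == "XY", config.n_xxy_males)
    for i in xxy:
        true_sex[i] = "XXY"
    mislabeled = draw(lambda i: true_sex[i] == "XX", config.n_sex_mislabels)
    bad_idx = draw(lambda i: True, len(config.bad_samples))

    nominal = np.array(["M" if _HAS_Y[s] else "F" for s in true_sex], dtype=object)
    for i in mislabeled:
        nominal[i] = "M" if nominal[i] == "F" else "F"
    sample_ids = pd.Index(
        [f"{nominal[i]}{i + 1:03d}" for i in range(n)], name="sample"
    )

    gen_eff = pd.Series(
        [config.gen_eff(int(g)) for g in generations], index=sample_ids, name="n_gen_eff"
    )

    # --- mosaics and true genotypes -------------------------------------
    auto_chroms = [str(c) for c in range(1, config.n_chromosomes + 1)]
    mosaics: dict[str, dict] = {}
    true_calls = np.empty((len(geno_markers), n), dtype=np.int8)
    marker_pos = {c: gmap.positions_on(c) for c in auto_chroms + ["X"]}
    marker_rows = {
        c: geno_markers.get_indexer(gmap.markers_on(c)) for c in auto_chroms + ["X"]
    }
    dup_source = {j: i for i, j in dup_pairs}

    for i in range(n):
        s = sample_ids[i]
        if i in dup_source:
            mosaics[s] = mosaics[sample_ids[dup_source[i]]]
        else:
            per_chrom = {}
            for c in auto_chroms:
                per_chrom[c] = (
                    simulate_mosaic(marker_pos[c], gen_eff.iloc[i], rng_mosaic),
                    simulate_mosaic(marker_pos[c], gen_eff.iloc[i], rng_mosaic),
                )
            n_x_haps = 2 if true_sex[i] in ("XX", "XXY") else 1
            hx1 = simulate_mosaic(marker_pos["X"], gen_eff.iloc[i], rng_mosaic)
            hx2 = simulate_mosaic(marker_pos["X"], gen_eff.iloc[i], rng_mosaic) if n_x_haps == 2 else None
            per_chrom["X"] = (hx1, hx2)
            mosaics[s] = per_chrom
        for c in auto_chroms + ["X"]:
            h1, h2 = mosaics[s][c]
            rows = marker_rows[c]
            true_calls[rows, i] = genotypes_from_mosaic(h1, h2, founder_full.to_numpy()[rows])

    true_df = pd.DataFrame(true_calls, index=geno_markers, columns=sample_ids)

    # --- corruption ------------------------------------------------------
    bad_specs = {sample_ids[i]: spec for i, spec in zip(bad_idx, config.bad_samples)}
    observed, error_mask, missing_mask = corrupt(
        true_df, config.epsilon_sim, config.missing_rate, bad_specs, rng_corrupt
    )

    # --- founder matrix with optional missingness ------------------------
    founder_out = founder_full.copy()
    if config.founder_missing_rate > 0:
        mask = rng_corrupt.random(founder_out.shape) < config.founder_missing_rate
        arr = founder_out.to_numpy().copy()
        arr[mask] = ALLELE_NA
        founder_out = pd.DataFrame(arr, index=founder_out.index, columns=founder_out.columns)

    # --- intensities ------------------------------------------------------
    sex_series = pd.Series(true_sex, index=sample_ids, name="true_sex")
    intensities = simulate_intensities(
        true_df, sex_series, config.intensity, x_markers, y_markers, rng_intens
    )

    meta = pd.DataFrame(
        {"nominal_sex": nominal, "generation": pd.array(generations, dtype="Int64")},
        index=sample_ids,
    )
    genotypes = GenotypeMatrix(observed, meta)
    truth = SimTruth(
        mosaics=mosaics,
        true_calls=true_df,
        error_mask=error_mask,
        missing_mask=missing_mask,
        founder_alleles=founder_full,
        true_sex=sex_series,
        nominal_sex=pd.Series(nominal, index=sample_ids, name="nominal_sex"),
        generation=pd.Series(pd.array(generations, dtype="Int64"), index=sample_ids, name="generation"),
        n_gen_eff=gen_eff,
        duplicates=[(sample_ids[i], sample_ids[j]) for i, j in dup_pairs],
        bad_samples=bad_specs,
    )
    return SimDataset(genotypes, FounderGenotypes(founder_out), gmap, intensities, truth, config)


def write_dataset(ds: SimDataset, out_dir) -> Path:
    """Write a simulated dataset in the standard CSV + control-file layout.

    Returns the path of the control file.  The hidden truth goes to a
    ``truth/`` subdirectory (sex classes, switch counts, corruption masks).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotypes(ds.genotypes, out / "geno.csv")
    write_founders(ds.founders, out / "founder_geno.csv")
    write_map(ds.gmap, out / "gmap.csv")
    write_sample_meta(ds.genotypes.sample_meta, out / "covar.csv")
    write_intensities(ds.intensities, out / "intensity_x.csv", out / "intensity_y.csv")
    control = out / "control.yaml"
    write_control_file(
        control,
        geno="geno.csv",
        founder_geno="founder_geno.csv",
        gmap="gmap.csv",
        covar="covar.csv",
        intensities=("intensity_x.csv", "intensity_y.csv"),
    )

    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    autosomes = ds.gmap.autosomes
    truth_samples = pd.DataFrame(
        {
            "true_sex": ds.truth.true_sex,
            "nominal_sex": ds.truth.nominal_sex,
            "generation": ds.truth.generation,
            "n_gen_eff": ds.truth.n_gen_eff,
            "n_switches_autosomal": [
                ds.truth.visible_switches(s, autosomes) for s in ds.truth.true_sex.index
            ],
        }
    )
    truth_samples.rename_axis("sample").to_csv(tdir / "samples.csv")
    ds.truth.error_mask.astype(int).rename_axis("marker").to_csv(tdir / "error_mask.csv")
    ds.truth.missing_mask.astype(int).rename_axis("marker").to_csv(tdir / "missing_mask.csv")
    pd.DataFrame(
        ds.truth.duplicates, columns=["sample1", "sample2"]
    ).to_csv(tdir / "duplicates.csv", index=False)
    return control


__all__ = [
    "BINOMIAL_MAF_WEIGHTS",
    "BadSampleSpec",
    "IntensityParams",
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_founders",
    "simulate_mosaic",
    "genotypes_from_mosaic",
    "corrupt",
    "simulate_intensities",
    "make_dataset",
    "write_dataset",
]
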