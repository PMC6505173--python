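"""Per-sample quality-control diagnostics.

Missing-data rates, sex verification from sex-chromosome probe intensities,
duplicate detection from pairwise genotype sharing, array-intensity
profiles, genotype frequencies by founder minor-allele-frequency class,
minimal crossover counts from called diplotypes, and per-sample genotyping
error rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import (
    GENO_AB,
    GENO_NA,
    FounderGenotypes,
    GenotypeMatrix,
    IntensityMatrix,
    founder_maf_class,
    maf_class_expected_freqs,
)
from .do_hmm import STATE_PAIRS


@dataclass(frozen=True)
class QcThresholds:
    """Decision cutoffs for the whole QC pipeline.

    Fractions are on the 0-1 scale.  ``sample_missing_omit`` / ``_note``
    drive sample omission and annotation; ``errorlod_cut`` defines a
    presumed genotyping error; ``duplicate_share`` flags near-identical
    sample pairs (scored only when at least ``min_shared_markers`` markers
    are non-missing in both); ``marker_error_omit`` drives marker
    exclusion; ``call_threshold`` is the minimum posterior for a diplotype
    call.  The two frequency-outlier bounds are advisory: founder-MAF-1/8
    markers whose population minor-allele frequency exceeds
    ``maf1_do_maf_bound`` (allele-frequency distortion, e.g. meiotic
    drive), and founder-MAF-4/8 markers with heterozygosity below
    ``maf4_het_bound``.
    """

    sample_missing_omit: float = 0.20
    sample_missing_note: float = 0.02
    errorlod_cut: float = 2.0
    duplicate_share: float = 0.90
    min_shared_markers: int = 1000
    call_threshold: float = 0.5
    marker_error_omit: float = 0.05
    maf1_do_maf_bound: float = 0.40
    maf4_het_bound: float = 0.25
    marker_missing_note: float = 0.10
    sex_marker_min_z: float = 4.0

    def __post_init__(self):
        for name in (
            "sample_missing_omit",
            "sample_missing_note",
            "duplicate_share",
            "call_threshold",
            "marker_error_omit",
            "maf1_do_maf_bound",
            "maf4_het_bound",
            "marker_missing_note",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


# ---------------------------------------------------------------------------
# missing data
# ---------------------------------------------------------------------------


def percent_missing_by_sample(gm: GenotypeMatrix, informative_markers=None) -> pd.Series:
    """Percent missing genotypes per sample, over the informative markers."""
    calls = gm.calls if informative_markers is None else gm.calls.loc[informative_markers]
    if calls.shape[0] == 0:
        raise ValueError("informative marker set is empty")
    return 100.0 * (calls == GENO_NA).mean(axis=0).rename("pct_missing")


# ---------------------------------------------------------------------------
# sex verification
# ---------------------------------------------------------------------------


def select_sex_informative_x_markers(
    intensities: IntensityMatrix,
    x_markers,
    nominal_sex: pd.Series,
    min_z: float = 4.0,
) -> pd.Index:
    """X markers whose mean intensity separates the nominal sexes.

    Some X-chromosome probes do not show the expected dosage difference
    between XX and XY animals; they are dropped before sex inference.  A
    marker is kept when the z-statistic for the male-female difference in
    mean intensity exceeds ``min_z``.
    """
    x_markers = pd.Index(x_markers)
    avg = intensities.average().loc[x_markers]
    sex = nominal_sex.reindex(avg.columns)
    males, females = avg.loc[:, sex == "M"], avg.loc[:, sex == "F"]
    if males.shape[1] < 2 or females.shape[1] < 2:
        return x_markers
    diff = (females.mean(axis=1) - males.mean(axis=1)).abs()
    se = np.sqrt(
        females.var(axis=1, ddof=1) / females.shape[1]
        + males.var(axis=1, ddof=1) / males.shape[1]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = diff / se
    return x_markers[(z > min_z).fillna(False)]


def sex_check(
    intensities: IntensityMatrix,
    x_markers,
    y_markers,
    nominal_sex: pd.Series | None = None,
    thresholds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Infer each sample's sex-chromosome constitution from probe intensities.

    Per-marker intensity is the mean of the two channels; each sample gets
    its mean over X markers and over Y markers.  Classification against
    thresholds ``(tx, ty)``: high-X/low-Y -> XX, low-X/high-Y -> XY,
    low/low -> XO, high/high -> XXY.  When ``thresholds`` is None they
    default to the midpoints between the nominal-sex group medians; if that
    is impossible (single-sex or unlabeled cohort) every sample is
    ``ambiguous``.
    """
    avg = intensities.average()
    mean_x = avg.loc[pd.Index(x_markers)].mean(axis=0)
    mean_y = avg.loc[pd.Index(y_markers)].mean(axis=0)
    out = pd.DataFrame({"mean_X_intensity": mean_x, "mean_Y_intensity": mean_y})

    if thresholds is None and nominal_sex is not None:
        sex = nominal_sex.reindex(out.index)
        m, f = out[sex == "M"], out[sex == "F"]
        if len(m) and len(f):
            tx = (m["mean_X_intensity"].median() + f["mean_X_intensity"].median()) / 2.0
            ty = (m["mean_Y_intensity"].median() + f["mean_Y_intensity"].median()) / 2.0
            thresholds = (float(tx), float(ty))

    if thresholds is None:
        out["inferred_sex"] = "ambiguous"
        out["sex_mismatch"] = False
        return out

    tx, ty = thresholds
    x_high = out["mean_X_intensity"] > tx
    y_high = out["mean_Y_intensity"] > ty
    inferred = np.select(
        [x_high & ~y_high, ~x_high & y_high, ~x_high & ~y_high, x_high & y_high],
        ["XX", "XY", "XO", "XXY"],
        default="ambiguous",
    )
    out["inferred_sex"] = inferred
    if nominal_sex is not None:
        sex = nominal_sex.reindex(out.index)
        out["sex_mismatch"] = (
            ((sex == "M") & pd.Series(inferred, index=out.index).isin(["XX", "XO"]))
            | ((sex == "F") & pd.Series(inferred, index=out.index).isin(["XY", "XXY"]))
        ).fillna(False)
    else:
        out["sex_mismatch"] = False
    return out


def x_heterozygosity(gm: GenotypeMatrix, x_markers) -> pd.Series:
    """Proportion of heterozygous calls among non-missing X-chromosome calls."""
    calls = gm.calls.loc[pd.Index(x_markers)]
    n_called = (calls != GENO_NA).sum(axis=0)
    n_het = (calls == GENO_AB).sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = n_het / n_called.replace(0, np.nan)
    return out.rename("het_X")


# ---------------------------------------------------------------------------
# duplicates
# ---------------------------------------------------------------------------


def pairwise_match(gm: GenotypeMatrix, min_shared: int = 1000) -> pd.DataFrame:
    """Proportion of matching genotypes for every sample pair.

    For each pair, matches are counted over markers non-missing in both
    samples.  Pairs sharing fewer than ``min_shared`` markers are reported
    with ``prop_match`` NaN (unscored).  Upper-triangular in input sample
    order; a sample is never paired with itself.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    arr = gm.calls.to_numpy()
    called = (arr != GENO_NA).astype(np.float32)
    n_shared = called.T @ called
    n_match = np.zeros_like(n_shared)
    for g in range(3):
        ind = (arr == g).astype(np.float32)
        n_match += ind.T @ ind
    iu, ju = np.triu_indices(gm.n_samples, k=1)
    shared = n_shared[iu, ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(shared > 0, n_match[iu, ju] / shared, np.nan)
    prop = np.where(shared >= min_shared, prop, np.nan)
    samples = gm.sample_ids.to_numpy()
    return pd.DataFrame(
        {
            "sample1": samples[iu],
            "sample2": samples[ju],
            "n_shared": shared.astype(int),
            "prop_match": prop,
        }
    )


def flag_duplicates(match_table: pd.DataFrame, thresholds: QcThresholds | None = None) -> pd.DataFrame:
    """Sample pairs whose genotype sharing exceeds the duplicate threshold.

    Expects a match table computed after omitting high-missingness samples.
    The recommended omission is the second sample of each pair (input
    order); when the two labels cannot be resolved (e.g. same sex) the
    caller may prefer to drop both.
    """
    thresholds = thresholds or QcThresholds()
    flagged = match_table[match_table["prop_match"] > thresholds.duplicate_share].copy()
    flagged["omit_recommended"] = flagged["sample2"]
    return flagged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# array intensity profiles
# ---------------------------------------------------------------------------


@dataclass
class IntensityProfile:
    """Summary of one sample's array-intensity distribution (log10(x+1) scale)."""

    sample: str
    p1: float
    p99: float
    density: pd.DataFrame  # columns bin_left, bin_right, count


def intensity_profile(
    intensities: IntensityMatrix, sample: str, n_bins: int = 50
) -> IntensityProfile:
    """Distribution of a sample's probe intensities after log10(x+1).

    Both channels are pooled across markers.  Percentiles use linear
    interpolation between order statistics (numpy default, type 7).
    """
    vals = np.concatenate(
        [intensities.x[sample].to_numpy(float), intensities.y[sample].to_numpy(float)]
    )
    vals = np.log10(vals[~np.isnan(vals)] + 1.0)
    p1, p99 = np.percentile(vals, [1, 99])
    counts, edges = np.histogram(vals, bins=n_bins)
    density = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    return IntensityProfile(sample=sample, p1=float(p1), p99=float(p99), density=density)


def intensity_percentiles(intensities: IntensityMatrix) -> pd.DataFrame:
    """1st and 99th percentile of log10(x+1) intensities for every sample."""
    rows = {}
    for s in intensities.sample_ids:
        prof = intensity_profile(intensities, s)
        rows[s] = {"intensity_p1": prof.p1, "intensity_p99": prof.p99}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample")


# ---------------------------------------------------------------------------
# genotype frequencies by founder MAF class
# ---------------------------------------------------------------------------


def genotype_freq_by_maf(
    gm: GenotypeMatrix, founders: FounderGenotypes, samples=None
) -> pd.DataFrame:
    """Observed and expected SNP genotype frequencies per founder-MAF class.

    Markers are grouped by minor-allele count among the eight founders
    (classes 1-4; only markers with complete founder genotypes).  For each
    sample and class the observed (f_AA, f_AB, f_BB) among non-missing
    calls is reported next to the equal-dosage expectation.
    """
    classes = founder_maf_class(founders)
    samples = list(samples) if samples is not None else list(gm.sample_ids)
    rows = []
    for cls in (1, 2, 3, 4):
        markers = classes.index[(classes == cls).fillna(False)]
        markers = markers[markers.isin(gm.marker_ids)]
        exp_aa, exp_ab, exp_bb = maf_class_expected_freqs(cls)
        if len(markers) == 0:
            continue
        sub = gm.calls.loc[markers, samples]
        called = (sub != GENO_NA).sum(axis=0)
        for s in samples:
            n = int(called[s])
            col = sub[s]
            f = [float((col == g).sum()) / n if n else np.nan for g in range(3)]
            rows.append(
                {
                    "sample": s,
                    "maf_class": cls,
                    "n_called": n,
                    "f_AA": f[0],
                    "f_AB": f[1],
                    "f_BB": f[2],
                    "exp_AA": exp_aa,
                    "exp_AB": exp_ab,
                    "exp_BB": exp_bb,
                }
            )
    return pd.DataFrame(rows)


def ternary_coords(f_hom_minor, f_het, f_hom_major):
    """Map trinomial frequencies to coordinates in a unit-side triangle.

    The distances to the three sides of an equilateral triangle sum to a
    constant, so (f_hom_minor, f_het, f_hom_major) with sum 1 maps to
    ``x = f_hom_major + f_het / 2``, ``y = f_het * sqrt(3) / 2``.
    """
    a = np.asarray(f_hom_minor, dtype=float)
    h = np.asarray(f_het, dtype=float)
    b = np.asarray(f_hom_major, dtype=float)
    if not np.allclose(a + h + b, 1.0):
        raise ValueError("frequencies must sum to 1")
    x = b + h / 2.0
    y = h * np.sqrt(3.0) / 2.0
    if np.ndim(f_het) == 0:
        return float(x), float(y)
    return x, y


# ---------------------------------------------------------------------------
# crossover counting
# ---------------------------------------------------------------------------


def pair_state_distance(s1: int, s2: int) -> int:
    """Minimal crossovers between two unordered diplotype states.

    0 for identical states, 1 when exactly one founder is shared, 2 when
    the founder pairs are disjoint.
    """
    a = tuple(STATE_PAIRS[s1])
    b = tuple(STATE_PAIRS[s2])
    if a == b:
        return 0
    return 1 if set(a) & set(b) else 2


def count_crossovers(calls_by_chrom) -> int:
    """Minimum crossovers consistent with called diplotypes, genome-wide.

    ``calls_by_chrom`` maps chromosome -> array of called state indices
    (-1 missing).  Missing calls are skipped: the switch distance is taken
    between flanking non-missing calls, which undercounts double
    recombinants hidden in gaps, consistent with a minimal count.
    """
    total = 0
    for seq in calls_by_chrom.values():
        seq = np.asarray(seq)
        present = seq[seq >= 0]
        for s1, s2 in zip(present[:-1], present[1:]):
            total += pair_state_distance(int(s1), int(s2))
    return total


def count_crossovers_by_sample(calls: dict[tuple[str, str], np.ndarray]) -> pd.Series:
    """Genome-wide minimal crossover counts per sample.

    ``calls`` maps (sample, chromosome) -> called state indices, as
    produced by :func:`doqc.do_hmm.call_all`.
    """
    per_sample: dict[str, dict[str, np.ndarray]] = {}
    for (s, chrom), seq in calls.items():
        per_sample.setdefault(s, {})[chrom] = seq
    out = {s: count_crossovers(chroms) for s, chroms in sorted(per_sample.items())}
    return pd.Series(out, name="n_crossovers", dtype=int)


# ---------------------------------------------------------------------------
# error rates
# ---------------------------------------------------------------------------


def sample_error_rate(lod_table: pd.DataFrame, thresholds: QcThresholds | None = None) -> pd.Series:
    """Fraction of scored sites with error LOD above the cutoff, per sample."""
    thresholds = thresholds or QcThresholds()
    scored = lod_table[lod_table["lod"].notna()]
    if not len(scored):
        return pd.Series(dtype=float, name="error_rate")
    rate = scored.groupby("sample")["lod"].apply(
        lambda x: float((x > thresholds.errorlod_cut).mean())
    )
    return rate.rename("error_rate")


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def build_sample_report(
    gm: GenotypeMatrix,
    informative_markers,
    thresholds: QcThresholds | None = None,
    *,
    sex_table: pd.DataFrame | None = None,
    xhet: pd.Series | None = None,
    duplicate_flags: pd.DataFrame | None = None,
    intensity_pcts: pd.DataFrame | None = None,
    crossovers: pd.Series | None = None,
    error_rates: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-sample QC report.

    Missing-data flags are always computed; the other columns are filled
    from whichever diagnostic tables are supplied.
    """
    thresholds = thresholds or QcThresholds()
    pct_missing = percent_missing_by_sample(gm, informative_markers)
    report = pd.DataFrame({"pct_missing": pct_missing})
    report["nominal_sex"] = gm.sample_meta["nominal_sex"]
    report["generation"] = gm.sample_meta["generation"]
    report["flag_omit_missing"] = report["pct_missing"] >= 100.0 * thresholds.sample_missing_omit
    report["flag_note_missing"] = (
        report["pct_missing"] >= 100.0 * thresholds.sample_missing_note
    ) & ~report["flag_omit_missing"]

    if sex_table is not None:
        for col in ("mean_X_intensity", "mean_Y_intensity", "inferred_sex", "sex_mismatch"):
            report[col] = sex_table[col]
    if xhet is not None:
        report["pct_het_X"] = 100.0 * xhet
    if intensity_pcts is not None:
        report = report.join(intensity_pcts)
    if crossovers is not None:
        report["n_crossovers"] = crossovers
    if error_rates is not None:
        report["pct_errors"] = 100.0 * error_rates
    report["duplicate_of"] = pd.NA
    if duplicate_flags is not None:
        for _, row in duplicate_flags.iterrows():
            report.loc[row["sample2"], "duplicate_of"] = row["sample1"]
    return report.rename_axis("sample")


__all__ = [
    "QcThresholds",
    "IntensityProfile",
    "percent_missing_by_sample",
    "select_sex_informative_x_markers",
    "sex_check",
    "x_heterozygosity",
    "pairwise_match",
    "flag_duplicates",
    "intensity_profile",
    "intensity_percentiles",
    "genotype_freq_by_maf",
    "ternary_coords",
    "pair_state_distance",
    "count_crossovers",
    "count_crossovers_by_sample",
    "sample_error_rate",
    "build_sample_report",
]
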