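"""Per-marker quality-control diagnostics.

Missing-data and genotyping-error rates per marker, genotype frequencies
against founder-MAF-class expectations, exclusion flags, the
cleaning-impact rerun (how much diplotype posteriors change when flagged
markers are dropped), and export of allele-intensity tables for visual
inspection of problem SNPs.

Marker QC is computed only on samples that survived sample-level omission;
the order of operations is fixed: samples first, then markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import (
    GENO_LABELS,
    GENO_NA,
    FounderGenotypes,
    GeneticMap,
    GenotypeMatrix,
    IntensityMatrix,
    founder_maf_class,
    maf_class_expected_freqs,
)
from . import do_hmm
from .do_hmm import DiplotypePosterior, HmmParams, posterior_abs_diff
from .sample_diagnostics import QcThresholds


def percent_missing_by_marker(gm: GenotypeMatrix, retained_samples=None) -> pd.Series:
    """Percent missing genotypes per marker among retained samples."""
    calls = gm.calls if retained_samples is None else gm.calls[list(retained_samples)]
    return 100.0 * (calls == GENO_NA).mean(axis=1).rename("pct_missing")


def marker_error_rate(lod_table: pd.DataFrame, thresholds: QcThresholds | None = None) -> pd.Series:
    """Fraction of scored sites with error LOD above the cutoff, per marker.

    Markers with no scored sites get NaN.
    """
    thresholds = thresholds or QcThresholds()
    scored = lod_table[lod_table["lod"].notna()]
    if not len(scored):
        return pd.Series(dtype=float, name="error_rate")
    rate = scored.groupby("marker")["lod"].apply(
        lambda x: float((x > thresholds.errorlod_cut).mean())
    )
    return rate.rename("error_rate")


def marker_genotype_freqs(
    gm: GenotypeMatrix,
    founders: FounderGenotypes,
    retained_samples=None,
    thresholds: QcThresholds | None = None,
) -> pd.DataFrame:
    """Genotype frequencies per marker with MAF class and expectation.

    Only markers with complete founder genotypes are reported.  Two
    advisory outlier flags: founder-MAF-1/8 markers where the population
    minor-allele frequency exceeds the configured bound (allele-frequency
    distortion), and founder-MAF-4/8 markers with heterozygosity below the
    configured bound.
    """
    thresholds = thresholds or QcThresholds()
    classes = founder_maf_class(founders)
    keep = classes.index[classes.notna() & (classes > 0)]
    keep = keep[keep.isin(gm.marker_ids)]
    calls = gm.calls.loc[keep] if retained_samples is None else gm.calls.loc[keep, list(retained_samples)]
    arr = calls.to_numpy()
    n_called = (arr != GENO_NA).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = {
            g: np.where(n_called > 0, (arr == g).sum(axis=1) / n_called, np.nan)
            for g in range(3)
        }
    out = pd.DataFrame(
        {
            "maf_class": classes.loc[keep].astype(int),
            "n_called": n_called.astype(int),
            "f_AA": freqs[0],
            "f_AB": freqs[1],
            "f_BB": freqs[2],
        },
        index=keep,
    )
    expected = np.array([maf_class_expected_freqs(c) for c in out["maf_class"]])
    out[["exp_AA", "exp_AB", "exp_BB"]] = expected
    # population minor-allele frequency (B is the founder-minor allele)
    f_b = out["f_BB"] + out["f_AB"] / 2.0
    out["do_maf"] = np.minimum(f_b, 1.0 - f_b)
    out["flag_freq_outlier"] = (
        ((out["maf_class"] == 1) & (out["do_maf"] > thresholds.maf1_do_maf_bound))
        | ((out["maf_class"] == 4) & (out["f_AB"] < thresholds.maf4_het_bound))
    ) & (out["n_called"] > 0)
    return out.rename_axis("marker")


def flag_markers(report: pd.DataFrame, thresholds: QcThresholds | None = None) -> pd.Index:
    """Markers recommended for omission: error rate above the cutoff.

    High-missingness and frequency-outlier flags in the report are
    advisory only; only the error-rate rule drives exclusion.
    """
    thresholds = thresholds or QcThresholds()
    if "error_rate" not in report.columns or not len(report):
        return pd.Index([], name="marker")
    omit = report.index[report["error_rate"].fillna(0.0) > thresholds.marker_error_omit]
    return omit


def build_marker_report(
    gm: GenotypeMatrix,
    founders: FounderGenotypes,
    gmap: GeneticMap,
    retained_samples=None,
    lod_table: pd.DataFrame | None = None,
    thresholds: QcThresholds | None = None,
    informative_markers=None,
) -> pd.DataFrame:
    """Assemble the per-marker QC report over informative markers."""
    thresholds = thresholds or QcThresholds()
    markers = (
        pd.Index(informative_markers) if informative_markers is not None else gm.marker_ids
    )
    report = pd.DataFrame(index=markers).rename_axis("marker")
    report["chromosome"] = gmap.table["chromosome"].reindex(markers)
    report["position_cM"] = gmap.table["position_cM"].reindex(markers)
    report["pct_missing"] = percent_missing_by_marker(gm, retained_samples).reindex(markers)
    if lod_table is not None:
        report["error_rate"] = marker_error_rate(lod_table, thresholds).reindex(markers)
    freqs = marker_genotype_freqs(gm, founders, retained_samples, thresholds)
    report = report.join(freqs.drop(columns=["n_called"]), how="left")
    report["flag_high_missing"] = (
        report["pct_missing"] >= 100.0 * thresholds.marker_missing_note
    )
    if "error_rate" in report.columns:
        report["flag_omit_error"] = (
            report["error_rate"].fillna(0.0) > thresholds.marker_error_omit
        )
    # the equal-dosage frequency expectation only holds for autosomes:
    # hemizygous male X calls depress heterozygosity by design
    autosomal = report["chromosome"].astype(str).str.isdigit()
    report["flag_freq_outlier"] = (
        report["flag_freq_outlier"].fillna(False).astype(bool) & autosomal
    )
    return report


# ---------------------------------------------------------------------------
# cleaning impact
# ---------------------------------------------------------------------------


@dataclass
class CleaningImpact:
    """Change in diplotype posteriors after omitting a marker set.

    ``diffs`` has one row per (sample, chromosome, marker) with the sum of
    absolute posterior differences (in [0, 2]); the summary counts sites
    above 1 and above 1.5.
    """

    diffs: pd.DataFrame
    n_sites: int
    n_gt_1: int
    n_gt_1_5: int
    max_diff: float

    def summary(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "n_gt_1": self.n_gt_1,
            "n_gt_1_5": self.n_gt_1_5,
            "max_diff": self.max_diff,
        }


def cleaning_impact(
    gm: GenotypeMatrix,
    founders: FounderGenotypes,
    gmap: GeneticMap,
    omitted_markers,
    params: HmmParams | None = None,
    *,
    samples=None,
    posteriors_before: dict[tuple[str, str], DiplotypePosterior] | None = None,
    gen_eff: pd.Series | None = None,
) -> CleaningImpact:
    """Recompute posteriors with markers omitted and measure the change.

    Omitted markers have their genotype calls masked to missing, so the
    rerun posterior is still defined at every original marker position and
    the before/after difference covers the full sample x marker grid.
    """
    params = params or HmmParams()
    if posteriors_before is None:
        posteriors_before = do_hmm.reconstruct(
            gm, founders, gmap, params, samples=samples, gen_eff=gen_eff
        )
    omitted = pd.Index(omitted_markers)
    masked_calls = gm.calls.copy()
    masked_calls.loc[masked_calls.index.intersection(omitted)] = GENO_NA
    gm_after = GenotypeMatrix(masked_calls, gm.sample_meta.copy())
    posteriors_after = do_hmm.reconstruct(
        gm_after, founders, gmap, params, samples=samples, gen_eff=gen_eff
    )

    frames = []
    for key in sorted(posteriors_before):
        before = posteriors_before[key]
        after = posteriors_after[key]
        d = posterior_abs_diff(before.probs, after.probs)
        frames.append(
            pd.DataFrame(
                {
                    "sample": key[0],
                    "chromosome": key[1],
                    "marker": before.markers,
                    "abs_diff": d,
                }
            )
        )
    diffs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample", "chromosome", "marker", "abs_diff"]
    )
    return CleaningImpact(
        diffs=diffs,
        n_sites=len(diffs),
        n_gt_1=int((diffs["abs_diff"] > 1.0).sum()),
        n_gt_1_5=int((diffs["abs_diff"] > 1.5).sum()),
        max_diff=float(diffs["abs_diff"].max()) if len(diffs) else 0.0,
    )


# ---------------------------------------------------------------------------
# allele-intensity export
# ---------------------------------------------------------------------------


def allele_intensity_table(
    intensities: IntensityMatrix,
    gm: GenotypeMatrix,
    predicted: pd.DataFrame,
    marker: str,
) -> pd.DataFrame:
    """Per-sample allele intensities with observed and predicted calls.

    ``predicted`` is a markers x samples table of predicted genotype codes
    (from the haplotype reconstruction).  The output enables the standard
    two-channel scatter diagnostic, colored by observed vs predicted
    genotype; no clustering or re-calling is performed.  Samples missing
    from the intensity table keep their row with NaN coordinates.
    """
    if marker not in gm.marker_ids:
        raise KeyError(f"marker {marker!r} not in genotype matrix")
    samples = gm.sample_ids
    x = intensities.x.loc[marker].reindex(samples) if marker in intensities.marker_ids else pd.Series(np.nan, index=samples)
    y = intensities.y.loc[marker].reindex(samples) if marker in intensities.marker_ids else pd.Series(np.nan, index=samples)
    obs = gm.calls.loc[marker].map(GENO_LABELS)
    if marker in predicted.index:
        pred = predicted.loc[marker].reindex(samples).map(GENO_LABELS)
    else:
        pred = pd.Series("NA", index=samples)
    return pd.DataFrame(
        {"sample": samples, "x": x.to_numpy(), "y": y.to_numpy(),
         "observed": obs.to_numpy(), "predicted": pred.to_numpy()}
    )


__all__ = [
    "percent_missing_by_marker",
    "marker_error_rate",
    "marker_genotype_freqs",
    "flag_markers",
    "build_marker_report",
    "CleaningImpact",
    "cleaning_impact",
    "allele_intensity_table",
]
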